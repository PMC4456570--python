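"""Binary activity patterns and the synthetic stimuli used throughout.

The model's universal currency is a fixed-length binary vector over a
population of cells.  Exteroceptive stimuli are sparse random patterns
(300 cells, exactly 8 active by default); interoceptive valence states are
3-cell one-hot codes: pleasant ``(1 0 0)``, unpleasant ``(0 1 0)``, neutral
``(0 0 1)``.  This module also provides the Hamming-distance metric used
for every mismatch/novelty computation, partial-cue degradation, and the
cue/context reversal-learning task set.

Cell indices are 0-based everywhere, including reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BinaryPattern",
    "StimulusPair",
    "ReversalTaskSet",
    "VALENCE_LABELS",
    "VALENCE_CODES",
    "hamming_distance",
    "generate_exteroceptive",
    "make_valence",
    "degrade_cue",
    "generate_stimulus_set",
    "generate_reversal_task",
    "named_streams",
    "write_patterns",
    "read_patterns",
    "write_stimulus_manifest",
    "read_stimulus_manifest",
]

#: Valence labels in the order of their one-hot cells (cells 0, 1, 2).
VALENCE_LABELS = ("positive", "negative", "neutral")

#: One-hot code printed for each valence label.
VALENCE_CODES = {
    "positive": (1, 0, 0),
    "negative": (0, 1, 0),
    "neutral": (0, 0, 1),
}


class BinaryPattern:
    """A fixed-length binary activity vector.

    Wraps a read-only ``numpy`` uint8 array and caches the active count.
    Instances are immutable and hashable, so they can be used as dict keys
    and set members in experiment bookkeeping.
    """

    __slots__ = ("bits", "_n_active")

    def __init__(self, bits: Iterable[int] | np.ndarray):
        arr = np.asarray(bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError(f"pattern must be 1-D, got shape {arr.shape}")
        if arr.size and arr.max() > 1:
            raise ValueError("pattern elements must be 0 or 1")
        arr = arr.copy()
        arr.setflags(write=False)
        self.bits = arr
        self._n_active = int(arr.sum())

    # -- constructors -------------------------------------------------
    @classmethod
    def zeros(cls, length: int) -> "BinaryPattern":
        return cls(np.zeros(length, dtype=np.uint8))

    @classmethod
    def from_indices(cls, length: int, active: Iterable[int]) -> "BinaryPattern":
        bits = np.zeros(length, dtype=np.uint8)
        idx = np.asarray(list(active), dtype=np.intp)
        if idx.size and (idx.min() < 0 or idx.max() >= length):
            raise ValueError("active index out of range")
        bits[idx] = 1
        return cls(bits)

    @classmethod
    def from_string(cls, s: str) -> "BinaryPattern":
        return cls(np.frombuffer(s.encode("ascii"), dtype=np.uint8) - ord("0"))

    # -- views --------------------------------------------------------
    @property
    def length(self) -> int:
        return self.bits.size

    @property
    def n_active(self) -> int:
        """Number of active (1) cells."""
        return self._n_active

    @property
    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    # -- dunder -------------------------------------------------------
    def __len__(self) -> int:
        return self.bits.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryPattern):
            return NotImplemented
        return self.bits.size == other.bits.size and bool(
            np.array_equal(self.bits, other.bits)
        )

    def __hash__(self) -> int:
        return hash(self.bits.tobytes())

    def __repr__(self) -> str:
        if self.length <= 32:
            return f"BinaryPattern('{self.to_string()}')"
        return (
            f"BinaryPattern(length={self.length}, "
            f"active={self.active_indices.tolist()})"
        )


@dataclass(frozen=True)
class StimulusPair:
    """An exteroceptive pattern together with its valence.

    ``intero`` is always the one-hot encoding of ``valence_label``.
    """

    extero: BinaryPattern
    valence_label: str
    intero: BinaryPattern

    def __post_init__(self):
        if self.valence_label not in VALENCE_CODES:
            raise ValueError(f"unknown valence label {self.valence_label!r}")
        if self.intero != make_valence(self.valence_label):
            raise ValueError("intero pattern does not encode valence_label")

    @classmethod
    def make(cls, extero: BinaryPattern, valence_label: str) -> "StimulusPair":
        return cls(extero, valence_label, make_valence(valence_label))


@dataclass(frozen=True)
class ReversalTaskSet:
    """The 12-pattern cue/context discrimination-reversal task.

    Three groups of four stimuli built from 8 cue cells and 8 disjoint
    7-cell context blocks; every stimulus activates exactly one cue cell
    plus the cells of exactly one context block.  Group 1 is the original
    discrimination set, group 2 reverses cues, group 3 reverses contexts.
    """

    group1: tuple[StimulusPair, ...]
    group2: tuple[StimulusPair, ...]
    group3: tuple[StimulusPair, ...]
    cue_cells: tuple[int, ...]
    context_cells: tuple[tuple[int, ...], ...]

    @property
    def all_patterns(self) -> tuple[StimulusPair, ...]:
        return self.group1 + self.group2 + self.group3

    @property
    def old_patterns(self) -> tuple[StimulusPair, ...]:
        return self.group1

    @property
    def new_patterns(self) -> tuple[StimulusPair, ...]:
        return self.group2 + self.group3


def hamming_distance(x: BinaryPattern, y: BinaryPattern) -> int:
    """Number of positions at which two equal-length patterns differ."""
    if x.length != y.length:
        raise ValueError(
            f"incompatible pattern lengths: {x.length} != {y.length}"
        )
    return int(np.count_nonzero(x.bits != y.bits))


def generate_exteroceptive(
    n: int, k: int, rng: np.random.Generator
) -> BinaryPattern:
    """Uniformly random pattern of ``n`` cells with exactly ``k`` active."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    idx = rng.choice(n, size=k, replace=False)
    return BinaryPattern.from_indices(n, idx)


def make_valence(label: str) -> BinaryPattern:
    """One-hot interoceptive pattern for a valence label."""
    try:
        code = VALENCE_CODES[label]
    except KeyError:
        raise ValueError(
            f"unknown valence label {label!r}; expected one of {VALENCE_LABELS}"
        ) from None
    return BinaryPattern(code)


def degrade_cue(
    p: BinaryPattern, d: int, rng: np.random.Generator
) -> BinaryPattern:
    """Silence ``d`` uniformly chosen active cells of ``p`` (partial cue)."""
    if not 0 <= d <= p.n_active:
        raise ValueError(
            f"cannot silence {d} cells of a pattern with {p.n_active} active"
        )
    bits = p.bits.copy()
    off = rng.choice(p.active_indices, size=d, replace=False)
    bits[off] = 0
    return BinaryPattern(bits)


def generate_stimulus_set(
    N: int, n: int, k: int, rng: np.random.Generator
) -> list[StimulusPair]:
    """``N`` independent stimuli with uniformly drawn 3-way valences."""
    if N < 1:
        raise ValueError("N must be >= 1")
    pairs = []
    for _ in range(N):
        extero = generate_exteroceptive(n, k, rng)
        label = VALENCE_LABELS[rng.integers(0, len(VALENCE_LABELS))]
        pairs.append(StimulusPair.make(extero, label))
    return pairs


# Valence signs of the reversal task, per group, in presentation order.
# Names follow cue letter + context number, e.g. "A1".
_REVERSAL_DESIGN = (
    (("A", 1, "positive"), ("B", 2, "positive"), ("C", 3, "negative"), ("D", 4, "negative")),
    (("E", 1, "negative"), ("F", 2, "negative"), ("G", 3, "positive"), ("H", 4, "positive")),
    (("A", 5, "negative"), ("B", 6, "negative"), ("C", 7, "positive"), ("D", 8, "positive")),
)

_CUE_LETTERS = "ABCDEFGH"


def generate_reversal_task(n: int, rng: np.random.Generator) -> ReversalTaskSet:
    """Build the 12-pattern cue/context reversal task on ``n`` cells.

    8 distinct cells encode the 8 cues and 8 disjoint blocks of 7 cells
    encode the 8 contexts (64 cells total); each stimulus is one cue cell
    plus one context block, so every pattern has exactly 8 active cells.
    """
    if n < 64:
        raise ValueError(f"need n >= 64 cells to allocate the task, got {n}")
    cells = rng.choice(n, size=64, replace=False)
    cue_cells = tuple(int(c) for c in cells[:8])
    context_cells = tuple(
        tuple(int(c) for c in cells[8 + 7 * i : 8 + 7 * (i + 1)])
        for i in range(8)
    )

    def build(cue: str, context: int, label: str) -> StimulusPair:
        active = (cue_cells[_CUE_LETTERS.index(cue)],) + context_cells[context - 1]
        return StimulusPair.make(BinaryPattern.from_indices(n, active), label)

    groups = tuple(
        tuple(build(cue, ctx, label) for cue, ctx, label in group)
        for group in _REVERSAL_DESIGN
    )
    return ReversalTaskSet(groups[0], groups[1], groups[2], cue_cells, context_cells)


def named_streams(
    master_seed: int, names: Sequence[str]
) -> dict[str, np.random.Generator]:
    """Independent named RNG substreams derived from one master seed.

    Streams are assigned by position in ``names``, so the same (seed,
    names) call is reproducible bit-for-bit; adding a name at the end does
    not perturb earlier streams.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ----------------------------------------------------------------------
# Plain-text fixtures: one pattern per line as a 0/1 string; stimulus sets
# as a JSON manifest of valence labels + active cell indices.

def write_patterns(path, patterns: Iterable[BinaryPattern]) -> None:
    with open(path, "w") as fh:
        for p in patterns:
            fh.write(p.to_string() + "\n")


def read_patterns(path) -> list[BinaryPattern]:
    with open(path) as fh:
        return [BinaryPattern.from_string(line.strip()) for line in fh if line.strip()]


def write_stimulus_manifest(path, pairs: Iterable[StimulusPair], n: int) -> None:
    payload = {
        "n_cells": n,
        "stimuli": [
            {
                "valence": p.valence_label,
                "active": p.extero.active_indices.tolist(),
            }
            for p in pairs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_stimulus_manifest(path) -> list[StimulusPair]:
    with open(path) as fh:
        payload = json.load(fh)
    n = payload["n_cells"]
    return [
        StimulusPair.make(
            BinaryPattern.from_indices(n, entry["active"]), entry["valence"]
        )
        for entry in payload["stimuli"]
    ]
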