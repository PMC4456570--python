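"""The hippocampal binding model.

Two Willshaw autoassociative networks — one for exteroceptive patterns
(pattern completion), one for interoceptive valence codes — are linked by
plastic heteroassociative synapses onto `p` ordered groups of intermediate
valence cells.  Group 0 is the *primary* group, directly drivable by
interoceptive afferents; groups 1..p-1 are *associated* groups whose
afferent input is gated and only opens when a valence-overload
interference signal is raised by the preceding group.  Prewired
shunting inhibition runs from every later group onto every earlier one,
so at most one group can be active at a time; a group that has been
recruited to re-encode a conflicted association thereby silences the
stale response of earlier groups at recall.

A trial has three phases (recall cascade, mismatch evaluation, optional
learning); both high exteroceptive novelty (HD > e) and valence
prediction errors (HD > v) switch the model into learning mode, in which
activity is driven purely by the afferent patterns and the clipped
Hebbian updates are applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .patterns import BinaryPattern, hamming_distance
from .willshaw import ClippedWeightMatrix

__all__ = [
    "ModelConfig",
    "ValenceLayer",
    "RecallResult",
    "GatingState",
    "TrialRecord",
    "HippocampalModel",
]


@dataclass(frozen=True)
class ModelConfig:
    """Sizes and novelty thresholds of the model.

    n: exteroceptive cells; m: interoceptive (valence) cells;
    n_assoc_groups: associated valence-cell groups beyond the primary one
    (total groups p = 1 + n_assoc_groups); e / v: Hamming-distance novelty
    thresholds for exteroceptive input and valence prediction (strict
    inequality, HD > threshold).
    """

    n: int = 300
    m: int = 3
    n_assoc_groups: int = 4
    e: int = 0
    v: int = 0

    def __post_init__(self):
        if self.n < 1 or self.m < 1 or self.n_assoc_groups < 0:
            raise ValueError("invalid model sizes")
        if self.e < 0 or self.v < 0:
            raise ValueError("novelty thresholds must be >= 0")

    @property
    def p(self) -> int:
        """Total number of valence-cell groups (primary + associated)."""
        return 1 + self.n_assoc_groups


class ValenceLayer:
    """Prewired structure of the intermediate valence cells.

    ``p`` groups of ``m`` cells laid out contiguously (cell i belongs to
    group i // m at within-group position i % m).  Inhibition I_ij = 1 iff
    group(i) > group(j): later groups shunt all earlier ones, none within
    a group.  The projection onto the interoceptive network wires cell i
    to interoceptive cell i % m (valence-identity alignment).
    """

    def __init__(self, p: int, m: int):
        if p < 1 or m < 1:
            raise ValueError("need at least one group of one cell")
        self.p = p
        self.m = m
        size = p * m
        groups = np.arange(size) // m
        self.inhibition = (groups[:, None] > groups[None, :]).astype(np.uint8)
        self.projection = np.zeros((size, m), dtype=np.uint8)
        self.projection[np.arange(size), np.arange(size) % m] = 1

    @property
    def size(self) -> int:
        return self.p * self.m

    def group_slice(self, k: int) -> slice:
        return slice(k * self.m, (k + 1) * self.m)

    def active_groups(self, activity: np.ndarray) -> np.ndarray:
        """Indices of groups containing at least one active cell."""
        return np.flatnonzero(
            activity.reshape(self.p, self.m).any(axis=1)
        )

    def resolve_inhibition(self, excitation: np.ndarray) -> np.ndarray:
        """Closed form of the shunting dynamics.

        Only later->earlier inhibitory wiring exists, so the settling
        process has a unique fixed point: the highest-indexed group with
        any excited cell keeps its activity, every earlier group is
        silenced.
        """
        out = np.zeros_like(excitation)
        active = self.active_groups(excitation)
        if active.size:
            sl = self.group_slice(int(active[-1]))
            out[sl] = excitation[sl]
        return out


@dataclass(frozen=True)
class RecallResult:
    """Activity produced by one pass of the recall cascade."""

    completed_extero: BinaryPattern
    valence_excitation: np.ndarray  # pre-inhibition, length p*m
    valence_activity: np.ndarray  # post-inhibition, length p*m
    intero_input: BinaryPattern
    predicted_intero: BinaryPattern

    def group_activity(self, layer: ValenceLayer, k: int) -> np.ndarray:
        return self.valence_activity[layer.group_slice(k)]


@dataclass(frozen=True)
class GatingState:
    """Per-group interference flags and afferent gates for one trial.

    ``xi[k]`` = interference detected at group k (group active post-
    inhibition AND its activity mismatches the afferent valence beyond
    threshold v).  ``gate[0]`` is always open; ``gate[k]`` opens iff
    ``xi[k-1]`` — the mismatch at a group signals the next one.  Gating is
    recomputed from each trial's recall and not persisted.
    """

    xi: tuple[int, ...]
    gate: tuple[int, ...]

    @property
    def interference_detected(self) -> bool:
        return any(self.xi)


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one trial (recall, mismatch evaluation, optional learning)."""

    completion_hd: int
    prediction_hd: int
    extero_novel: bool
    valence_error: bool
    interference_detected: bool
    learned: bool
    group_used: int | None
    capacity_exhausted: bool
    recall: RecallResult = field(repr=False, compare=False, default=None)

    @property
    def prediction_error(self) -> bool:
        """Valence prediction differs from the delivered valence at all."""
        return self.prediction_hd > 0

    @property
    def completion_error(self) -> bool:
        return self.completion_hd > 0


class HippocampalModel:
    """Interconnected auto/heteroassociative memories with gated valence groups.

    Plastic state: W_e (n x n exteroceptive autoassociation), W_i
    (m x m interoceptive autoassociation), W_ev (n x p*m heteroassociative
    links onto the intermediate valence cells).  All start at zero.
    The valence layer's inhibition and projection are prewired and fixed.
    """

    def __init__(self, config: ModelConfig | None = None, **kwargs):
        if config is None:
            config = ModelConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword fields, not both")
        self.config = config
        self.layer = ValenceLayer(config.p, config.m)
        self.W_e = ClippedWeightMatrix(config.n)
        self.W_i = ClippedWeightMatrix(config.m)
        self.W_ev = ClippedWeightMatrix(config.n, self.layer.size)

    # -- recall cascade ----------------------------------------------
    def recall_extero(self, a_e: BinaryPattern) -> BinaryPattern:
        """Pattern completion in the exteroceptive autoassociative network."""
        return self.W_e.recall(a_e)

    def activate_valence(
        self, completed: BinaryPattern
    ) -> tuple[np.ndarray, np.ndarray]:
        """Drive the intermediate valence cells from a completed pattern.

        Returns (excitation, activity): the thresholded dendritic
        excitation and its inhibition-resolved version, in which only the
        highest-indexed excited group survives.
        """
        if completed.length != self.config.n:
            raise ValueError("completed pattern length mismatch")
        theta = completed.n_active
        if theta == 0:
            exc = np.zeros(self.layer.size, dtype=np.uint8)
        else:
            sums = self.W_ev.w.T @ completed.bits.astype(np.int64)
            exc = (sums >= theta).astype(np.uint8)
        return exc, self.layer.resolve_inhibition(exc)

    def predict_intero(
        self, y: np.ndarray
    ) -> tuple[BinaryPattern, BinaryPattern]:
        """Project valence activity into the interoceptive network and recall."""
        if y.size != self.layer.size:
            raise ValueError("valence activity length mismatch")
        tilde = BinaryPattern(
            (self.layer.projection.T @ y.astype(np.int64) > 0).astype(np.uint8)
        )
        return tilde, self.W_i.recall(tilde)

    def recall(self, cue: BinaryPattern) -> RecallResult:
        """Full feedforward recall cascade from an exteroceptive cue."""
        completed = self.recall_extero(cue)
        exc, act = self.activate_valence(completed)
        tilde, predicted = self.predict_intero(act)
        return RecallResult(completed, exc, act, tilde, predicted)

    # -- mismatch and learning ---------------------------------------
    def detect_interference(
        self, result: RecallResult, a_i: BinaryPattern
    ) -> GatingState:
        """Per-group valence-overload check against the afferent valence.

        Interference at group k requires activity in that group (post-
        inhibition) whose Hamming distance to the delivered interoceptive
        pattern exceeds v.  Since inhibition leaves at most one group
        active, at most one xi flag can be set per trial.
        """
        if a_i.length != self.config.m:
            raise ValueError("interoceptive pattern length mismatch")
        xi = []
        for k in range(self.config.p):
            g = result.valence_activity[self.layer.group_slice(k)]
            active = bool(g.any())
            hd = int(np.count_nonzero(g != a_i.bits))
            xi.append(int(active and hd > self.config.v))
        gate = [1] + [xi[k - 1] for k in range(1, self.config.p)]
        return GatingState(tuple(xi), tuple(gate))

    def learn(
        self, a_e: BinaryPattern, a_i: BinaryPattern, gating: GatingState
    ) -> tuple[int | None, bool]:
        """Apply the clipped Hebbian updates for one learning-mode trial.

        Activity is afferent-driven: both autoassociative stores always
        proceed.  The learning-phase valence activity places ``a_i`` onto
        every gated group; inhibition resolution keeps the highest-indexed
        gated group, which receives the heteroassociative update and is
        returned as ``group_used``.

        If interference was flagged at the last group there is no further
        group to recruit: the heteroassociative update is skipped and
        capacity exhaustion flagged (writing into an already-conflicted
        group could not resolve the conflict).  With p = 1 there is no
        associated-group machinery at all and learning always targets the
        primary group — this is exactly the simple heteroassociative
        baseline.
        """
        self.W_e.store_auto(a_e)
        self.W_i.store_auto(a_i)
        if self.config.p > 1 and gating.xi[-1]:
            return None, True
        x = np.zeros(self.layer.size, dtype=np.uint8)
        for k in range(self.config.p):
            if gating.gate[k]:
                x[self.layer.group_slice(k)] = a_i.bits
        h = self.layer.resolve_inhibition(x)
        group_used = int(self.layer.active_groups(h)[-1]) if h.any() else None
        if h.any():
            self.W_ev.store_hetero(a_e, BinaryPattern(h))
        return group_used, False

    def process_trial(
        self,
        a_e: BinaryPattern,
        a_i: BinaryPattern,
        learning_enabled: bool = True,
        cue: BinaryPattern | None = None,
    ) -> TrialRecord:
        """Run one trial: recall cascade, mismatch evaluation, learning.

        ``cue`` defaults to ``a_e``; pass a degraded version to test
        partial-cue recall (errors are always measured against the intact
        ``a_e`` / ``a_i``).  With learning disabled the model state is
        untouched and the flags are purely diagnostic.
        """
        if cue is None:
            cue = a_e
        result = self.recall(cue)
        completion_hd = hamming_distance(result.completed_extero, a_e)
        prediction_hd = hamming_distance(result.predicted_intero, a_i)
        extero_novel = completion_hd > self.config.e
        valence_error = prediction_hd > self.config.v
        gating = self.detect_interference(result, a_i)
        learned = False
        group_used: int | None = None
        capacity_exhausted = False
        if learning_enabled and (extero_novel or valence_error):
            group_used, capacity_exhausted = self.learn(a_e, a_i, gating)
            learned = True
        return TrialRecord(
            completion_hd=completion_hd,
            prediction_hd=prediction_hd,
            extero_novel=extero_novel,
            valence_error=valence_error,
            interference_detected=gating.interference_detected,
            learned=learned,
            group_used=group_used,
            capacity_exhausted=capacity_exhausted,
            recall=result,
        )

    # -- diagnostics ---------------------------------------------------
    def groups_in_use(self) -> int:
        """Number of associated groups holding any heteroassociative synapse.

        Measured structurally (nonzero W_ev columns within associated
        groups), so it does not depend on transient activity.
        """
        used = 0
        for k in range(1, self.config.p):
            if self.W_ev.w[:, self.layer.group_slice(k)].any():
                used += 1
        return used

    # -- snapshots -----------------------------------------------------
    def snapshot(self) -> dict:
        return {
            "config": {
                "n": self.config.n,
                "m": self.config.m,
                "n_assoc_groups": self.config.n_assoc_groups,
                "e": self.config.e,
                "v": self.config.v,
            },
            "W_e": self.W_e.to_json_obj(),
            "W_i": self.W_i.to_json_obj(),
            "W_ev": self.W_ev.to_json_obj(),
        }

    @classmethod
    def from_snapshot(cls, obj: dict) -> "HippocampalModel":
        model = cls(ModelConfig(**obj["config"]))
        model.W_e = ClippedWeightMatrix.from_json_obj(obj["W_e"])
        model.W_i = ClippedWeightMatrix.from_json_obj(obj["W_i"])
        model.W_ev = ClippedWeightMatrix.from_json_obj(obj["W_ev"])
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.snapshot(), fh)

    @classmethod
    def load(cls, path) -> "HippocampalModel":
        with open(path) as fh:
            return cls.from_snapshot(json.load(fh))

    def __repr__(self) -> str:
        c = self.config
        return (
            f"HippocampalModel(n={c.n}, m={c.m}, p={c.p}, e={c.e}, v={c.v}, "
            f"groups_in_use={self.groups_in_use()})"
        )
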