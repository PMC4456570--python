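"""Binary Willshaw associative memory primitives.

Clipped Hebbian storage on binary synapses (a single pre/post coincidence
sets a weight from 0 to 1; further coincidences change nothing) and
all-or-none threshold recall with the classical Willshaw threshold: a cell
fires iff its dendritic sum reaches the number of active input cells.
These primitives back every plastic projection in the package — the
exteroceptive and interoceptive autoassociative networks, the
extero-to-valence heteroassociative links, and the concatenated baseline.
"""

from __future__ import annotations

import json

import numpy as np

from .patterns import BinaryPattern

__all__ = ["ClippedWeightMatrix"]


class ClippedWeightMatrix:
    """A rows x cols matrix of binary synapses under clipped Hebbian learning.

    Weights only ever grow (monotone) and re-storing a pair is a no-op
    (idempotent).  A square matrix used autoassociatively stores a pattern
    against itself; self-connections (the diagonal) are learned by default,
    which is what makes full-cue recall of a stored pattern exact.
    """

    def __init__(self, rows: int, cols: int | None = None):
        if cols is None:
            cols = rows
        if rows < 1 or cols < 1:
            raise ValueError("matrix dimensions must be positive")
        self.w = np.zeros((rows, cols), dtype=np.uint8)

    @property
    def rows(self) -> int:
        return self.w.shape[0]

    @property
    def cols(self) -> int:
        return self.w.shape[1]

    @property
    def n_set(self) -> int:
        """Number of synapses currently at 1."""
        return int(self.w.sum())

    def copy(self) -> "ClippedWeightMatrix":
        out = ClippedWeightMatrix(self.rows, self.cols)
        out.w = self.w.copy()
        return out

    # -- learning -----------------------------------------------------
    def store_auto(
        self, a: BinaryPattern, include_diagonal: bool = True
    ) -> "ClippedWeightMatrix":
        """Autoassociative storage: set w_ij wherever a_i = a_j = 1."""
        if self.rows != self.cols:
            raise ValueError("store_auto requires a square matrix")
        if a.length != self.rows:
            raise ValueError(
                f"pattern length {a.length} != matrix size {self.rows}"
            )
        idx = a.active_indices
        self.w[np.ix_(idx, idx)] = 1
        if not include_diagonal:
            self.w[idx, idx] = 0
        return self

    def store_hetero(
        self, x: BinaryPattern, y: BinaryPattern
    ) -> "ClippedWeightMatrix":
        """Heteroassociative storage: set w_ij wherever x_i = y_j = 1."""
        if x.length != self.rows or y.length != self.cols:
            raise ValueError(
                f"pair shape ({x.length}, {y.length}) != matrix shape "
                f"({self.rows}, {self.cols})"
            )
        self.w[np.ix_(x.active_indices, y.active_indices)] = 1
        return self

    # -- recall -------------------------------------------------------
    def recall(self, cue: BinaryPattern) -> BinaryPattern:
        """One synchronous threshold pass.

        Output cell j fires iff sum_i w_ij cue_i >= theta with theta the
        number of active cue cells (a cell exactly at threshold fires).
        An all-zero cue returns an all-zero output: with theta = 0 the
        printed rule would fire every cell, and "no input, no recall" is
        the only behaviour consistent with the downstream use of recalled
        activity.
        """
        if cue.length != self.rows:
            raise ValueError(
                f"cue length {cue.length} != matrix rows {self.rows}"
            )
        theta = cue.n_active
        if theta == 0:
            return BinaryPattern.zeros(self.cols)
        sums = self.w.T @ cue.bits.astype(np.int64)
        return BinaryPattern((sums >= theta).astype(np.uint8))

    def dendritic_sums(self, cue: BinaryPattern) -> np.ndarray:
        """Per-output-cell dendritic sums for a cue (diagnostic view)."""
        if cue.length != self.rows:
            raise ValueError("cue length mismatch")
        return self.w.T @ cue.bits.astype(np.int64)

    # -- snapshots ----------------------------------------------------
    def to_text(self, path) -> None:
        """Write the matrix as rows of 0/1 characters."""
        with open(path, "w") as fh:
            for row in self.w:
                fh.write("".join("1" if b else "0" for b in row) + "\n")

    @classmethod
    def from_text(cls, path) -> "ClippedWeightMatrix":
        with open(path) as fh:
            rows = [line.strip() for line in fh if line.strip()]
        out = cls(len(rows), len(rows[0]))
        out.w = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
        return out

    def to_json_obj(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "w": ["".join("1" if b else "0" for b in row) for row in self.w],
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ClippedWeightMatrix":
        out = cls(obj["rows"], obj["cols"])
        out.w = np.array(
            [[int(c) for c in row] for row in obj["w"]], dtype=np.uint8
        )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_obj(), fh)

    @classmethod
    def from_json(cls, path) -> "ClippedWeightMatrix":
        with open(path) as fh:
            return cls.from_json_obj(json.load(fh))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClippedWeightMatrix):
            return NotImplemented
        return bool(np.array_equal(self.w, other.w))

    def __repr__(self) -> str:
        return (
            f"ClippedWeightMatrix({self.rows}x{self.cols}, "
            f"{self.n_set} synapses set)"
        )
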