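"""Comparison models: flat concatenated binding and the plain hetero model.

The *standard autoassociative* model stores each stimulus as a single
concatenated pattern [extero | intero] in one Willshaw network, so pattern
completion and valence prediction happen concurrently in one pass.  The
*simple heteroassociative* model is the full hippocampal model reduced to
its primary valence group (p = 1): completion happens before valence
prediction, but there is no interference-resolution machinery, so
conflicting valences are written straight over each other.
"""

from __future__ import annotations

import numpy as np

from .hippocampus import HippocampalModel, ModelConfig, TrialRecord
from .patterns import BinaryPattern, hamming_distance
from .willshaw import ClippedWeightMatrix

__all__ = ["StandardAutoassociativeModel", "simple_hetero_model"]


class StandardAutoassociativeModel:
    """One autoassociative network over the concatenated [extero | intero].

    Recall cues carry zeros in the interoceptive segment, and the firing
    threshold counts only the exteroceptive cue cells — the only reading
    under which full-cue recall of stored pairs is exact.  Valence
    prediction is the interoceptive segment of the completed pattern.
    """

    def __init__(self, config: ModelConfig | None = None, **kwargs):
        if config is None:
            config = ModelConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword fields, not both")
        self.config = config
        self.W = ClippedWeightMatrix(config.n + config.m)

    def _concat(self, a_e: BinaryPattern, a_i: BinaryPattern) -> BinaryPattern:
        return BinaryPattern(np.concatenate([a_e.bits, a_i.bits]))

    def store(self, a_e: BinaryPattern, a_i: BinaryPattern) -> None:
        if a_e.length != self.config.n or a_i.length != self.config.m:
            raise ValueError("pattern length mismatch")
        self.W.store_auto(self._concat(a_e, a_i))

    def recall(self, cue_e: BinaryPattern) -> tuple[BinaryPattern, BinaryPattern]:
        """Concurrent completion + prediction from an exteroceptive cue."""
        if cue_e.length != self.config.n:
            raise ValueError("cue length mismatch")
        full = self.W.recall(self._concat(cue_e, BinaryPattern.zeros(self.config.m)))
        return (
            BinaryPattern(full.bits[: self.config.n]),
            BinaryPattern(full.bits[self.config.n :]),
        )

    def process_trial(
        self,
        a_e: BinaryPattern,
        a_i: BinaryPattern,
        learning_enabled: bool = True,
        cue: BinaryPattern | None = None,
    ) -> TrialRecord:
        """Same trial protocol as the hippocampal model, on the flat store.

        Novelty gating uses the same two mismatch signals (completion HD
        vs e, prediction HD vs v); with clipped weights, novelty-gated
        storage is equivalent to store-once.
        """
        if cue is None:
            cue = a_e
        completed, predicted = self.recall(cue)
        completion_hd = hamming_distance(completed, a_e)
        prediction_hd = hamming_distance(predicted, a_i)
        extero_novel = completion_hd > self.config.e
        valence_error = prediction_hd > self.config.v
        learned = False
        if learning_enabled and (extero_novel or valence_error):
            self.store(a_e, a_i)
            learned = True
        return TrialRecord(
            completion_hd=completion_hd,
            prediction_hd=prediction_hd,
            extero_novel=extero_novel,
            valence_error=valence_error,
            interference_detected=False,
            learned=learned,
            group_used=None,
            capacity_exhausted=False,
        )

    def groups_in_use(self) -> int:
        """No associated valence groups exist in this model."""
        return 0

    def __repr__(self) -> str:
        return (
            f"StandardAutoassociativeModel(n={self.config.n}, "
            f"m={self.config.m}, {self.W.n_set} synapses set)"
        )


def simple_hetero_model(config: ModelConfig | None = None, **kwargs) -> HippocampalModel:
    """The proposed model stripped of its associated valence groups.

    Returns a :class:`HippocampalModel` with p = 1: completion precedes
    prediction, but a valence conflict is relearned directly into the
    primary group, so clipped weights accumulate contradictory
    associations that can never be unlearned.
    """
    if config is None:
        config = ModelConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword fields, not both")
    reduced = ModelConfig(
        n=config.n, m=config.m, n_assoc_groups=0, e=config.e, v=config.v
    )
    return HippocampalModel(reduced)
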