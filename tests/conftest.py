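import numpy as np
import pytest

from hippobind import BinaryPattern, make_valence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def feature_stimuli():
    """Four disjoint 4-cell features A-D on 16 cells, paired into stimuli.

    Returns a builder: stim("AB") gives the 8-active pattern A ∪ B.
    """
    feats = {name: list(range(4 * i, 4 * i + 4)) for i, name in enumerate("ABCD")}

    def stim(pair: str) -> BinaryPattern:
        return BinaryPattern.from_indices(16, feats[pair[0]] + feats[pair[1]])

    return stim


@pytest.fixture
def valences():
    return {lab: make_valence(lab) for lab in ("positive", "negative", "neutral")}
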