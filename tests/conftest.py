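import numpy as np
import pytest

from domhier.core import GroupComposition, InteractionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def toy_matrix():
    """A beats B 3-1; B beats C 1-0; A and C never met (A=male, B,C=female)."""
    counts = np.array([[0, 3, 0], [1, 0, 1], [0, 0, 0]])
    return InteractionMatrix(
        ids=["m1", "f1", "f2"], sexes=["male", "female", "female"], counts=counts
    )


@pytest.fixture
def comp_2m4f():
    return GroupComposition(2, 4)
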