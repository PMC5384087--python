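import numpy as np
import pytest

from pterodiv import simulate, trees


@pytest.fixture
def cherry():
    return trees.parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return trees.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_chronogram(rng: np.random.Generator, n_tips: int, lam: float = 0.3):
    """Seeded Yule chronogram used across property tests."""
    return simulate.simulate_yule_n_tips(n_tips, lam, rng)
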