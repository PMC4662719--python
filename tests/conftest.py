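import numpy as np
import pytest

from pathga import Compendium, GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_path_compendium():
    """Two overlapping length-3 paths a→b→c and b→c→d (as gene sets)."""
    return Compendium((GeneSet("p1", ("a", "b", "c")), GeneSet("p2", ("b", "c", "d"))))


@pytest.fixture
def three_set_compendium():
    """Three length-4 sets, enough room for crossover/mutation tests."""
    return Compendium(
        (
            GeneSet("p1", ("a", "b", "c", "d")),
            GeneSet("p2", ("a", "c", "b", "e")),
            GeneSet("p3", ("f", "b", "c", "d")),
        )
    )


def random_compendium(rng, m=4, max_len=5):
    """A small random compendium over a shared gene pool (overlapping sets)."""
    pool = [f"g{i}" for i in range(8)]
    sets = []
    for i in range(m):
        L = int(rng.integers(3, max_len + 1))
        genes = tuple(rng.choice(pool, size=L, replace=False))
        sets.append(GeneSet(f"p{i}", genes))
    return Compendium(tuple(sets))
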