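import numpy as np
import pytest

from focusct import FeatureUniverse, FocusFamily, table_oracles


@pytest.fixture
def toy_universe():
    return FeatureUniverse([1, 2, 3, 4])


@pytest.fixture
def toy_family(toy_universe):
    """Two overlapping focus sets F1={1,2}, F2={2,4} over W={1,2,3,4}."""
    return FocusFamily.from_id_sets(toy_universe, [[1, 2], [2, 4]])


@pytest.fixture
def toy_oracles(toy_family):
    """Tabulated partial bounds d1=1 on F1, d2=2 on F2 (level-independent)."""
    return table_oracles(toy_family, {0: 1, 1: 2})


@pytest.fixture
def toy_bounds():
    return (1, 2)


# The worked four-feature example: columns of the trivial procedure d(0),
# one interpolation round d(1), and the coherent fixpoint d(2), keyed by
# external feature ids.
TOY_TABLE = {
    (): (0, 0, 0),
    (1,): (0, 0, 0),
    (2,): (0, 1, 1),
    (3,): (0, 0, 0),
    (4,): (0, 1, 1),
    (1, 2): (1, 1, 1),
    (1, 3): (0, 0, 0),
    (1, 4): (0, 1, 1),
    (2, 3): (0, 1, 1),
    (2, 4): (2, 2, 2),
    (3, 4): (0, 1, 1),
    (1, 2, 3): (0, 1, 1),
    (1, 2, 4): (0, 2, 2),
    (1, 3, 4): (0, 1, 1),
    (2, 3, 4): (0, 2, 2),
    (1, 2, 3, 4): (0, 2, 2),
}


@pytest.fixture
def toy_table():
    return TOY_TABLE


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)
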