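import numpy as np
import pytest

from rqlnet.engine import SatisfactionMatrix
from rqlnet.synthetic import toy_database
from rqlnet.synthetic import TOY_QUERY


@pytest.fixture(scope="session")
def toy():
    """The six-sample, three-table heterogeneous database."""
    return toy_database(seed=0)


@pytest.fixture(scope="session")
def toy_query_text():
    return TOY_QUERY


@pytest.fixture
def ac_matrix():
    """Hand-countable matrix: A true in 3 of 6 units, C in the first 2."""
    return SatisfactionMatrix.from_columns({
        "A": [1, 1, 1, 0, 0, 0],
        "C": [1, 1, 0, 0, 0, 0],
    })


@pytest.fixture
def indep_matrix():
    """Exactly independent pair: count(XY)/N = (count X/N)(count Y/N)."""
    return SatisfactionMatrix.from_columns({
        "X": [1, 1, 0, 0],
        "Y": [1, 0, 1, 0],
    })


def random_bool_matrix(rng: np.random.Generator, max_cols=10, max_units=12,
                       p_missing=0.0) -> SatisfactionMatrix:
    """Small random satisfaction matrix (optionally with missing cells)."""
    n_cols = int(rng.integers(2, max_cols + 1))
    n_units = int(rng.integers(3, max_units + 1))
    cols = {}
    for j in range(n_cols):
        vals = (rng.random(n_units) < 0.5).astype(int).tolist()
        if p_missing:
            vals = [None if rng.random() < p_missing else v for v in vals]
        cols[f"c{j}"] = vals
    return SatisfactionMatrix.from_columns(cols)
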