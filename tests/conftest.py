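import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from paleonull import IncidenceMatrix, titanosaur_fixtures

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_matrix():
    return titanosaur_fixtures()[0]


@pytest.fixture(scope="session")
def fixture_sizes():
    return titanosaur_fixtures()[1]


def brute_force_cscore(matrix: IncidenceMatrix):
    """Independent pair-enumeration oracle: recompute shared sites from columns.

    Returns (sum of CU as exact int, number of pairs, pairs with CU > 0).
    Deliberately naive — double loop over pairs, shared-site count from an
    explicit column scan — so it shares no code path with the implementation.
    """
    rows = matrix.cells.tolist()
    total = 0
    n_pairs = 0
    n_checker = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            s = sum(1 for a, b in zip(rows[i], rows[j]) if a == 1 and b == 1)
            ri = sum(rows[i])
            rj = sum(rows[j])
            cu = (ri - s) * (rj - s)
            total += cu
            n_pairs += 1
            n_checker += cu > 0
    return total, n_pairs, n_checker


@st.composite
def incidence_matrices(draw, min_side=2, max_side=8):
    n = draw(st.integers(min_side, max_side))
    m = draw(st.integers(min_side, max_side))
    cells = draw(
        st.lists(
            st.lists(st.integers(0, 1), min_size=m, max_size=m),
            min_size=n,
            max_size=n,
        )
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # generated matrices may have empty rows
        return IncidenceMatrix(
            [f"sp{i}" for i in range(n)], [f"site{j}" for j in range(m)], np.array(cells)
        )
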