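"""C-score, checkerboard units, and the sequential-swap null model."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import brute_force_cscore, incidence_matrices
from paleonull import (
    IncidenceMatrix,
    NullModelResult,
    c_score,
    checkerboard_pair_count,
    checkerboard_units,
    make_nested,
    null_model_cscore,
    pair_cooccurrences,
    sequential_swap_step,
)


class TestCheckerboardUnits:
    @pytest.mark.parametrize("ri,rj,s,expected", [(4, 3, 2, 2), (4, 4, 2, 4), (3, 5, 0, 15)])
    def test_formula(self, ri, rj, s, expected):
        assert checkerboard_units(ri, rj, s) == expected

    @pytest.mark.parametrize("s", [3, 4])
    def test_zero_when_one_range_is_contained(self, s):
        assert checkerboard_units(s, 6, s) == 0

    def test_shared_count_cannot_exceed_row_totals(self):
        with pytest.raises(ValueError):
            checkerboard_units(2, 5, 3)

    def test_fixture_pair_antarctosaurus_neuquensaurus(self, fixture_matrix):
        # both occupy 4 formations and share Anacleto + Palacio, so CU = 2*2
        pairs = {
            frozenset((p.species_i, p.species_j)): p
            for p in pair_cooccurrences(fixture_matrix)
        }
        p = pairs[frozenset(("Antarctosaurus wichmannianus", "Neuquensaurus australis"))]
        assert (p.r_i, p.r_j, p.s, p.cu) == (4, 4, 2, 4)


class TestCScore:
    def test_two_exclusive_species_score_one(self):
        m = IncidenceMatrix(["a", "b"], ["x", "y"], [[1, 0], [0, 1]])
        assert c_score(m) == 1.0
        assert checkerboard_pair_count(m) == 1

    def test_identical_ranges_score_zero(self):
        m = IncidenceMatrix(["a", "b"], ["x", "y", "z"], [[1, 1, 0], [1, 1, 0]])
        assert c_score(m) == 0.0
        assert checkerboard_pair_count(m) == 0

    def test_single_species_is_an_error(self):
        with pytest.warns(UserWarning, match="all-zero"):
            m = IncidenceMatrix(["a", "b"], ["x", "y"], [[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="at least 2 species"):
            c_score(m)  # the all-zero row is dropped, leaving one species

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n, m = rng.integers(2, 9, size=2)
            cells = (rng.random((n, m)) < rng.uniform(0.2, 0.8)).astype(int)
            mat = IncidenceMatrix(
                [f"sp{i}" for i in range(n)], [f"site{j}" for j in range(m)], cells
            )
            total, n_pairs, n_checker = brute_force_cscore(mat)
            assert c_score(mat, drop_empty=False) == pytest.approx(total / n_pairs)
            assert checkerboard_pair_count(mat, drop_empty=False) == n_checker

    @given(incidence_matrices(), st.integers(0, 2**31 - 1))
    def test_invariant_under_row_and_column_permutation(self, m, seed):
        rng = np.random.default_rng(seed)
        ri = rng.permutation(m.n_species)
        ci = rng.permutation(m.n_sites)
        perm = IncidenceMatrix(
            [m.species_names[i] for i in ri],
            [m.site_names[j] for j in ci],
            m.cells[np.ix_(ri, ci)],
        )
        assert c_score(perm, drop_empty=False) == pytest.approx(
            c_score(m, drop_empty=False)
        )


class TestSequentialSwap:
    def test_two_by_two_checkerboard_alternates(self):
        rng = np.random.default_rng(0)
        m = IncidenceMatrix(["a", "b"], ["x", "y"], [[1, 0], [0, 1]])
        states = set()
        for _ in range(6):
            m, swapped = sequential_swap_step(m, rng)
            assert swapped  # the only selectable submatrix is a checkerboard
            states.add(tuple(m.cells.ravel().tolist()))
        assert states == {(1, 0, 0, 1), (0, 1, 1, 0)}

    def test_full_matrix_has_nothing_to_swap(self):
        rng = np.random.default_rng(1)
        m = IncidenceMatrix(["a", "b"], ["x", "y"], [[1, 1], [1, 1]])
        out, swapped = sequential_swap_step(m, rng)
        assert not swapped
        assert out == m

    @given(incidence_matrices(), st.integers(0, 2**31 - 1))
    def test_margins_conserved_after_any_number_of_steps(self, m, seed):
        rng = np.random.default_rng(seed)
        before = m.margins()
        for _ in range(20):
            m, _ = sequential_swap_step(m, rng)
        assert m.margins() == before


class TestNullModel:
    def test_add_one_tail_probability(self):
        # observed strictly above 999 null draws -> p_upper = 1/1000
        res = NullModelResult.from_samples("stat", 5.0, np.linspace(0, 4, 999))
        assert res.p_upper == pytest.approx(0.001)
        assert res.p_lower == pytest.approx(1.0)

    def test_ties_count_toward_both_tails(self):
        res = NullModelResult.from_samples("stat", 1.0, np.ones(9))
        assert res.p_upper == 1.0
        assert res.p_lower == 1.0

    def test_ses_sign_matches_deviation(self):
        res = NullModelResult.from_samples("stat", 10.0, np.array([1.0, 2.0, 3.0]))
        assert res.ses > 0

    def test_fixed_seed_reproducible(self, fixture_matrix):
        r1 = null_model_cscore(fixture_matrix, iterations=200, burn_in=1000, seed=9)
        r2 = null_model_cscore(fixture_matrix, iterations=200, burn_in=1000, seed=9)
        assert np.array_equal(r1.null_values, r2.null_values)
        assert r1.observed == r2.observed

    def test_observed_statistic_matches_direct_computation(self, fixture_matrix):
        res = null_model_cscore(fixture_matrix, iterations=50, burn_in=500, seed=0)
        assert res.observed == pytest.approx(c_score(fixture_matrix))

    def test_nested_matrix_is_degenerate(self):
        res = null_model_cscore(make_nested(4, 6), iterations=100, burn_in=100, seed=0)
        assert res.degenerate
        assert res.null_sd == 0.0
        assert np.isnan(res.ses)

    def test_thinning_and_iteration_counts_are_recorded(self, fixture_matrix):
        res = null_model_cscore(
            fixture_matrix, iterations=60, burn_in=200, thin=3, seed=2
        )
        assert res.iterations == len(res.null_values) == 60
        assert (res.burn_in, res.thin) == (200, 3)
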