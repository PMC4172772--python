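"""Ground-truth generators: structure, determinism, and tally recovery."""

import numpy as np
import pytest

from paleonull import (
    ScenarioSpec,
    c_score,
    chao1_estimate,
    checkerboard_pair_count,
    generate_scenario,
    make_abundances,
    make_checkerboard,
    make_nested,
    make_random_margins,
    make_sizes,
    pair_cooccurrences,
    segment_profile,
    synthetic_titanosaur_sizes,
    tally_frequencies,
    titanosaur_fixtures,
)
from paleonull.data_model import ValidationError


class TestCheckerboardGenerator:
    def test_single_pair_single_site_is_the_identity_pattern(self):
        m = make_checkerboard(1, 1)
        assert sorted(map(tuple, m.cells.tolist())) == [(0, 1), (1, 0)]
        assert c_score(m) == 1.0

    def test_within_pair_cu_is_squared_block_size(self):
        m = make_checkerboard(2, 2)
        pairs = {
            frozenset((p.species_i, p.species_j)): p.cu for p in pair_cooccurrences(m)
        }
        assert pairs[frozenset(("sp01", "sp02"))] == 4
        assert pairs[frozenset(("sp03", "sp04"))] == 4

    def test_every_species_occupies_the_block_size(self):
        m = make_checkerboard(3, 4)
        assert (m.margins().row_totals == 4).all()


class TestNestedGenerator:
    def test_perfect_nesting_has_no_checkerboards(self):
        m = make_nested(5, 9)
        assert c_score(m) == 0.0
        assert checkerboard_pair_count(m) == 0

    def test_row_totals_non_increasing(self):
        m = make_nested(6, 10)
        assert (np.diff(m.margins().row_totals) <= 0).all()


class TestRandomMargins:
    def test_zero_swaps_returns_the_template(self, fixture_matrix):
        assert make_random_margins(fixture_matrix, 0) == fixture_matrix

    def test_swaps_conserve_margins(self, fixture_matrix):
        shuffled = make_random_margins(fixture_matrix, 20_000, seed=3)
        assert shuffled.margins() == fixture_matrix.margins()
        assert shuffled != fixture_matrix  # 20k swaps virtually never return home

    def test_pinned_template_is_rejected(self):
        with pytest.raises(ValueError, match="no swappable"):
            make_random_margins(make_nested(4, 6), 10, seed=0)


class TestAbundanceGenerator:
    def test_exact_tally_recovery(self):
        a = make_abundances(23, 10, 5, seed=0)
        assert tally_frequencies(a) == (23, 10, 5)

    def test_all_singletons_exercises_the_fallback(self):
        a = make_abundances(7, 7, 0, seed=1)
        est = chao1_estimate(a)
        assert est.bias_corrected
        assert est.chao1 == 7 + 7 * 6 / 2

    def test_deterministic_under_seed(self):
        a = make_abundances(15, 4, 3, seed=9)
        b = make_abundances(15, 4, 3, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_infeasible_targets_rejected(self):
        with pytest.raises(ValueError):
            make_abundances(5, 4, 2)


class TestSizeGenerator:
    def test_even_log_segments_are_exactly_equal(self):
        sizes = make_sizes(4, "even_log", range_m=(8.0, 30.0))
        prof = segment_profile(sizes)
        assert prof.segments == pytest.approx([0.1913437559092396] * 3)
        assert prof.variance_segments == pytest.approx(0.0, abs=1e-25)

    def test_clustered_is_tighter_and_more_uneven_than_even(self):
        even = segment_profile(make_sizes(12, "even_log", seed=0))
        clus = segment_profile(make_sizes(12, "clustered", seed=0))
        assert clus.min_segment < even.min_segment
        assert clus.variance_segments > even.variance_segments

    def test_sizes_respect_range_and_seed(self):
        a = make_sizes(9, "uniform", range_m=(5.0, 40.0), seed=2)
        b = make_sizes(9, "uniform", range_m=(5.0, 40.0), seed=2)
        assert np.array_equal(a.lengths_m, b.lengths_m)
        assert a.lengths_m.min() >= 5.0 and a.lengths_m.max() <= 40.0


class TestScenarios:
    def test_structure_ordering_of_c_scores(self):
        # segregation maximizes, nesting annihilates; margin-shuffled noise
        # sits between, across several seeds on matched dimensions
        for seed in range(3):
            seg = make_checkerboard(5, 5, seed=seed)  # 10 species x 10 sites
            shuffled = make_random_margins(seg, 5_000, seed=seed)
            nested = make_nested(10, 10, seed=seed)
            assert c_score(seg) > c_score(shuffled) > c_score(nested) == 0.0

    def test_generate_scenario_emits_valid_consistent_objects(self):
        spec = ScenarioSpec(n_species=12, n_sites=10, f1=4, f2=2, seed=5)
        matrix, abundances, sizes = generate_scenario(spec)
        assert matrix.n_species == abundances.n_species == sizes.n_species == 12
        assert tally_frequencies(abundances) == (12, 4, 2)
        m2, a2, s2 = generate_scenario(spec)
        assert m2 == matrix
        assert np.array_equal(a2.counts, abundances.counts)
        assert np.array_equal(s2.lengths_m, sizes.lengths_m)

    def test_scenario_validation(self):
        with pytest.raises(ValidationError):
            ScenarioSpec(fill=1.5)
        with pytest.raises(ValidationError):
            ScenarioSpec(size_range_m=(30.0, 8.0))


class TestSyntheticStandInSizes:
    def test_keeps_published_extremes_and_fills_the_rest(self):
        stand_in = synthetic_titanosaur_sizes()
        _, fixture = titanosaur_fixtures()
        assert stand_in.n_known == 23
        assert stand_in.lengths_m.min() == 8.0
        assert stand_in.lengths_m.max() == 30.0
        known = ~np.isnan(fixture.lengths_m)
        assert np.array_equal(stand_in.lengths_m[known], fixture.lengths_m[known])

    def test_deterministic(self):
        assert np.array_equal(
            synthetic_titanosaur_sizes().lengths_m, synthetic_titanosaur_sizes().lengths_m
        )
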