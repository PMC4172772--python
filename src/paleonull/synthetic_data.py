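"""Generators for assemblage test beds with known ground-truth structure.

Everything the analysis pipeline consumes — incidence matrices with
controllable segregation or nesting, abundance vectors with chosen
singleton/doubleton tallies, body-size spectra with chosen log-scale
spacing — can be generated here deterministically from a seed, so each
statistical routine can be exercised against constructions whose correct
answer is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cooccurrence import _attempt_stream, _has_swappable_submatrix, _try_swap
from .data_model import AbundanceVector, BodySizeTable, IncidenceMatrix, ValidationError

__all__ = [
    "ScenarioSpec",
    "make_checkerboard",
    "make_nested",
    "make_random_margins",
    "make_abundances",
    "make_sizes",
    "generate_scenario",
    "synthetic_titanosaur_sizes",
]


def _species_labels(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def _site_labels(n: int) -> list[str]:
    return [f"site{i + 1:02d}" for i in range(n)]


def make_checkerboard(
    n_pairs: int, sites_per_species: int = 1, seed: int | None = None
) -> IncidenceMatrix:
    """Maximally segregated assemblage of ``2 * n_pairs`` species.

    Sites form two disjoint blocks of ``sites_per_species`` columns; the
    even member of every species pair fills the first block and the odd
    member the second, so each within-pair CU equals
    ``sites_per_species ** 2`` and no pair of opposite-block species ever
    co-occurs.  The seed only shuffles the species order (cosmetic; all
    pair statistics are order-invariant).
    """
    if n_pairs < 1 or sites_per_species < 1:
        raise ValueError("n_pairs and sites_per_species must be >= 1")
    k = sites_per_species
    cells = np.zeros((2 * n_pairs, 2 * k), dtype=np.int8)
    cells[0::2, :k] = 1
    cells[1::2, k:] = 1
    order = np.arange(2 * n_pairs)
    if seed is not None:
        np.random.default_rng(seed).shuffle(order)
    labels = _species_labels(2 * n_pairs)
    return IncidenceMatrix([labels[i] for i in order], _site_labels(2 * k), cells[order])


def make_nested(n_species: int, n_sites: int, seed: int | None = None) -> IncidenceMatrix:
    """Perfectly nested assemblage: each species' range contains the next's.

    Row i occupies the first k_i sites with k_i decreasing linearly from
    ``n_sites`` to 1, so every pair shares min(r_i, r_j) sites, every CU is
    zero and the C-score is exactly 0.  The seed is accepted for interface
    uniformity but unused (the construction is deterministic).
    """
    if n_species < 2 or n_species > n_sites:
        raise ValueError("need 2 <= n_species <= n_sites")
    cells = np.zeros((n_species, n_sites), dtype=np.int8)
    for i in range(n_species):
        k_i = round(n_sites - i * (n_sites - 1) / (n_species - 1))
        cells[i, :k_i] = 1
    return IncidenceMatrix(_species_labels(n_species), _site_labels(n_sites), cells)


def make_random_margins(
    template: IncidenceMatrix, n_swaps: int, seed: int | None = None
) -> IncidenceMatrix:
    """Margin-preserving randomization of ``template`` by successful swaps.

    Applies exactly ``n_swaps`` successful sequential swaps to a copy of
    the template; row and column totals are conserved by construction.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    out = template.copy()
    if n_swaps == 0:
        return out
    if not _has_swappable_submatrix(out.cells):
        raise ValueError("template has no swappable submatrix; margins pin it uniquely")
    rng = np.random.default_rng(seed)
    attempts = _attempt_stream(out.shape, rng)
    done = 0
    while done < n_swaps:
        if _try_swap(out.cells, *next(attempts)):
            done += 1
    return out


def make_abundances(
    sobs: int, f1: int, f2: int, seed: int | None = None, tail_mean: float = 5.0
) -> AbundanceVector:
    """Abundance vector with exact singleton and doubleton tallies.

    ``f1`` species get count 1, ``f2`` get count 2, and the remaining
    species get counts >= 3 from a shifted geometric with the given mean.
    Only (f1, f2) matter to Chao1; the tail shape is cosmetic.
    """
    if sobs < 1 or f1 < 0 or f2 < 0 or f1 + f2 > sobs:
        raise ValueError("need sobs >= 1 and f1 + f2 <= sobs")
    if tail_mean <= 3:
        raise ValueError("tail_mean must exceed 3 (tail counts start at 3)")
    rng = np.random.default_rng(seed)
    n_tail = sobs - f1 - f2
    # counts = 3 + (G - 1), G geometric with mean 1/p  =>  mean = 2 + 1/p
    tail = 2 + rng.geometric(1 / (tail_mean - 2), size=n_tail)
    counts = np.concatenate([np.ones(f1, dtype=int), np.full(f2, 2), tail])
    rng.shuffle(counts)
    return AbundanceVector(_species_labels(sobs), counts)


def make_sizes(
    n: int,
    pattern: str = "uniform",
    range_m: tuple[float, float] = (8.0, 30.0),
    seed: int | None = None,
) -> BodySizeTable:
    """Body-size spectrum with controlled log-scale spacing.

    Patterns: ``even_log`` — exactly geometric between the range endpoints
    (zero variance of log segments); ``uniform`` — log sizes uniform over
    the range; ``clustered`` — two tight Gaussian clumps (s.d. 2% of the
    log-range) at the endpoints, giving near-zero minimum segments.
    """
    lo, hi = range_m
    if n < 3:
        raise ValueError("need at least 3 species")
    if not 0 < lo < hi:
        raise ValueError("size range must satisfy 0 < min < max")
    rng = np.random.default_rng(seed)
    llo, lhi = np.log10(lo), np.log10(hi)
    if pattern == "even_log":
        logs = np.linspace(llo, lhi, n)
    elif pattern == "uniform":
        logs = rng.uniform(llo, lhi, size=n)
    elif pattern == "clustered":
        sd = 0.02 * (lhi - llo)
        centers = np.where(np.arange(n) < n // 2, llo, lhi)
        logs = np.clip(rng.normal(centers, sd), llo, lhi)
    else:
        raise ValueError(f"unknown size pattern {pattern!r}")
    return BodySizeTable(_species_labels(n), 10.0**logs)


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete recipe for one synthetic assemblage test bed."""

    n_species: int = 20
    n_sites: int = 14
    structure: str = "random_margins"  # segregated | nested | random_margins
    fill: float = 0.15
    f1: int = 6
    f2: int = 3
    size_pattern: str = "uniform"
    size_range_m: tuple[float, float] = (8.0, 30.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fill < 1:
            raise ValidationError("fill must be in (0, 1)")
        if self.n_species < 2:
            raise ValidationError("need at least 2 species")
        lo, hi = self.size_range_m
        if not 0 < lo < hi:
            raise ValidationError("size range must satisfy 0 < min < max")
        if self.f1 + self.f2 > self.n_species:
            raise ValidationError("f1 + f2 cannot exceed n_species")


def _random_fill_matrix(spec: ScenarioSpec, rng: np.random.Generator) -> IncidenceMatrix:
    cells = (rng.random((spec.n_species, spec.n_sites)) < spec.fill).astype(np.int8)
    # no empty species/sites: each gets at least one record
    for i in np.flatnonzero(cells.sum(axis=1) == 0):
        cells[i, rng.integers(spec.n_sites)] = 1
    for j in np.flatnonzero(cells.sum(axis=0) == 0):
        cells[rng.integers(spec.n_species), j] = 1
    return IncidenceMatrix(_species_labels(spec.n_species), _site_labels(spec.n_sites), cells)


def generate_scenario(
    spec: ScenarioSpec,
) -> tuple[IncidenceMatrix, AbundanceVector, BodySizeTable]:
    """Materialize a scenario: incidence matrix, abundances, and sizes.

    ``fill`` applies to the random_margins structure; the segregated and
    nested constructions determine their own fill from the dimensions.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_mat, s_ab, s_sz = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    if spec.structure == "segregated":
        if spec.n_species % 2:
            raise ValidationError("segregated structure needs an even species count")
        matrix = make_checkerboard(spec.n_species // 2, max(1, spec.n_sites // 2), seed=s_mat)
    elif spec.structure == "nested":
        matrix = make_nested(spec.n_species, max(spec.n_sites, spec.n_species), seed=s_mat)
    elif spec.structure == "random_margins":
        matrix = _random_fill_matrix(spec, np.random.default_rng(s_mat))
    else:
        raise ValidationError(f"unknown structure {spec.structure!r}")
    abundances = make_abundances(spec.n_species, spec.f1, spec.f2, seed=s_ab)
    sizes = make_sizes(spec.n_species, spec.size_pattern, spec.size_range_m, seed=s_sz)
    return matrix, abundances, sizes


def synthetic_titanosaur_sizes(seed: int = 20140923) -> BodySizeTable:
    """Synthetic stand-in body-size table for the titanosaur assemblage.

    The published record fixes only the two extremes of the size spectrum
    (8 m and 30 m); the per-species lengths of the other 21 species are
    not in the packaged data.  This stand-in keeps the two published
    values and fills every missing species with a log-uniform draw between
    the extremes — a synthetic completion that lets the size-overlap
    pipeline run end to end.  It carries no information about the real
    species' sizes and is flagged as synthetic in the analysis provenance.
    """
    from .data_model import titanosaur_fixtures

    _, sizes = titanosaur_fixtures()
    rng = np.random.default_rng(seed)
    lengths = sizes.lengths_m.copy()
    missing = np.isnan(lengths)
    lengths[missing] = 10.0 ** rng.uniform(np.log10(8.0), np.log10(30.0), size=missing.sum())
    return BodySizeTable(sizes.species_names, lengths)
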