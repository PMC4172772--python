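"""C-score co-occurrence analysis under the fixed-fixed sequential-swap null.

For a pair of species occupying r_i and r_j sites with S sites in common,
the number of checkerboard units is

    CU = (r_i - S) (r_j - S),

the count of mutually exclusive site pairs the two species form.  The
C-score is the mean CU over all R(R-1)/2 unordered species pairs; large
values indicate spatial segregation.

Significance is assessed against the fixed-fixed null: binary matrices
with exactly the observed row totals (occurrences per species) and column
totals (richness per site), sampled by the sequential-swap Markov chain
that repeatedly flips randomly chosen 2x2 checkerboard submatrices.  Each
recorded null matrix is separated from the previous one by a configurable
number of successful swaps (``thin``), after an initial burn-in of
attempted swaps, mirroring the sequential-swap behavior of classic
co-occurrence software.  Tail probabilities use the add-one correction
p = (1 + #{null >= observed}) / (1 + iterations), counting the observed
matrix as one realization of the null; ties count toward the tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .data_model import IncidenceMatrix

__all__ = [
    "PairCooccurrence",
    "NullModelResult",
    "checkerboard_units",
    "pair_cooccurrences",
    "c_score",
    "checkerboard_pair_count",
    "sequential_swap_step",
    "null_model_cscore",
]


def checkerboard_units(r_i: int, r_j: int, s: int) -> int:
    """Checkerboard units (r_i - s)(r_j - s) for one species pair.

    ``s`` is the number of sites occupied by both species and can never
    exceed either row total.
    """
    if s > min(r_i, r_j) or s < 0:
        raise ValueError(f"shared-site count s={s} exceeds a row total ({r_i}, {r_j})")
    return (r_i - s) * (r_j - s)


@dataclass(frozen=True)
class PairCooccurrence:
    """CU bookkeeping for a single unordered species pair."""

    species_i: str
    species_j: str
    r_i: int
    r_j: int
    s: int
    cu: int


@dataclass(frozen=True)
class NullModelResult:
    """Observed statistic with its Monte Carlo null distribution.

    ``ses`` is the standardized effect size (observed - null mean) / null
    standard deviation, NaN when the null is degenerate (zero spread).
    ``p_upper``/``p_lower`` use the add-one correction and therefore lie
    in (0, 1].
    """

    statistic_name: str
    observed: float
    null_values: np.ndarray
    null_mean: float
    null_sd: float
    ses: float
    p_upper: float
    p_lower: float
    iterations: int
    burn_in: int
    thin: int
    seed: int | None
    degenerate: bool = False
    notes: tuple[str, ...] = ()

    @classmethod
    def from_samples(
        cls,
        statistic_name: str,
        observed: float,
        null_values: np.ndarray,
        *,
        burn_in: int = 0,
        thin: int = 1,
        seed: int | None = None,
        degenerate: bool = False,
        notes: tuple[str, ...] = (),
    ) -> "NullModelResult":
        null_values = np.asarray(null_values, dtype=float)
        iterations = null_values.size
        mean = float(null_values.mean())
        sd = float(null_values.std(ddof=1)) if iterations > 1 else 0.0
        ses = (observed - mean) / sd if sd > 0 else float("nan")
        p_upper = (1 + int((null_values >= observed).sum())) / (1 + iterations)
        p_lower = (1 + int((null_values <= observed).sum())) / (1 + iterations)
        return cls(
            statistic_name=statistic_name,
            observed=float(observed),
            null_values=null_values,
            null_mean=mean,
            null_sd=sd,
            ses=ses,
            p_upper=p_upper,
            p_lower=p_lower,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            degenerate=degenerate,
            notes=notes,
        )

    def summary(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": self.ses,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "iterations": self.iterations,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "notes": list(self.notes),
        }


# ---------------------------------------------------------------------------
# Observed statistics
# ---------------------------------------------------------------------------

def _prepare(m: IncidenceMatrix, drop_empty: bool) -> IncidenceMatrix:
    if drop_empty:
        m = m.drop_empty()
    if m.n_species < 2:
        raise ValueError("co-occurrence analysis needs at least 2 species")
    return m


def _cu_matrix(a: np.ndarray) -> np.ndarray:
    """Pairwise CU values; entry (i, j) for rows i and j of the 0/1 array."""
    a = a.astype(np.int64, copy=False)
    shared = a @ a.T
    r = a.sum(axis=1)
    return (r[:, None] - shared) * (r[None, :] - shared)


def _cscore_from_array(a: np.ndarray) -> float:
    cu = _cu_matrix(a)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(cu[iu].mean())


def pair_cooccurrences(m: IncidenceMatrix, drop_empty: bool = True) -> list[PairCooccurrence]:
    """CU for every unordered species pair."""
    m = _prepare(m, drop_empty)
    a = m.cells.astype(np.int64)
    shared = a @ a.T
    r = a.sum(axis=1)
    out = []
    for i in range(m.n_species):
        for j in range(i + 1, m.n_species):
            s = int(shared[i, j])
            out.append(
                PairCooccurrence(
                    m.species_names[i],
                    m.species_names[j],
                    int(r[i]),
                    int(r[j]),
                    s,
                    checkerboard_units(int(r[i]), int(r[j]), s),
                )
            )
    return out


def c_score(m: IncidenceMatrix, drop_empty: bool = True) -> float:
    """Mean checkerboard units over all unordered species pairs."""
    m = _prepare(m, drop_empty)
    return _cscore_from_array(m.cells)


def checkerboard_pair_count(m: IncidenceMatrix, drop_empty: bool = True) -> int:
    """Number of unordered species pairs with at least one checkerboard unit."""
    m = _prepare(m, drop_empty)
    cu = _cu_matrix(m.cells)
    iu = np.triu_indices(m.n_species, k=1)
    return int((cu[iu] > 0).sum())


# ---------------------------------------------------------------------------
# Sequential swap chain
# ---------------------------------------------------------------------------

_BATCH = 4096


def _attempt_stream(shape: tuple[int, int], rng: np.random.Generator) -> Iterator[tuple[int, int, int, int]]:
    """Endless stream of uniformly chosen (row, row, col, col) quadruples.

    Rows and columns within a quadruple are distinct; draws are batched for
    speed but consumed one attempt at a time.
    """
    n, m = shape
    while True:
        i = rng.integers(0, n, size=_BATCH)
        j = rng.integers(0, n - 1, size=_BATCH)
        j = j + (j >= i)
        k = rng.integers(0, m, size=_BATCH)
        l = rng.integers(0, m - 1, size=_BATCH)
        l = l + (l >= k)
        yield from zip(i.tolist(), j.tolist(), k.tolist(), l.tolist())


def _try_swap(a: np.ndarray, i: int, j: int, k: int, l: int) -> bool:
    """Flip the 2x2 submatrix (i,j)x(k,l) if it is a checkerboard."""
    aik = a[i, k]
    ail = a[i, l]
    if aik == ail:
        return False
    if a[j, k] == ail and a[j, l] == aik:
        a[i, k] = ail
        a[i, l] = aik
        a[j, k] = aik
        a[j, l] = ail
        return True
    return False


def sequential_swap_step(
    m: IncidenceMatrix, rng: np.random.Generator
) -> tuple[IncidenceMatrix, bool]:
    """One attempted sequential swap on a copy of ``m``.

    Picks two distinct rows and two distinct columns uniformly at random;
    if the selected 2x2 submatrix is a checkerboard (diagonal of 1s against
    a diagonal of 0s, in either orientation) it is flipped.  Row and column
    totals are conserved in every case.
    """
    out = m.copy()
    n, cols = out.shape
    i = int(rng.integers(0, n))
    j = int(rng.integers(0, n - 1))
    j += j >= i
    k = int(rng.integers(0, cols))
    l = int(rng.integers(0, cols - 1))
    l += l >= k
    swapped = _try_swap(out.cells, i, j, k, l)
    return out, swapped


def _has_swappable_submatrix(a: np.ndarray) -> bool:
    # A swap exists iff some row pair shares fewer sites than either occupies
    # (neither support contains the other).
    a = a.astype(np.int64, copy=False)
    shared = a @ a.T
    r = a.sum(axis=1)
    ok = (shared < r[:, None]) & (shared < r[None, :])
    np.fill_diagonal(ok, False)
    return bool(ok.any())


def null_model_cscore(
    m: IncidenceMatrix,
    iterations: int = 10_000,
    burn_in: int = 30_000,
    thin: int = 1,
    seed: int | None = None,
    drop_empty: bool = True,
) -> NullModelResult:
    """Fixed-fixed sequential-swap null-model test of the C-score.

    After ``burn_in`` attempted swaps, the C-score of the current matrix is
    recorded once per ``thin`` successful swaps, ``iterations`` times.
    Deterministic for a fixed seed.  A matrix with no swappable 2x2
    submatrix (e.g. perfectly nested) cannot be randomized: the result is
    flagged degenerate with zero null spread and undefined SES.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if burn_in < 0 or thin < 1:
        raise ValueError("burn_in must be >= 0 and thin >= 1")
    m = _prepare(m, drop_empty)
    observed = _cscore_from_array(m.cells)
    a = m.cells.astype(np.int8).copy()
    if not _has_swappable_submatrix(a):
        return NullModelResult.from_samples(
            "c_score",
            observed,
            np.full(iterations, observed),
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            degenerate=True,
            notes=("matrix has no swappable submatrix; null distribution is a point mass",),
        )
    rng = np.random.default_rng(seed)
    attempts = _attempt_stream(a.shape, rng)
    for _ in range(burn_in):
        _try_swap(a, *next(attempts))
    null_values = np.empty(iterations)
    for it in range(iterations):
        successes = 0
        while successes < thin:
            if _try_swap(a, *next(attempts)):
                successes += 1
        null_values[it] = _cscore_from_array(a)
    return NullModelResult.from_samples(
        "c_score",
        observed,
        null_values,
        burn_in=burn_in,
        thin=thin,
        seed=seed,
    )
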