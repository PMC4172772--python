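"""Nonparametric species-richness estimation from abundance data.

Implements the Chao1 estimator

    S_chao1 = S_obs + F1^2 / (2 F2)

where S_obs is the observed species count, F1 the number of singletons
(species with exactly one record) and F2 the number of doubletons.  When
F2 = 0 the classic ratio is undefined and the bias-corrected term
F1 (F1 - 1) / (2 (F2 + 1)) is used instead (flagged in the result).  The
confidence interval is the standard log-normal interval of Chao (1987),
which keeps the lower bound at or above S_obs's excess over zero and is
the interval reported by the EstimateS family of programs.

Randomized accumulation (rarefaction) curves pool individual fossil
records in random order and recompute S_obs and Chao1 at every sample
size, averaging over randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import AbundanceVector, ValidationError

__all__ = [
    "RichnessEstimate",
    "AccumulationCurve",
    "tally_frequencies",
    "chao1_estimate",
    "accumulation_curve",
]


@dataclass(frozen=True)
class RichnessEstimate:
    """Chao1 point estimate with log-normal confidence interval."""

    sobs: int
    f1: int
    f2: int
    chao1: float
    ci_low: float
    ci_high: float
    conf_level: float
    variance: float
    bias_corrected: bool  # True when the F2 = 0 fallback term was used

    def __post_init__(self) -> None:
        if self.chao1 < self.sobs - 1e-9:
            raise ValidationError("Chao1 estimate cannot fall below observed richness")
        if not (0 <= self.ci_low <= self.chao1 + 1e-9 <= self.ci_high + 1e-9):
            raise ValidationError("confidence interval must bracket the point estimate")


def tally_frequencies(a: AbundanceVector) -> tuple[int, int, int]:
    """Observed richness, singleton count and doubleton count."""
    counts = a.counts
    return int(counts.size), int((counts == 1).sum()), int((counts == 2).sum())


def _chao1_variance(sobs: int, f1: int, f2: int, chao1: float) -> float:
    # Chao (1987) asymptotic variance; separate form for the F2 = 0 case.
    if f1 == 0:
        return 0.0
    if f2 > 0:
        g = f1 / f2
        return f2 * (g**2 / 2 + g**3 + g**4 / 4)
    return f1 * (f1 - 1) / 2 + f1 * (2 * f1 - 1) ** 2 / 4 - f1**4 / (4 * chao1)


def chao1_estimate(a: AbundanceVector, conf_level: float = 0.95) -> RichnessEstimate:
    """Chao1 richness estimate with a log-normal confidence interval.

    With T = chao1 - sobs, G = f1/f2 and z the two-sided normal quantile,
    K = exp(z * sqrt(ln(1 + var/T^2))) and the interval is
    [sobs + T/K, sobs + T*K]; T = 0 degenerates to [sobs, sobs].
    """
    if not 0 < conf_level < 1:
        raise ValueError("conf_level must be in (0, 1)")
    sobs, f1, f2 = tally_frequencies(a)
    if f2 > 0:
        extra = f1**2 / (2 * f2)
        bias_corrected = False
    else:
        extra = f1 * (f1 - 1) / (2 * (f2 + 1))
        bias_corrected = True
    chao1 = sobs + extra
    variance = _chao1_variance(sobs, f1, f2, chao1)
    t = chao1 - sobs
    if t <= 0 or variance <= 0:
        ci_low = ci_high = float(chao1)
    else:
        z = stats.norm.ppf(1 - (1 - conf_level) / 2)
        k = np.exp(z * np.sqrt(np.log(1 + variance / t**2)))
        ci_low = sobs + t / k
        ci_high = sobs + t * k
    return RichnessEstimate(
        sobs=sobs,
        f1=f1,
        f2=f2,
        chao1=float(chao1),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        conf_level=conf_level,
        variance=float(variance),
        bias_corrected=bias_corrected,
    )


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean observed and estimated richness as records accumulate."""

    levels: np.ndarray
    mean_sobs: np.ndarray
    mean_chao1: np.ndarray
    n_randomizations: int
    seed: int | None
    replacement: bool


def accumulation_curve(
    a: AbundanceVector,
    n_rand: int = 1000,
    replacement: bool = False,
    seed: int | None = None,
    levels: np.ndarray | None = None,
) -> AccumulationCurve:
    """Randomized accumulation curve over individual fossil records.

    Each randomization draws the pooled individual records in random order
    (without replacement by default; with replacement resamples the pool),
    recomputing S_obs and Chao1 at every accumulation level.

    Parameters
    ----------
    levels
        Accumulation sizes to evaluate; defaults to 1..total records.
        Levels beyond the total are an error when sampling without
        replacement.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    rng = np.random.default_rng(seed)
    n_total = a.total_records
    if levels is None:
        levels = np.arange(1, n_total + 1)
    else:
        levels = np.asarray(levels, dtype=int)
        if (levels < 1).any():
            raise ValueError("accumulation levels must be >= 1")
        if not replacement and (levels > n_total).any():
            raise ValueError(
                f"cannot accumulate {levels.max()} records without replacement "
                f"from a pool of {n_total}"
            )
    # One individual record = one species label; accumulate labels in random order.
    pool = np.repeat(np.arange(a.n_species), a.counts)
    sum_sobs = np.zeros(levels.size)
    sum_chao1 = np.zeros(levels.size)
    max_level = int(levels.max())
    for _ in range(n_rand):
        if replacement:
            order = rng.choice(pool, size=max_level, replace=True)
        else:
            order = rng.permutation(pool)[:max_level]
        for k, lev in enumerate(levels):
            sub = np.bincount(order[:lev], minlength=a.n_species)
            sub = sub[sub > 0]
            sobs = sub.size
            f1 = int((sub == 1).sum())
            f2 = int((sub == 2).sum())
            if f2 > 0:
                chao1 = sobs + f1**2 / (2 * f2)
            else:
                chao1 = sobs + f1 * (f1 - 1) / 2
            sum_sobs[k] += sobs
            sum_chao1[k] += chao1
    return AccumulationCurve(
        levels=levels,
        mean_sobs=sum_sobs / n_rand,
        mean_chao1=sum_chao1 / n_rand,
        n_randomizations=n_rand,
        seed=seed,
        replacement=replacement,
    )
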