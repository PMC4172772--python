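"""Optional matplotlib figures: accumulation curves and null histograms."""

from __future__ import annotations

from .cooccurrence import NullModelResult
from .richness import AccumulationCurve

__all__ = ["plot_accumulation", "plot_null_distribution"]


def plot_accumulation(curve: AccumulationCurve, ax=None):
    """Mean observed and Chao1-estimated richness vs records accumulated."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.levels, curve.mean_sobs, label="observed richness")
    ax.plot(curve.levels, curve.mean_chao1, label="Chao1 estimate", linestyle="--")
    ax.set_xlabel("fossil records accumulated")
    ax.set_ylabel("species")
    ax.legend()
    return ax


def plot_null_distribution(result: NullModelResult, ax=None, bins: int = 40):
    """Histogram of the Monte Carlo null with the observed value marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(result.null_values, bins=bins, color="0.7", edgecolor="0.4")
    ax.axvline(result.observed, color="crimson", label=f"observed = {result.observed:.3g}")
    ax.set_xlabel(result.statistic_name)
    ax.set_ylabel("simulations")
    ax.set_title(
        f"null mean {result.null_mean:.3g}, "
        f"P(null ≥ obs) = {result.p_upper:.4g}"
    )
    ax.legend()
    return ax
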