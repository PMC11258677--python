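"""Plot-level canopy cover from dot-grid observations, plus normality checks.

A field plot is observed at M systematic points with a sight tube; the
plot canopy cover is the covered fraction Cc = m/M.  Before kriging, the
variable of interest must be approximately Gaussian, so `summarize` also
reports skewness, excess kurtosis and a normality test (Shapiro-Wilk up to
n = 5000, D'Agostino K^2 beyond), with log and normal-score transforms
offered when the test fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PlotGrid", "SummaryStats", "canopy_cover", "summarize", "suggest_transform"]


@dataclass(frozen=True)
class PlotGrid:
    """Boolean canopy-hit flags at the M observation points of one plot."""

    flags: np.ndarray
    plot_id: int = 0

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if flags.ndim != 1 or flags.size < 1:
            raise ValueError("a plot needs at least one observation point")
        object.__setattr__(self, "flags", flags)

    @property
    def m_points(self) -> int:
        return self.flags.size


@dataclass(frozen=True)
class SummaryStats:
    n: int
    vmin: float
    vmax: float
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float
    normality_test: str
    normality_p: float
    normal: bool
    degenerate: bool = False


def canopy_cover(plot: PlotGrid) -> float:
    """Cc = m/M: covered observation points over all observation points."""
    return float(np.count_nonzero(plot.flags)) / plot.m_points


def summarize(values, alpha: float = 0.05) -> SummaryStats:
    """Descriptive statistics and a normality report for a sample.

    The standard deviation uses the n-1 denominator.  Shapiro-Wilk is used
    for n <= 5000, the D'Agostino K^2 test otherwise; a constant sample is
    flagged degenerate rather than tested.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    if v.size < 3:
        raise ValueError("need n >= 3 for the normality check")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        return SummaryStats(v.size, float(v.min()), float(v.max()), float(v.mean()),
                            0.0, 0.0, 0.0, "none", np.nan, normal=False, degenerate=True)
    if v.size <= 5000:
        test, (_, p) = "shapiro", stats.shapiro(v)
    else:
        test, (_, p) = "dagostino", stats.normaltest(v)
    return SummaryStats(
        n=v.size,
        vmin=float(v.min()),
        vmax=float(v.max()),
        mean=float(v.mean()),
        sd=sd,
        skewness=float(stats.skew(v)),
        excess_kurtosis=float(stats.kurtosis(v)),
        normality_test=test,
        normality_p=float(p),
        normal=bool(p >= alpha),
    )


def suggest_transform(values, alpha: float = 0.05):
    """Pick a normalizing transform for a sample that fails the check.

    Tries, in order: identity, natural log (positive data only) and the
    rank-based normal-score transform; returns ``(name, transformed)`` for
    the first that passes at ``alpha`` (normal scores pass by construction
    for continuous data).
    """
    v = np.asarray(values, dtype=float).ravel()
    if summarize(v, alpha).normal:
        return "identity", v
    if np.all(v > 0):
        logged = np.log(v)
        if summarize(logged, alpha).normal:
            return "log", logged
    from .kriging import normal_scores

    scores, _ = normal_scores(v)
    return "normal_score", scores
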