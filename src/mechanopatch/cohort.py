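"""Cohort proliferation statistics: growth normalization, exponential growth
fits, group summaries, percent-positive scoring, and the one-tailed
unequal-variance two-sample t-test.

These are the statistics used to compare wild-type and knockout stem-cell
lines: live-cell counts per line over days in culture are normalized to each
line's own day-0 value and fit with ``N(t) = N0 exp(k t)``; mitotic fraction
is the percentage of DAPI-positive nuclei that stain for phosphohistone H3
(PH3); group comparisons use Welch's t-test (one-tailed, unequal variance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import ttest_ind

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "normalize_growth",
    "fit_exponential_growth",
    "group_mean_sd",
    "t_test_one_tailed_unequal_var",
    "percent_positive",
    "growth_series_from_frame",
]


@dataclass(frozen=True)
class GrowthSeries:
    """Live-cell counts for one line over days in culture."""

    line: str
    genotype: str  # "WT" | "KO"
    days: tuple[float, ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if days.size != counts.size:
            raise ValueError("days and counts must have the same length")
        if days.size and (np.any(days < 0) or np.any(np.diff(days) <= 0)):
            raise ValueError("days must be non-negative and strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be >= 0")


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth-curve fit for one line."""

    line: str
    k_per_day: float
    r_squared: float
    n0: float
    flagged: bool = False  # degenerate input (constant counts)


def normalize_growth(series: GrowthSeries, anchor: str = "day0_per_line") -> GrowthSeries:
    """Normalize counts to the line's own day-0 value (day 0 maps to 1.000).

    ``anchor`` exists because two normalization conventions are in
    circulation for such tables: ``"day0_per_line"`` (the default, each line
    to its own day-0 count) and ``"day1_per_line"`` (each line to its day-1
    count).  Normalization is idempotent: normalizing an already-normalized
    series is a no-op.
    """
    anchors = {"day0_per_line": 0.0, "day1_per_line": 1.0}
    if anchor not in anchors:
        raise ValueError(f"anchor must be one of {sorted(anchors)}")
    days = np.asarray(series.days, dtype=float)
    counts = np.asarray(series.counts, dtype=float)
    where = np.flatnonzero(days == anchors[anchor])
    if not where.size:
        raise ValueError(f"series has no day-{anchors[anchor]:g} point to anchor on")
    ref = counts[where[0]]
    if ref <= 0:
        raise ValueError("anchor-day count is zero; cannot normalize")
    return replace(series, counts=tuple(counts / ref))


def fit_exponential_growth(series: GrowthSeries) -> GrowthFit:
    """Nonlinear least-squares fit of ``N(t) = N0 exp(k t)`` in natural scale.

    Returns the growth constant k (1/day) and R².  The fit is done on the
    counts as given (normalize first if desired); natural-scale fitting
    weights the later, larger counts the way the published growth constants
    behave, unlike log-linear regression.  Constant series return k = 0 with
    a flag; fewer than 3 points or all-zero counts raise.
    """
    days = np.asarray(series.days, dtype=float)
    counts = np.asarray(series.counts, dtype=float)
    if days.size < 3:
        raise ValueError("exponential fit needs at least 3 time points")
    if np.all(counts == 0):
        raise ValueError("all counts are zero; growth is undefined")
    if np.all(counts == counts[0]):
        return GrowthFit(series.line, 0.0, 1.0, float(counts[0]), flagged=True)

    # log-linear seed where possible
    pos = counts > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(days[pos], np.log(counts[pos]), 1)
        p0 = [float(np.exp(intercept)), float(slope)]
    else:
        p0 = [max(counts[0], 1e-6), 0.1]

    def f(t, n0, k):
        return n0 * np.exp(k * t)

    popt, _ = curve_fit(f, days, counts, p0=p0, maxfev=20000)
    resid = counts - f(days, *popt)
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return GrowthFit(series.line, float(popt[1]), r2, float(popt[0]))


def group_mean_sd(
    values_by_group: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-group arithmetic mean, sample SD (n−1 denominator) and n.

    SD is NaN for singleton groups (undefined, not zero).  Returns a tidy
    frame indexed by group with columns ``mean``, ``sd``, ``n``.
    """
    rows = {}
    for group, values in values_by_group.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {group!r} is empty")
        sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
        rows[group] = {"mean": float(v.mean()), "sd": sd, "n": v.size}
    return pd.DataFrame.from_dict(rows, orient="index")


def t_test_one_tailed_unequal_var(
    group_a: Sequence[float],
    group_b: Sequence[float],
    direction: str,
) -> tuple[float, float, float]:
    """Welch's two-sample t-test with a one-tailed p-value.

    ``direction`` states the alternative for group A relative to group B:
    ``"greater"`` (A > B) or ``"less"`` (A < B).  It is a required argument —
    a one-tailed test without a declared direction is meaningless.  Returns
    ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.  If both
    groups have zero variance and equal means, p = 0.5 by convention.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 0.5
        raise ValueError("zero variance in both groups with unequal means")
    res = ttest_ind(a, b, equal_var=False, alternative=direction)
    return float(res.statistic), float(res.df), float(res.pvalue)


def percent_positive(positive: int, total: int) -> float:
    """Percentage of positive cells: 100 * positive / total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= positive <= total:
        raise ValueError("positive count must lie in [0, total]")
    return 100.0 * positive / total


def growth_series_from_frame(df: pd.DataFrame) -> list[GrowthSeries]:
    """Build :class:`GrowthSeries` objects from a tidy frame with columns
    ``line``, ``genotype``, ``day``, ``count`` (one row per line and day)."""
    required = {"line", "genotype", "day", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table is missing columns: {sorted(missing)}")
    out = []
    for (line, genotype), sub in df.groupby(["line", "genotype"], sort=True):
        sub = sub.sort_values("day")
        out.append(
            GrowthSeries(
                line=str(line),
                genotype=str(genotype),
                days=tuple(sub["day"].astype(float)),
                counts=tuple(sub["count"].astype(float)),
            )
        )
    return out
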