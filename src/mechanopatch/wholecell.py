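"""Whole-cell mechanosensitive-current metrics.

The statistics computed here characterize the inactivation behavior of
poke- or pressure-evoked whole-cell currents:

* **baseline** — mean current in a pre-stimulus window (pA);
* **peak** — maximum current deviation from baseline during the stimulus,
  reported as a positive magnitude (pA);
* **slow** — current remaining 75 ms after stimulus onset, again as a
  magnitude over baseline (pA);
* **slow fraction** — slow / peak, the headline inactivation statistic: a
  canonical fast-inactivating mechanosensitive channel gives < 0.2, while
  mES-cell currents average about 0.67;
* **fast component** — peak − slow (pA);
* optional mono- or bi-exponential inactivation fits with a quality flag,
  since real decays are often too variable to fit reliably.

All currents are stored signed (inward negative) but reported as magnitudes
over baseline, matching how such measurements are usually tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import ttest_ind

from .sweeps import Sweep

__all__ = [
    "MSCurrentMetrics",
    "InactivationFit",
    "StageSummary",
    "estimate_baseline",
    "peak_current",
    "slow_current",
    "slow_fraction",
    "fast_component",
    "fit_inactivation",
    "compute_metrics",
    "summarize_stage",
    "compare_slow_fraction",
]

#: Readout time of the "slow" current, ms after stimulus onset.
SLOW_TIME_MS = 75.0
#: Width of the averaging window centred on the 75-ms readout, ms.
SLOW_WINDOW_MS = 5.0
#: Blanking applied after the stimulus edge before the peak search, ms
#: (excludes capacitive transients).
PEAK_BLANK_MS = 2.0


@dataclass
class InactivationFit:
    """Result of an exponential fit to the decay phase."""

    form: str  # "mono" | "bi"
    taus_ms: tuple[float, ...]
    amplitudes_pA: tuple[float, ...]
    offset_pA: float
    r_squared: float
    ok: bool


@dataclass
class MSCurrentMetrics:
    """Per-sweep mechanosensitive-current metrics (magnitudes over baseline)."""

    baseline: float
    peak: float
    slow: float
    slow_fraction: float
    fast_component: float
    slow_fraction_flagged: bool = False  # slow fraction > 1 (growing current)
    fast_negative_flagged: bool = False  # fast component < 0
    tau_fit: InactivationFit | None = None
    sweep_id: str = ""
    annotations: dict = field(default_factory=dict)


@dataclass
class StageSummary:
    """Mean +/- SEM of the metrics for one differentiation stage."""

    stage: str
    n: int
    peak_mean: float
    peak_sem: float
    slow_mean: float
    slow_sem: float
    slow_fraction_mean: float
    slow_fraction_sem: float


def estimate_baseline(sweep: Sweep, window: tuple[float, float]) -> float:
    """Mean current (pA) in a pre-stimulus window ``(t0, t1)`` ms.

    The window must precede the stimulus onset and contain at least 10
    samples.
    """
    t0, t1 = window
    if t1 > sweep.stim_onset + 1e-9:
        raise ValueError(
            f"baseline window [{t0}, {t1}) ms overlaps the stimulus "
            f"(onset {sweep.stim_onset} ms)"
        )
    seg = sweep.slice_ms(t0, t1)
    if seg.size < 10:
        raise ValueError(
            f"baseline window contains only {seg.size} samples (need >= 10)"
        )
    return float(seg.mean())


def _stim_window(sweep: Sweep, blank_ms: float) -> tuple[float, float]:
    t0 = sweep.stim_onset + blank_ms
    t1 = min(sweep.stim_onset + sweep.stim_duration, sweep.duration_ms)
    if t1 <= t0:
        raise ValueError("stimulus window is empty after edge blanking")
    return t0, t1


def peak_current(
    sweep: Sweep, baseline: float, blank_ms: float = PEAK_BLANK_MS
) -> float:
    """Peak current magnitude over baseline during the stimulus (pA).

    The search is restricted to the stimulus window, excluding ``blank_ms``
    after the step edge where capacitive transients would dominate.
    """
    t0, t1 = _stim_window(sweep, blank_ms)
    seg = sweep.slice_ms(t0, t1)
    return float(np.max(np.abs(seg - baseline)))


def peak_time_ms(
    sweep: Sweep, baseline: float, blank_ms: float = PEAK_BLANK_MS
) -> float:
    """Time (ms, from sweep start) of the peak deviation from baseline."""
    t0, t1 = _stim_window(sweep, blank_ms)
    i0 = sweep.index_at(t0)
    seg = sweep.slice_ms(t0, t1)
    return (i0 + int(np.argmax(np.abs(seg - baseline)))) * 1000.0 / sweep.fs


def slow_current(
    sweep: Sweep,
    baseline: float,
    at_ms: float = SLOW_TIME_MS,
    window_ms: float = SLOW_WINDOW_MS,
) -> float:
    """Current magnitude over baseline ``at_ms`` after stimulus onset (pA).

    Averaged over a short symmetric window (default 5 ms) centred on the
    readout time, for robustness against recording noise.
    """
    t_read = sweep.stim_onset + at_ms
    t0, t1 = t_read - window_ms / 2.0, t_read + window_ms / 2.0
    if t1 > sweep.duration_ms + 1e-9:
        raise ValueError(
            f"sweep ends at {sweep.duration_ms:.1f} ms, before the "
            f"{at_ms:g}-ms readout window"
        )
    seg = sweep.slice_ms(t0, t1)
    return float(abs(seg.mean() - baseline))


def slow_fraction(peak: float, slow: float) -> float:
    """Ratio slow/peak. Values above 1 are legal (growing current) but are
    flagged by :func:`compute_metrics` rather than clipped."""
    if peak <= 0:
        raise ValueError("slow fraction is undefined for zero peak current")
    return slow / peak


def fast_component(peak: float, slow: float) -> float:
    """Fast component = peak − slow (pA). May be negative up to noise;
    negative values are flagged by :func:`compute_metrics`, not clipped."""
    return peak - slow


def fit_inactivation(
    sweep: Sweep,
    baseline: float,
    form: str = "mono",
    blank_ms: float = PEAK_BLANK_MS,
    r2_threshold: float = 0.8,
) -> InactivationFit:
    """Least-squares exponential fit of the decay from the peak to the end of
    the stimulus.

    Fits ``y(t) = A exp(-t/tau) + C`` (mono) or the two-exponential analogue
    (bi) to the baseline-subtracted current magnitude.  ``ok`` is False when
    R² falls below ``r2_threshold`` or a time constant hits the fit bounds —
    decays with a variable initial step often cannot be fit reliably, and the
    flag records that honestly instead of returning a misleading number.
    """
    if form not in ("mono", "bi"):
        raise ValueError("form must be 'mono' or 'bi'")
    t_pk = peak_time_ms(sweep, baseline, blank_ms=blank_ms)
    t_end = min(sweep.stim_onset + sweep.stim_duration, sweep.duration_ms)
    if t_end - t_pk < 5.0:
        raise ValueError("no usable decay segment between peak and stimulus end")
    seg = sweep.slice_ms(t_pk, t_end)
    t = np.arange(seg.size) * 1000.0 / sweep.fs  # ms from the peak
    y = np.abs(seg - baseline)

    a0 = max(y[0] - y[-1], 1e-6)
    span = t[-1]
    tau_lo, tau_hi = 0.05, 50.0 * span

    if form == "mono":
        def f(tt, a, tau, c):
            return a * np.exp(-tt / tau) + c
        p0 = [a0, span / 5.0, y[-1]]
        lb = [0.0, tau_lo, 0.0]
        ub = [np.inf, tau_hi, np.inf]
    else:
        def f(tt, a1, tau1, a2, tau2, c):
            return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2) + c
        p0 = [a0 / 2, span / 20.0, a0 / 2, span / 2.0, y[-1]]
        lb = [0.0, tau_lo, 0.0, tau_lo, 0.0]
        ub = [np.inf, tau_hi, np.inf, tau_hi, np.inf]

    try:
        popt, _ = curve_fit(f, t, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except RuntimeError:
        return InactivationFit(form, (), (), float("nan"), 0.0, ok=False)

    resid = y - f(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0

    if form == "mono":
        amps, taus, offset = (popt[0],), (popt[1],), popt[2]
    else:
        order = np.argsort([popt[1], popt[3]])
        taus = tuple(np.array([popt[1], popt[3]])[order])
        amps = tuple(np.array([popt[0], popt[2]])[order])
        offset = popt[4]

    at_bound = any(
        tau < tau_lo * 1.01 or tau > tau_hi * 0.99 for tau in taus
    )
    ok = (r2 >= r2_threshold) and not at_bound
    return InactivationFit(
        form=form,
        taus_ms=tuple(float(x) for x in taus),
        amplitudes_pA=tuple(float(x) for x in amps),
        offset_pA=float(offset),
        r_squared=r2,
        ok=ok,
    )


def compute_metrics(
    sweep: Sweep,
    baseline_window: tuple[float, float],
    fit_form: str | None = None,
    blank_ms: float = PEAK_BLANK_MS,
) -> MSCurrentMetrics:
    """Full per-sweep metric computation: baseline, peak, slow, slow
    fraction, fast component, and (optionally) an inactivation fit."""
    base = estimate_baseline(sweep, baseline_window)
    pk = peak_current(sweep, base, blank_ms=blank_ms)
    sl = slow_current(sweep, base)
    sf = slow_fraction(pk, sl)
    fc = fast_component(pk, sl)
    fit = None
    if fit_form is not None:
        try:
            fit = fit_inactivation(sweep, base, form=fit_form, blank_ms=blank_ms)
        except ValueError:
            fit = None
    return MSCurrentMetrics(
        baseline=base,
        peak=pk,
        slow=sl,
        slow_fraction=sf,
        fast_component=fc,
        slow_fraction_flagged=sf > 1.0,
        fast_negative_flagged=fc < 0.0,
        tau_fit=fit,
        sweep_id=sweep.sweep_id,
        annotations=dict(sweep.annotations),
    )


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return mean, sem


def summarize_stage(
    metrics: Sequence[MSCurrentMetrics], stage: str
) -> StageSummary:
    """Mean ± SEM of peak, slow, and slow fraction for one stage.

    Data from independent differentiations are pooled without batch terms.
    """
    if not metrics:
        raise ValueError("cannot summarize an empty group of metrics")
    peaks = np.array([m.peak for m in metrics])
    slows = np.array([m.slow for m in metrics])
    sfs = np.array([m.slow_fraction for m in metrics])
    pm, ps = _mean_sem(peaks)
    sm, ss = _mean_sem(slows)
    fm, fsem = _mean_sem(sfs)
    return StageSummary(
        stage=stage, n=len(metrics),
        peak_mean=pm, peak_sem=ps,
        slow_mean=sm, slow_sem=ss,
        slow_fraction_mean=fm, slow_fraction_sem=fsem,
    )


def compare_slow_fraction(
    group_a: Sequence[MSCurrentMetrics], group_b: Sequence[MSCurrentMetrics]
) -> tuple[float, float, float]:
    """Two-sample unequal-variance (Welch) t-test on slow fractions,
    two-tailed. Returns ``(t, df, p)``."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 metrics for the t-test")
    a = np.array([m.slow_fraction for m in group_a])
    b = np.array([m.slow_fraction for m in group_b])
    res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
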