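"""Per-cell trace processing and fluctuation statistics.

The quantities defined here operate on the cytoplasmic:nuclear
translocation ratio of the CDK2 reporter: 3-point smoothing, trace QC,
landmark calling (CDK2 rise, APC/C inactivation), polynomial-residual and
second-derivative fluctuation scores, S-phase slope, drug-response
percent change and recovery kinetics, and population autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import CellTrace

__all__ = [
    "EventCalls",
    "FluctuationProfile",
    "RecoveryMetrics",
    "smooth_trace",
    "qc_filter",
    "call_cdk2_rise",
    "call_apc_inactivation",
    "fluctuation_polyfit",
    "fluctuation_second_derivative",
    "population_profile",
    "s_phase_slope",
    "percent_change",
    "recovery_metrics",
    "autocorrelation_profile",
]


@dataclass
class EventCalls:
    """Per-cell landmark times (h); ``None`` where a landmark was not called."""

    cdk2_rise: float | None = None
    apc_inactivation: float | None = None
    drug_add: float | None = None
    washout: float | None = None


@dataclass
class FluctuationProfile:
    """Population fluctuation summary on an aligned time axis."""

    aligned_time: np.ndarray  # h relative to the alignment event
    mean_sq_dev: np.ndarray
    sem: np.ndarray
    n: np.ndarray


@dataclass
class RecoveryMetrics:
    """Washout recovery readouts, both in minutes; ``None`` if not reached."""

    recovery_time: float | None
    halflife: float | None


def smooth_trace(trace: CellTrace, window: int = 3) -> CellTrace:
    """Centered moving-mean smoothing of the ratio (default 3 frames).

    Endpoints use the truncated window so the trace keeps its length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > trace.n_frames:
        raise ValueError("window larger than trace")
    half = window // 2
    x = trace.ratio
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = np.mean(x[lo:hi])
    return trace.with_ratio(out)


def qc_filter(
    traces: list[CellTrace],
    expression_percentile: float = 5.0,
    jump_threshold: float = 0.25,
) -> tuple[list[CellTrace], list[tuple[CellTrace, str]]]:
    """Remove low-expression and noisy traces.

    A cell's expression statistic is its mean total reporter intensity
    (nuclear + cytoplasmic) across frames; cells strictly below the
    ``expression_percentile`` of that statistic are dropped (boundary
    ties kept).  A trace with any frame-to-frame ratio change exceeding
    ``jump_threshold`` is dropped as noisy.
    """
    if not traces:
        raise ValueError("need at least one trace")
    expr = np.array([float(np.mean(t.nuc + t.cyto)) for t in traces])
    cutoff = np.percentile(expr, expression_percentile)
    kept, removed = [], []
    for trace, e in zip(traces, expr):
        if e < cutoff:
            trace.qc_flags.add("low_expression")
            removed.append((trace, "low_expression"))
        elif np.any(np.abs(np.diff(trace.ratio)) > jump_threshold):
            trace.qc_flags.add("noisy")
            removed.append((trace, "noisy"))
        else:
            kept.append(trace)
    return kept, removed


def _refine_onset(
    time: np.ndarray, y: np.ndarray, i0: int, level: float, window_h: float
) -> float:
    """Back-extrapolate a line fitted just after a crossing to ``level``.

    Returns the time where the local linear fit over
    ``[time[i0], time[i0]+window_h]`` attains ``level``; this removes the
    threshold-induced lateness of the raw crossing frame on ramp-like
    onsets.  Falls back to the crossing frame for non-rising fits.
    """
    dt = time[1] - time[0]
    i1 = min(len(time), i0 + max(3, int(round(window_h / dt)) + 1))
    coef = np.polyfit(time[i0:i1], y[i0:i1], 1)
    if coef[0] <= 0:
        return float(time[i0])
    t = (level - coef[1]) / coef[0]
    return float(np.clip(t, time[0], time[i0]))


def call_cdk2_rise(
    trace: CellTrace,
    rise_delta: float = 0.1,
    baseline_window: float = 5.0,
    baseline_percentile: float = 10.0,
    sustain: int = 3,
    refine_window: float = 1.0,
) -> float | None:
    """Time of the initial CDK2 activity rise (G0/G1 transition), or None.

    The raw call is the first frame at which the (smoothed) ratio exceeds
    ``baseline + rise_delta`` and stays above it for ``sustain`` frames,
    with baseline the ``baseline_percentile`` of the first
    ``baseline_window`` hours.  The call is then refined by fitting a
    line to the following ``refine_window`` hours and back-extrapolating
    it to the baseline level.
    """
    t, x = trace.time, trace.ratio
    pre = x[t <= t[0] + baseline_window]
    if len(pre) == 0:
        pre = x[:1]
    baseline = float(np.percentile(pre, baseline_percentile))
    above = x > baseline + rise_delta
    for i in range(len(x) - sustain + 1):
        if np.all(above[i : i + sustain]):
            return _refine_onset(t, x, i, baseline, refine_window)
    return None


def call_apc_inactivation(
    trace: CellTrace,
    rise_fraction: float = 0.05,
    sustain: int = 3,
    refine_window: float = 1.0,
) -> float | None:
    """Time of APC/C inactivation (S entry) from the degron signal, or None.

    Raw call: first frame where the degron exceeds ``rise_fraction`` of
    its trace maximum and keeps increasing for ``sustain`` subsequent
    frames; refined by back-extrapolating a local line fit to zero.
    Returns None when the degron never accumulates.
    """
    t, d = trace.time, trace.degron
    peak = float(np.max(d))
    if peak <= 0:
        return None
    thr = rise_fraction * peak
    for i in range(len(d) - sustain):
        if d[i] > thr and np.all(np.diff(d[i : i + sustain + 1]) > 0):
            return _refine_onset(t, d, i, 0.0, refine_window)
    return None


def _aligned_segment(trace: CellTrace, align_at: float) -> np.ndarray:
    return np.flatnonzero(trace.time >= align_at - 1e-9)


def fluctuation_polyfit(
    trace: CellTrace,
    align_at: float,
    degree: int = 3,
    activity_gate: float = 1.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Squared deviation of the trace from its own cubic best fit.

    A degree-``degree`` polynomial is least-squares fitted to the ratio
    from ``align_at`` onward; the analysis window is truncated at the
    first frame where the fitted curve exceeds ``activity_gate``
    (measurement noise grows at high ratios) and the polynomial is refit
    on the truncated window.  Returns aligned times (h after
    ``align_at``) and the per-timepoint squared residuals.
    """
    idx = _aligned_segment(trace, align_at)
    if len(idx) < degree + 2:
        raise ValueError("segment too short for polynomial fit")
    t, x = trace.time[idx], trace.ratio[idx]
    fit = np.polyval(np.polyfit(t, x, degree), t)
    over = np.flatnonzero(fit > activity_gate)
    if len(over):
        end = int(over[0])
        if end < degree + 2:
            raise ValueError("segment too short after activity gating")
        t, x = t[:end], x[:end]
        fit = np.polyval(np.polyfit(t, x, degree), t)
    return t - align_at, (x - fit) ** 2


def fluctuation_second_derivative(
    trace: CellTrace, align_at: float
) -> tuple[np.ndarray, np.ndarray]:
    """Squared central second difference of the ratio, scaled to h^-4 units.

    An alternative fluctuation score that needs no global fit: for each
    interior frame, ``((x[i-1] - 2 x[i] + x[i+1]) / dt^2)^2``.
    """
    idx = _aligned_segment(trace, align_at)
    if len(idx) < 3:
        raise ValueError("need at least 3 frames after align_at")
    t, x = trace.time[idx], trace.ratio[idx]
    dt = trace.frame_interval
    d2 = (x[:-2] - 2 * x[1:-1] + x[2:]) / dt**2
    return t[1:-1] - align_at, d2**2


def population_profile(
    series: list[tuple[np.ndarray, np.ndarray]],
    frame_interval: float | None = None,
    min_cells: int = 2,
) -> FluctuationProfile:
    """Mean, SEM and n per aligned timepoint over per-cell score series.

    ``series`` holds (aligned_time, values) pairs; aligned times are
    snapped to the common frame grid.  Timepoints with fewer than
    ``min_cells`` contributing cells are suppressed.
    """
    if not series:
        raise ValueError("no per-cell series given")
    if frame_interval is None:
        ts = series[0][0]
        frame_interval = float(np.min(np.diff(ts))) if len(ts) > 1 else 1.0
    buckets: dict[int, list[float]] = {}
    for t, v in series:
        for ti, vi in zip(np.asarray(t), np.asarray(v)):
            buckets.setdefault(int(round(ti / frame_interval)), []).append(float(vi))
    keys = sorted(k for k, vals in buckets.items() if len(vals) >= min_cells)
    mean = np.array([np.mean(buckets[k]) for k in keys])
    n = np.array([len(buckets[k]) for k in keys])
    sem = np.array(
        [np.std(buckets[k], ddof=1) / np.sqrt(len(buckets[k])) for k in keys]
    )
    return FluctuationProfile(
        aligned_time=np.array(keys) * frame_interval, mean_sq_dev=mean, sem=sem, n=n
    )


def s_phase_slope(
    trace: CellTrace, s_entry: float, crossing: float = 1.5
) -> float | None:
    """Slope (activity/h) of a line fit from S entry to the 1.5 crossing.

    Returns None for cells whose ratio never reaches ``crossing`` within
    the trace (excluded rather than extrapolated).
    """
    idx = _aligned_segment(trace, s_entry)
    if len(idx) == 0:
        raise ValueError("s_entry beyond trace end")
    t, x = trace.time[idx], trace.ratio[idx]
    cross = np.flatnonzero(x >= crossing)
    if len(cross) == 0:
        return None
    end = int(cross[0]) + 1
    if end < 3:
        raise ValueError("fewer than 3 frames between S entry and crossing")
    return float(np.polyfit(t[:end], x[:end], 1)[0])


def percent_change(trace: CellTrace, drug_add: float, horizon: float = 1.0) -> float:
    """Percent change in activity from the pre-drug frame to +``horizon`` h."""
    t = trace.time
    i_add = int(np.searchsorted(t, drug_add - 1e-9))
    if i_add == 0 or i_add >= len(t):
        raise ValueError("drug_add has no preceding frame inside the trace")
    ref = trace.ratio[i_add - 1]
    if ref <= 0:
        raise ValueError("reference ratio is non-positive")
    post = trace.ratio[trace.frame_at(drug_add + horizon)]
    if t[-1] + 1e-9 < drug_add + horizon:
        raise ValueError("horizon beyond trace end")
    return float(100.0 * (post - ref) / ref)


def recovery_metrics(
    trace: CellTrace,
    drug_add: float,
    washout: float,
    fit_window: float = 1.0,
) -> RecoveryMetrics:
    """Post-washout recovery time and exponential deficit half-life (min).

    Recovery time is the linearly interpolated first time after washout
    at which the ratio regains half the pre-drug level.  The half-life
    comes from a least-squares line on the log of the deficit
    (pre-drug level minus ratio) over the positive-deficit frames within
    ``fit_window`` hours of washout; the fixed window avoids selecting
    frames by their own noisy deficit, which skews the fitted slope.
    """
    t = trace.time
    i_add = int(np.searchsorted(t, drug_add - 1e-9))
    if i_add == 0:
        raise ValueError("drug_add has no preceding frame")
    pre = float(trace.ratio[i_add - 1])
    post = t >= washout - 1e-9
    tw, xw = t[post], trace.ratio[post]
    if len(tw) < 3:
        raise ValueError("trace barely extends beyond washout")

    half = 0.5 * pre
    recovery_time: float | None = None
    if xw[0] >= half:
        recovery_time = 0.0
    else:
        hit = np.flatnonzero(xw >= half)
        if len(hit):
            j = int(hit[0])
            frac = (half - xw[j - 1]) / (xw[j] - xw[j - 1])
            recovery_time = float((tw[j - 1] + frac * (tw[j] - tw[j - 1]) - tw[0]) * 60)

    deficit = pre - xw
    halflife: float | None = None
    use = (tw - tw[0] <= fit_window + 1e-9) & (deficit > 0)
    if use.sum() >= 3:
        coef = np.polyfit(tw[use], np.log(deficit[use]), 1)
        if coef[0] < 0:
            halflife = float(np.log(2) / -coef[0] * 60)
    return RecoveryMetrics(recovery_time=recovery_time, halflife=halflife)


def autocorrelation_profile(
    traces: list[CellTrace],
    s_windows: list[tuple[float, float]],
    max_lag: float = 4.0,
    detrend_degree: int = 3,
    min_pairs: int = 5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean autocorrelation of detrended S-phase segments, and its minimum lag.

    Each cell's S-phase segment is detrended by subtracting a
    least-squares polynomial (cubic by default, so the activity ramp does
    not mask the oscillation), its biased autocorrelation estimate is
    normalized to 1 at lag 0, and estimates are averaged across cells.
    Cells whose segment supports fewer than ``min_pairs`` products at
    ``max_lag`` are skipped.  Returns (lags in h, mean profile,
    anticorrelation lag = lag of the profile minimum in (0, max_lag]).
    """
    if not traces:
        raise ValueError("no traces given")
    dt = traces[0].frame_interval
    n_lag = int(round(max_lag / dt))
    acfs = []
    for trace, (t0, t1) in zip(traces, s_windows):
        sel = (trace.time >= t0 - 1e-9) & (trace.time <= t1 + 1e-9)
        x = trace.ratio[sel]
        if len(x) < max(n_lag + min_pairs, detrend_degree + 2):
            continue
        tt = trace.time[sel]
        x = x - np.polyval(np.polyfit(tt, x, detrend_degree), tt)
        c0 = float(np.dot(x, x))
        if c0 == 0:
            continue
        acf = np.array(
            [np.dot(x[: len(x) - k], x[k:]) / c0 for k in range(n_lag + 1)]
        )
        acfs.append(acf)
    if not acfs:
        raise ValueError("no S-phase segment long enough for the requested lag")
    mean_acf = np.mean(acfs, axis=0)
    lags = np.arange(n_lag + 1) * dt
    anticorr_lag = float(lags[1:][np.argmin(mean_acf[1:])])
    return lags, mean_acf, anticorr_lag
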