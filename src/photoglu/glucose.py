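"""Glucose trace cleaning and blood-glucose (BG) excursion metrics.

The cleaning chain is: robust MAD despiking (flagged samples replaced by
linear interpolation), a short centered median filter, and a causal moving
average that smooths jitter while keeping the response aligned in time.
Metrics are computed on the baseline-subtracted trace dG(t): sustained
onset (slope-or-level thresholds held for >= 1 min), peak level and peak
derivative, half-max recovery, plateau, return to baseline, and the
positive-only incremental area under the curve (iAUC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import medfilt

from .session_io import Session

logger = logging.getLogger("photoglu")

_EPS = np.finfo(float).eps


class TraceError(ValueError):
    """Trace unusable for the requested operation."""


@dataclass
class CleanConfig:
    """Despike/filter parameters shared by the glucose and photometry chains."""

    mad_k: float = 2.0          # |y - median| > mad_k * MAD flags a sample
    median_window: int = 7      # samples, centered median filter (odd)
    causal_ma_window: int = 60  # samples, causal moving average

    def __post_init__(self) -> None:
        if self.median_window % 2 == 0 or self.median_window < 1:
            raise ValueError("median_window must be odd and >= 1")
        if self.causal_ma_window < 1:
            raise ValueError("causal_ma_window must be >= 1")


@dataclass
class OnsetConfig:
    """Sustained-onset detector thresholds.

    Onset requires either the derivative to exceed ``median + z_mult *
    sigma_d`` or the level to exceed ``level_mult * sigma_y`` (both robust
    scales from the pre-event baseline) for ``sustain`` consecutive samples.
    """

    z_mult: float = 3.0
    level_mult: float = 3.0
    sustain: int = 60                  # samples (1 min at 1 Hz)
    boxcar: int = 120                  # samples, causal boxcar before the derivative
    onset_baseline_window: tuple[float, float] = (-5.0, 0.0)  # min

    def __post_init__(self) -> None:
        if self.sustain < 1:
            raise ValueError("sustain must be >= 1")
        if self.z_mult <= 0 or self.level_mult <= 0:
            raise ValueError("threshold multipliers must be > 0")


@dataclass
class GlucoseMetrics:
    """Summary of one session's BG excursion; times in minutes, ``None``
    where a metric is undefined (``reason`` records why)."""

    theta: float | None = None              # onset, min
    peak_dG: float | None = None            # mg/dL
    peak_dG_time: float | None = None       # min, within [0, 90]
    peak_deriv: float | None = None         # mg/dL/min
    peak_deriv_time: float | None = None    # min, within [0, 30]
    fall_rate: float | None = None          # mg/dL/min, magnitude of steepest fall
    half_max_time: float | None = None      # min
    plateau_start: float | None = None      # min
    plateau_end: float | None = None        # min
    return_time: float | None = None        # min
    iauc: float = 0.0                       # mg/dL*min over [0, 90]
    baseline: float | None = None           # mg/dL
    reason: str = ""


# -- filtering primitives (also used by the photometry chain) ---------------


def causal_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Average of the most recent ``min(i+1, window)`` samples at index i.

    The warm-up uses an expanding window so the output keeps the input's
    length and a constant input is preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    c = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx + 1 - window, 0)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def mad_scale(x: np.ndarray) -> float:
    """Robust SD estimate: 1.4826 * median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def despike_mad(x: np.ndarray, mad_k: float, window: int = 7) -> np.ndarray:
    """Robust MAD despiking: flag |y - median| > mad_k * MAD, replace by
    linear interpolation between the nearest unflagged neighbours.

    The deviation is measured from a centered rolling median (``window``
    samples) and the MAD is the global MAD of those deviations. Measuring
    deviation locally keeps slow physiological excursions untouched — a
    single global median would flag an entire glucose excursion as outlying
    — while impulsive sensor spikes still stand out from the local median.
    """
    x = np.asarray(x, dtype=float)
    local_med = median_filter(x, size=window, mode="nearest")
    resid = x - local_med
    mad = np.median(np.abs(resid - np.median(resid)))
    flagged = np.abs(resid) > mad_k * mad
    if flagged.all():
        raise TraceError("all samples flagged as outliers; trace unusable")
    if not flagged.any():
        return x.copy()
    out = x.copy()
    idx = np.arange(x.size)
    out[flagged] = np.interp(idx[flagged], idx[~flagged], x[~flagged])
    return out


def clean_trace(raw: np.ndarray, cfg: CleanConfig | None = None) -> np.ndarray:
    """Despike -> centered median filter -> causal moving average."""
    cfg = cfg or CleanConfig()
    raw = np.asarray(raw, dtype=float)
    if raw.size < cfg.causal_ma_window:
        raise TraceError(
            f"trace has {raw.size} samples; need >= {cfg.causal_ma_window}"
        )
    x = despike_mad(raw, cfg.mad_k)
    x = medfilt(x, kernel_size=cfg.median_window)
    return causal_moving_average(x, cfg.causal_ma_window)


# -- baseline and derivative ------------------------------------------------


def baseline_delta(
    clean: np.ndarray,
    t: np.ndarray,
    baseline_window: tuple[float, float] = (-25.0, 0.0),
) -> tuple[np.ndarray, float]:
    """Baseline-subtracted trace dG(t) and the baseline mean.

    The baseline is the mean over ``baseline_window`` (minutes, half-open so
    the event sample is excluded).
    """
    lo, hi = (60.0 * w for w in baseline_window)
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise TraceError(
            f"baseline window [{baseline_window[0]}, {baseline_window[1]}] min "
            "outside trace support"
        )
    mask = (t >= lo - 1e-9) & (t < hi - 1e-9)
    if not mask.any():
        raise TraceError("baseline window contains no samples")
    base = float(np.mean(clean[mask]))
    return clean - base, base


def smoothed_derivative(series: np.ndarray, cfg: CleanConfig | None = None) -> np.ndarray:
    """Causal finite-difference derivative in mg/dL/min.

    The per-second forward difference is assigned to the later sample
    (right-aligned, first sample 0), converted to per-minute units, then
    smoothed with the same causal moving average as the level trace.
    """
    cfg = cfg or CleanConfig()
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise TraceError("need at least 2 samples for a derivative")
    d = np.zeros_like(series)
    d[1:] = np.diff(series) * 60.0
    return causal_moving_average(d, cfg.causal_ma_window)


# -- onset detection --------------------------------------------------------


def _first_sustained_run(marked: np.ndarray, sustain: int) -> int | None:
    """Index of the first sample of the first run of >= sustain Trues."""
    if sustain <= 1:
        hits = np.flatnonzero(marked)
        return int(hits[0]) if hits.size else None
    padded = np.concatenate(([False], marked, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s >= sustain:
            return int(s)
    return None


def detect_onset(
    clean: np.ndarray, t: np.ndarray, cfg: OnsetConfig | None = None
) -> float | None:
    """Sustained BG-rise onset time in minutes, or ``None``.

    The level condition tests the baseline-median-subtracted trace y0(t)
    against ``level_mult * sigma_y``; the slope condition tests the
    derivative of the 2-min-boxcar-smoothed y0 against
    ``median + z_mult * sigma_d``. Both robust scales (1.4826 * MAD) come
    from the pre-event segment. Onset is the first sample of the first run
    of >= ``sustain`` consecutive post-event samples where either condition
    holds.
    """
    cfg = cfg or OnsetConfig()
    clean = np.asarray(clean, dtype=float)
    pre = t < 0
    if not pre.any():
        raise TraceError("no pre-event baseline segment (t < 0)")

    lo, hi = (60.0 * w for w in cfg.onset_baseline_window)
    bmask = (t >= lo - 1e-9) & (t < hi - 1e-9)
    if not bmask.any():
        raise TraceError("onset baseline window contains no samples")
    y0 = clean - np.median(clean[bmask])
    y0_smooth = causal_moving_average(y0, cfg.boxcar)
    d = np.zeros_like(y0_smooth)
    d[1:] = np.diff(y0_smooth)

    md = float(np.median(d[pre]))
    sigma_d = mad_scale(d[pre])
    sigma_y = mad_scale(y0[pre])
    floor = _EPS * max(1.0, float(np.max(np.abs(clean))))
    if sigma_d == 0:
        logger.warning("degenerate baseline: MAD of derivative is 0; flooring")
        sigma_d = floor
    if sigma_y == 0:
        logger.warning("degenerate baseline: MAD of level is 0; flooring")
        sigma_y = floor

    slope_cond = d > md + cfg.z_mult * sigma_d
    level_cond = y0 > cfg.level_mult * sigma_y
    marked = (t >= 0) & (slope_cond | level_cond)
    idx = _first_sustained_run(marked, cfg.sustain)
    return float(t[idx] / 60.0) if idx is not None else None


# -- excursion metrics ------------------------------------------------------


def iauc_positive(
    delta: np.ndarray, t: np.ndarray, window: tuple[float, float] = (0.0, 90.0)
) -> float:
    """Positive-only incremental area under dG(t), mg/dL*min (trapezoidal)."""
    lo, hi = (60.0 * w for w in window)
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise TraceError("iAUC window outside trace support")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    clipped = np.clip(delta[mask], 0.0, None)
    return float(np.trapezoid(clipped, t[mask]) / 60.0)


def _interp_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First downward crossing of ``level`` in ``y``; linear interpolation."""
    below = y <= level
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y0 == y1:
        return float(t1)
    return float(t0 + (y0 - level) / (y0 - y1) * (t1 - t0))


def excursion_metrics(
    delta: np.ndarray,
    deriv: np.ndarray,
    t: np.ndarray,
    band_fraction: float = 0.1,
    sustain: int = 60,
) -> GlucoseMetrics:
    """Peak, half-max recovery, plateau and return-to-baseline metrics.

    ``band_fraction`` scales the near-zero derivative band that defines the
    plateau relative to the preceding peak rise rate. The return to baseline
    is the first dG <= 0 after the peak, with a sustained derivative
    relaxation (``deriv > 0`` for >= ``sustain`` samples after the fall
    phase) as a fallback.
    """
    m = GlucoseMetrics()
    if not ((t >= 0).any() and t[-1] >= 90 * 60 - 1e-9):
        raise TraceError("excursion metrics need dG spanning [0, 90] min")

    post = (t >= 0) & (t <= 90 * 60)
    early = (t >= 0) & (t <= 30 * 60)
    t_post, d_post = t[post], delta[post]

    i_peak = int(np.argmax(d_post))
    peak = float(d_post[i_peak])
    if peak <= 0:
        m.reason = "no excursion above baseline"
        m.iauc = iauc_positive(delta, t)
        return m
    m.peak_dG = peak
    m.peak_dG_time = float(t_post[i_peak] / 60.0)

    j = int(np.argmax(deriv[early]))
    m.peak_deriv = float(deriv[early][j])
    m.peak_deriv_time = float(t[early][j] / 60.0)

    after_peak = post & (t >= t_post[i_peak])
    if after_peak.sum() > 1:
        m.fall_rate = float(-np.min(deriv[after_peak]))

    # half-max: first post-peak crossing of baseline + peak/2, on the
    # unsmoothed dG series with linear interpolation
    tail_t = t_post[i_peak:]
    tail_y = d_post[i_peak:]
    m.half_max_time = _interp_crossing(tail_t, tail_y, 0.5 * peak)
    if m.half_max_time is not None:
        m.half_max_time /= 60.0

    # plateau: first interval after the peak rise where |dG/dt| stays
    # inside +-(band_fraction * peak rise rate)
    band = band_fraction * m.peak_deriv
    rise_end = int(np.flatnonzero(early)[j])
    in_band = np.abs(deriv) <= band
    in_band[: rise_end + 1] = False
    in_band[~post] = False
    start = _first_sustained_run(in_band, sustain)
    if start is not None:
        run_end = start
        while run_end + 1 < t.size and in_band[run_end + 1]:
            run_end += 1
        m.plateau_start = float(t[start] / 60.0)
        m.plateau_end = float(t[run_end] / 60.0)

    # return to baseline: first dG <= 0 after the peak ...
    ret = np.flatnonzero(after_peak & (delta <= 0))
    if ret.size:
        m.return_time = float(t[ret[0]] / 60.0)
    else:
        # ... else first sustained relaxation of the derivative after the
        # fall phase (past half-max when defined)
        t_fall = (m.half_max_time or m.peak_dG_time) * 60.0
        relax = (t > t_fall) & (deriv > 0)
        start = _first_sustained_run(relax, sustain)
        if start is not None:
            m.return_time = float(t[start] / 60.0)

    m.iauc = iauc_positive(delta, t)
    return m


# -- session-level driver ---------------------------------------------------


def analyze_glucose(
    session: Session,
    clean_cfg: CleanConfig | None = None,
    onset_cfg: OnsetConfig | None = None,
    baseline_window: tuple[float, float] = (-25.0, 0.0),
) -> tuple[GlucoseMetrics, dict[str, np.ndarray]]:
    """Full glucose chain for one session.

    Returns the metrics plus the intermediate traces (``clean``, ``delta``,
    ``deriv``) used by the coupling analyses.
    """
    clean_cfg = clean_cfg or CleanConfig()
    clean = clean_trace(session.glucose, clean_cfg)
    delta, base = baseline_delta(clean, session.t, baseline_window)
    deriv = smoothed_derivative(delta, clean_cfg)
    metrics = excursion_metrics(delta, deriv, session.t)
    metrics.baseline = base
    metrics.theta = detect_onset(clean, session.t, onset_cfg)
    traces = {"clean": clean, "delta": delta, "deriv": deriv}
    return metrics, traces
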