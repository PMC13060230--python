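"""Fiber-photometry preprocessing and response metrics.

Processing order: affine isosbestic (motion/bleaching) regression on the raw
channels, then despike/median/causal-average cleaning, a zero-phase
Butterworth low-pass defined by period, and baseline z-scoring. Response
metrics include the peak z and peak inhibition, negative/total AUC, a
spectral low-frequency onset tested against a jittered pseudo-event null,
and the aperiodic 1/f^k exponent of the baseline power spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .glucose import CleanConfig, TraceError, clean_trace
from .session_io import Session

logger = logging.getLogger("photoglu")


@dataclass
class FPConfig:
    """Photometry chain parameters (windows in minutes unless noted)."""

    mad_k: float = 2.0
    median_window: int = 7
    causal_ma_window: int = 60
    lowpass_period: float = 4.0        # min; cutoff frequency = 1/(period*60) Hz
    lowpass_order: int = 3
    baseline_window: tuple[float, float] = (-25.0, 0.0)
    peak_z_window: tuple[float, float] = (0.0, 15.0)
    inhibition_window: tuple[float, float] = (0.0, 10.0)
    band_period_min: tuple[float, float] = (14.0, 20.0)  # spectral band, minutes
    spec_window: float = 20.0          # min, spectrogram window
    spec_overlap: float = 0.99         # fraction
    n_pseudo: int = 200
    guard: float = 5.0                 # min, exclusion zone around the true event
    detect_window: tuple[float, float] = (-10.0, 10.0)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.spec_overlap < 1.0:
            raise ValueError("spec_overlap must be in [0, 1)")
        if self.band_period_min[0] >= self.band_period_min[1]:
            raise ValueError("band periods must satisfy min < max")
        if self.lowpass_period <= 0 or self.spec_window <= 0 or self.guard < 0:
            raise ValueError("windows must be positive")

    @property
    def clean(self) -> CleanConfig:
        return CleanConfig(self.mad_k, self.median_window, self.causal_ma_window)


@dataclass
class PhotometryMetrics:
    """Scalar summary of one session's z-scored photometry trace."""

    peak_z: float | None = None               # max z in the early window
    peak_inhibition: float | None = None      # min z in the inhibition window
    peak_inhibition_time: float | None = None  # min
    neg_auc: float | None = None              # z*min over [0, t_peak_bg], <= 0
    total_auc: float | None = None            # z*min over [0, end]
    lf_onset: float | None = None             # min, spectral band-power onset
    psd_slope_k: float | None = None          # aperiodic exponent
    lf_p_curve: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


# -- preprocessing ----------------------------------------------------------


def motion_correct(signal: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Remove shared motion/bleaching by affine regression of the reference
    onto the signal channel; the residual is zero-mean by construction."""
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if signal.size != reference.size:
        raise TraceError("signal and reference must have equal lengths")
    if signal.size < 10:
        raise TraceError("need >= 10 samples for the reference regression")
    ref_var = np.var(reference)
    if ref_var <= np.finfo(float).eps * max(1.0, np.mean(reference) ** 2):
        logger.warning("constant reference channel: falling back to mean subtraction")
        return signal - signal.mean()
    b = float(np.cov(signal, reference, bias=True)[0, 1] / ref_var)
    a = float(signal.mean() - b * reference.mean())
    return signal - (a + b * reference)


def clean_and_lowpass(corrected: np.ndarray, cfg: FPConfig | None = None) -> np.ndarray:
    """Despike/median/causal-average, then zero-phase Butterworth low-pass.

    The filter is applied forward and backward (``sosfiltfilt`` with
    odd-reflection padding), so it is zero-phase and symmetric under time
    reversal.
    """
    cfg = cfg or FPConfig()
    x = clean_trace(np.asarray(corrected, dtype=float), cfg.clean)
    cutoff_hz = 1.0 / (cfg.lowpass_period * 60.0)
    sos = sps.butter(cfg.lowpass_order, cutoff_hz, btype="low", fs=1.0, output="sos")
    # pad well past the filter's ~1/cutoff time constant so edge transients
    # decay inside the padding, not the data
    padlen = int(3.0 / cutoff_hz)
    if x.size <= 3 * padlen:
        raise TraceError(
            f"trace of {x.size} samples too short for zero-phase filtering at "
            f"a {cfg.lowpass_period:g} min cutoff (need > {3 * padlen})"
        )
    return sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def zscore_baseline(
    filtered: np.ndarray, t: np.ndarray, baseline_window: tuple[float, float] = (-25.0, 0.0)
) -> np.ndarray:
    """Z-score against the pre-event baseline: mean 0, SD 1 on the window."""
    lo, hi = (60.0 * w for w in baseline_window)
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise TraceError("baseline window outside trace support")
    mask = (t >= lo - 1e-9) & (t < hi - 1e-9)
    mu = float(np.mean(filtered[mask]))
    sd = float(np.std(filtered[mask]))
    if sd == 0:
        raise TraceError("zero baseline SD; cannot z-score")
    return (filtered - mu) / sd


# -- scalar response metrics ------------------------------------------------


def _window_mask(t: np.ndarray, window_min: tuple[float, float]) -> np.ndarray:
    lo, hi = (60.0 * w for w in window_min)
    return (t >= lo - 1e-9) & (t <= hi + 1e-9)


def response_metrics(
    z: np.ndarray,
    t: np.ndarray,
    t_peak_bg_min: float | None,
    cfg: FPConfig | None = None,
) -> PhotometryMetrics:
    """Peak z, peak inhibition, and negative/total AUC.

    ``neg_auc`` integrates only the below-baseline part of z from the event
    to the time of peak blood glucose; it is absent when ``t_peak_bg_min``
    is. ``total_auc`` integrates the unmodified z to the end of the session.
    """
    cfg = cfg or FPConfig()
    m = PhotometryMetrics()
    pk = _window_mask(t, cfg.peak_z_window)
    m.peak_z = float(np.max(z[pk]))
    inh = _window_mask(t, cfg.inhibition_window)
    i = int(np.argmin(z[inh]))
    m.peak_inhibition = float(z[inh][i])
    m.peak_inhibition_time = float(t[inh][i] / 60.0)
    post = t >= 0
    m.total_auc = float(np.trapezoid(z[post], t[post]) / 60.0)
    if t_peak_bg_min is not None:
        mask = (t >= 0) & (t <= t_peak_bg_min * 60.0 + 1e-9)
        m.neg_auc = float(np.trapezoid(np.clip(z[mask], None, 0.0), t[mask]) / 60.0)
    return m


# -- spectral low-frequency onset -------------------------------------------


def _band_power_series(
    z: np.ndarray, t: np.ndarray, cfg: FPConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Band-limited spectrogram power vs window-center time (seconds)."""
    nperseg = int(round(cfg.spec_window * 60.0))
    hop = max(1, int(round(nperseg * (1.0 - cfg.spec_overlap))))
    if z.size < nperseg:
        raise TraceError(
            f"trace of {z.size} samples shorter than one spectrogram window "
            f"({nperseg} samples)"
        )
    f, tau, S = sps.spectrogram(
        z, fs=1.0, window="hann", nperseg=nperseg, noverlap=nperseg - hop
    )
    lo_hz = 1.0 / (cfg.band_period_min[1] * 60.0)
    hi_hz = 1.0 / (cfg.band_period_min[0] * 60.0)
    band = (f >= lo_hz - 1e-12) & (f <= hi_hz + 1e-12)
    if not band.any():
        raise TraceError("no spectrogram frequency bins inside the band")
    power = S[band].mean(axis=0)
    centers = t[0] + tau  # session time of each window center
    return centers, power


def lf_onset(
    z: np.ndarray,
    t: np.ndarray,
    cfg: FPConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float | None, np.ndarray, np.ndarray]:
    """Low-frequency band-power onset against a jittered pseudo-event null.

    Band power around the true event is compared, at each relative offset
    tau in ``detect_window``, with the same band power around ``n_pseudo``
    pseudo-event times (drawn without replacement from the admissible grid,
    excluding a guard zone around the true event). The upper-tailed rank
    p-value is ``(1 + #{null >= real}) / (n_pseudo + 1)``; onset is the
    first tau with p < alpha.

    Returns ``(onset_min_or_None, tau_grid_min, p_curve)``.
    """
    cfg = cfg or FPConfig()
    rng = rng or np.random.default_rng()
    centers, power = _band_power_series(z, t, cfg)
    hop = centers[1] - centers[0] if centers.size > 1 else 1.0

    lo, hi = (60.0 * w for w in cfg.detect_window)
    tau_grid = np.arange(np.ceil(lo / hop), np.floor(hi / hop) + 0.5) * hop

    # admissible pseudo-event times: every offset must stay on the band-power
    # support, and the pseudo event must be >= guard from the true event
    support_lo = centers[0] - tau_grid[0]
    support_hi = centers[-1] - tau_grid[-1]
    admissible = centers[(centers >= support_lo) & (centers <= support_hi)]
    admissible = admissible[np.abs(admissible) >= cfg.guard * 60.0]
    if admissible.size < max(cfg.n_pseudo, 20):
        need = (tau_grid[-1] - tau_grid[0] + 2 * cfg.guard * 60.0) / 60.0
        raise TraceError(
            f"only {admissible.size} admissible pseudo-event times for "
            f"{cfg.n_pseudo} draws; trace must extend well beyond ~{need:.0f} min "
            "around the event"
        )
    pseudo = rng.choice(admissible, size=cfg.n_pseudo, replace=False)

    p_real = np.interp(tau_grid, centers, power)
    null = np.empty((cfg.n_pseudo, tau_grid.size))
    for k, t0 in enumerate(pseudo):
        null[k] = np.interp(t0 + tau_grid, centers, power)
    p = (1.0 + (null >= p_real[None, :]).sum(axis=0)) / (cfg.n_pseudo + 1.0)

    hits = np.flatnonzero(p < cfg.alpha)
    onset = float(tau_grid[hits[0]] / 60.0) if hits.size else None
    return onset, tau_grid / 60.0, p


# -- baseline PSD slope -----------------------------------------------------


def psd_slope(
    z_baseline: np.ndarray,
    fit_band_hz: tuple[float, float] = (1.0 / 600.0, 1.0 / 60.0),
    nperseg: int = 480,
) -> float:
    """Aperiodic exponent k of a 1/f^k fit to the baseline Welch PSD.

    The PSD is estimated with Hann-windowed 8-min segments at 50% overlap
    and fit by OLS in log-log space over ``fit_band_hz`` (default periods
    1-10 min, the range a 25-min baseline resolves); k is minus the slope.
    """
    z_baseline = np.asarray(z_baseline, dtype=float)
    if z_baseline.size < 25 * 60:
        raise TraceError("baseline segment must be >= 25 min for the PSD fit")
    f, pxx = sps.welch(
        z_baseline, fs=1.0, window="hann", nperseg=min(nperseg, z_baseline.size),
        noverlap=min(nperseg, z_baseline.size) // 2,
    )
    band = (f >= fit_band_hz[0] - 1e-12) & (f <= fit_band_hz[1] + 1e-12) & (pxx > 0)
    if band.sum() < 5:
        raise TraceError(
            f"only {int(band.sum())} frequency bins in the fit band; need >= 5"
        )
    slope = np.polyfit(np.log(f[band]), np.log(pxx[band]), 1)[0]
    return float(-slope)


# -- session-level driver ---------------------------------------------------


def preprocess_fp(session: Session, cfg: FPConfig | None = None) -> np.ndarray:
    """Raw channels -> motion-corrected, cleaned, low-passed, z-scored trace."""
    cfg = cfg or FPConfig()
    corrected = motion_correct(session.fp_signal, session.fp_reference)
    filtered = clean_and_lowpass(corrected, cfg)
    return zscore_baseline(filtered, session.t, cfg.baseline_window)


def analyze_fp(
    session: Session,
    t_peak_bg_min: float | None,
    cfg: FPConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PhotometryMetrics, np.ndarray]:
    """Full photometry chain for one session; returns metrics and Z_FP(t)."""
    cfg = cfg or FPConfig()
    z = preprocess_fp(session, cfg)
    metrics = response_metrics(z, session.t, t_peak_bg_min, cfg)
    onset, tau, p = lf_onset(z, session.t, cfg, rng)
    metrics.lf_onset = onset
    metrics.lf_p_curve = (tau, p)
    baseline_mask = (session.t >= cfg.baseline_window[0] * 60.0 - 1e-9) & (
        session.t < cfg.baseline_window[1] * 60.0 - 1e-9
    )
    metrics.psd_slope_k = psd_slope(z[baseline_mask])
    return metrics, z
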