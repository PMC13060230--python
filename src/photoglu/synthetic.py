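"""Synthetic cohorts of paired photometry + glucose sessions.

The generator emulates the statistical structure the analysis pipeline
assumes, not the underlying physiology: dose-dependent glucose excursions
whose rise *and* fall rates scale with dose (so recovery time is roughly
dose-invariant), an anticipatory dose-invariant photometry inhibition that
begins a few minutes before the gavage event, a second-phase inhibition
coupled with a lag to the positive glucose rate of change, 1/f-shaped
baseline noise, photobleaching drift, sensor spikes, and motion artifacts
shared between the signal and isosbestic channels.

Every ground-truth component trace is stored on the generated
:class:`~photoglu.session_io.Session` so downstream recovery tests can
compare against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from functools import lru_cache
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq

from .session_io import Session


@dataclass
class SyntheticConfig:
    """Cohort-level generative parameters.

    Dose-scaled glucose parameters are per (g/kg): e.g. with
    ``peak_amplitude_per_dose = 60`` a 2 g/kg gavage peaks ~120 mg/dL above
    baseline. Because the rise and fall rates also scale with dose, the time
    from excursion onset back to half-max is the same at every dose.
    Photometry amplitudes are in z-units of the baseline-normalised trace.
    """

    n_subjects: int = 6
    doses: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 2.5)
    seed: int = 0

    # session grid (minutes relative to the gavage event)
    t_start_min: float = -25.0
    t_end_min: float = 90.0

    # glucose excursion
    glucose_baseline: float = 150.0           # mg/dL, 5-h-fasted mouse
    rise_rate_per_dose: float = 6.0           # (mg/dL/min) per (g/kg)
    fall_rate_per_dose: float = 2.0           # (mg/dL/min) per (g/kg)
    peak_amplitude_per_dose: float = 60.0     # mg/dL per (g/kg)
    absorption_delay_min: float = 3.6         # min from gavage to BG rise
    absorption_delay_jitter_min: float = 0.5  # SD of per-session jitter
    glucose_noise_sd: float = 2.0             # mg/dL, sensor noise
    spike_rate_per_hour: float = 2.0
    spike_amplitude: float = 15.0             # mg/dL

    # anticipatory (first-phase) photometry component
    anticipatory_onset: float = -4.0          # min before event (negative)
    anticipatory_depth: float = 2.5           # z-units, dose-invariant
    anticipatory_ramp_min: float = 6.4        # min from onset to peak inhibition
    anticipatory_recovery_tau: float = 25.0   # min, exponential recovery
    anticipatory_scale_sd: float = 0.25       # lognormal SD of per-session scale

    # second-phase photometry component (lagged coupling to dG/dt)
    second_phase_gain: float = 0.05           # z per (mg/dL/min), on max(0, dG/dt)
    second_phase_lag: float = 5.0             # min, FP after the derivative

    # photometry nuisance structure
    fp_noise_exponent: float = 1.0            # aperiodic 1/f^k exponent
    fp_noise_sd: float = 0.3                  # z-units
    bleach_rate: float = 0.05                 # fractional drift per hour
    motion_sd: float = 1.0                    # a.u., shared artifact amplitude
    fp_spike_amplitude: float = 5.0           # a.u.
    fp_baseline: float = 100.0                # a.u., raw fluorescence level
    neural_gain: float = 5.0                  # a.u. per z-unit
    reference_gain: float = 0.8               # shared-artifact gain in reference
    reference_noise_sd: float = 0.05          # a.u., independent reference noise

    def __post_init__(self) -> None:
        for name in (
            "rise_rate_per_dose", "fall_rate_per_dose", "peak_amplitude_per_dose",
            "glucose_noise_sd", "spike_rate_per_hour", "spike_amplitude",
            "anticipatory_depth", "anticipatory_recovery_tau",
            "anticipatory_scale_sd", "second_phase_gain", "fp_noise_sd",
            "bleach_rate", "motion_sd", "reference_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")

    @property
    def t(self) -> np.ndarray:
        """The 1 Hz session grid, seconds relative to the event."""
        return np.arange(self.t_start_min * 60.0, self.t_end_min * 60.0 + 0.5)


# -- component generators ---------------------------------------------------


def _powerlaw_noise(n: int, exponent: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped Gaussian noise with power spectrum ~ 1/f^exponent."""
    if sd == 0:
        return np.zeros(n)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shape, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _sparse_spikes(
    n: int, rate_per_hour: float, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Single-sample artifacts at Poisson times, random sign."""
    out = np.zeros(n)
    k = rng.poisson(rate_per_hour * n / 3600.0)
    if k:
        idx = rng.integers(0, n, size=k)
        out[idx] = amplitude * rng.choice([-1.0, 1.0], size=k) * rng.uniform(0.8, 1.5, size=k)
    return out


@lru_cache(maxsize=32)
def _gamma_shape_params(fall_over_rise: float) -> tuple[float, float]:
    """Gamma-variate exponent alpha whose fall/rise slope ratio matches
    ``fall_over_rise``, plus the shape's peak rise slope in 1/peak-time
    units. Cached: the ratio is dose-invariant."""
    u = np.linspace(1e-6, 12.0, 20000)

    def stats(alpha: float) -> tuple[float, float]:
        g = u**alpha * np.exp(alpha * (1.0 - u))
        dg = np.gradient(g, u)
        return float(dg.max()), float(-dg.min())

    lo, hi = 1.05, 20.0
    r_lo = stats(lo)[1] / stats(lo)[0]
    r_hi = stats(hi)[1] / stats(hi)[0]
    target = float(np.clip(fall_over_rise, r_lo + 1e-9, r_hi - 1e-9))
    alpha = brentq(lambda a: stats(a)[1] / stats(a)[0] - target, lo, hi)
    return alpha, stats(alpha)[0]


def glucose_excursion(
    t: np.ndarray, dose: float, cfg: SyntheticConfig, delay_min: float
) -> np.ndarray:
    """Noise-free excursion: gamma-variate curve with dose-scaled amplitude.

    The gamma-variate ``(t/tp)^alpha * exp(alpha * (1 - t/tp))`` is smooth
    and causal with a single peak; alpha is chosen so the peak fall rate
    over peak rise rate matches ``fall_rate_per_dose / rise_rate_per_dose``
    and the peak time tp so the realized peak rise rate is
    ``rise_rate_per_dose * dose``. Because amplitude, rise rate and fall
    rate all scale with dose while the time constants do not, recovery time
    is dose-invariant.
    """
    if dose == 0:
        return np.zeros_like(t)
    amp = cfg.peak_amplitude_per_dose * dose
    rise = cfg.rise_rate_per_dose * dose
    fall = cfg.fall_rate_per_dose * dose
    alpha, peak_rise_shape = _gamma_shape_params(fall / rise)
    tp = amp * peak_rise_shape / rise  # minutes; dose cancels
    u = np.clip((t / 60.0 - delay_min) / tp, 0.0, None)
    with np.errstate(divide="ignore"):
        g = np.where(u > 0, u**alpha * np.exp(alpha * (1.0 - u)), 0.0)
    return amp * g


def simulate_glucose(
    dose: float, cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """One glucose trace (mg/dL, 1 Hz) and its ground-truth components."""
    t = cfg.t
    delay = cfg.absorption_delay_min + cfg.absorption_delay_jitter_min * rng.standard_normal()
    delay = max(delay, 0.5)
    excursion = glucose_excursion(t, dose, cfg, delay)
    noise = cfg.glucose_noise_sd * rng.standard_normal(t.size)
    spikes = _sparse_spikes(t.size, cfg.spike_rate_per_hour, cfg.spike_amplitude, rng)
    trace = cfg.glucose_baseline + excursion + noise + spikes
    dgdt = np.gradient(excursion) * 60.0  # mg/dL/min, noise-free
    truth = {
        "excursion": excursion,
        "dgdt_true": dgdt,
        "absorption_delay_min": delay,
    }
    return trace, truth


def anticipatory_shape(t: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Unit-depth first-phase template: smoothstep drop from the anticipatory
    onset to peak inhibition, then exponential recovery (values in [-1, 0])."""
    tm = t / 60.0
    u = np.clip((tm - cfg.anticipatory_onset) / cfg.anticipatory_ramp_min, 0.0, 1.0)
    ramp = u * u * (3.0 - 2.0 * u)
    t_min = cfg.anticipatory_onset + cfg.anticipatory_ramp_min
    rec = np.where(tm > t_min, np.exp(-(tm - t_min) / cfg.anticipatory_recovery_tau), 1.0)
    return -ramp * rec


def second_phase_component(dgdt: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Inhibition proportional to the positive glucose rate of change,
    delayed by ``second_phase_lag`` minutes (z-units, <= 0)."""
    drive = -cfg.second_phase_gain * np.clip(dgdt, 0.0, None)
    lag = int(round(cfg.second_phase_lag * 60.0))
    out = np.zeros_like(drive)
    if lag == 0:
        return drive
    out[lag:] = drive[:-lag]
    return out


def simulate_fp(
    dgdt_true: np.ndarray,
    dose: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    anticip_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two-channel photometry for one session.

    ``fp_signal`` = bleaching drift + shared motion + neural component
    (anticipatory + lagged second phase + 1/f noise, scaled into raw
    fluorescence units); ``fp_reference`` carries the same drift+motion
    artifact (scaled by ``reference_gain``) plus independent noise and *no*
    neural component.
    """
    t = cfg.t
    n = t.size
    anticipatory = anticip_scale * cfg.anticipatory_depth * anticipatory_shape(t, cfg)
    second = second_phase_component(dgdt_true, cfg)
    noise = _powerlaw_noise(n, cfg.fp_noise_exponent, cfg.fp_noise_sd, rng)
    neural = anticipatory + second

    drift = cfg.fp_baseline * np.exp(-cfg.bleach_rate * (t - t[0]) / 3600.0)
    if cfg.motion_sd > 0:
        motion = gaussian_filter1d(rng.standard_normal(n), sigma=5.0, mode="nearest")
        s = motion.std()
        motion *= cfg.motion_sd / s if s > 0 else 0.0
    else:
        motion = np.zeros(n)
    artifact = drift + motion

    spikes = _sparse_spikes(n, cfg.spike_rate_per_hour, cfg.fp_spike_amplitude, rng)
    fp_signal = artifact + cfg.neural_gain * (neural + noise) + spikes
    fp_reference = (
        cfg.reference_gain * artifact
        + cfg.reference_noise_sd * rng.standard_normal(n)
    )
    truth = {
        "anticipatory_z": anticipatory,
        "second_phase_z": second,
        "neural_z": neural,
        "anticip_scale": anticip_scale,
    }
    return fp_signal, fp_reference, truth


def simulate_session(
    subject_id: str,
    dose: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    session_order: int = 1,
) -> Session:
    """One complete synthetic session with ground-truth sidecar."""
    glucose, glu_truth = simulate_glucose(dose, cfg, rng)
    scale = (
        float(np.exp(cfg.anticipatory_scale_sd * rng.standard_normal()))
        if cfg.anticipatory_scale_sd > 0
        else 1.0
    )
    fp_signal, fp_reference, fp_truth = simulate_fp(
        glu_truth["dgdt_true"], dose, cfg, rng, anticip_scale=scale
    )
    return Session(
        subject_id=subject_id,
        dose=dose,
        t=cfg.t,
        fp_signal=fp_signal,
        fp_reference=fp_reference,
        glucose=glucose,
        session_order=session_order,
        ground_truth={**glu_truth, **fp_truth},
    )


def simulate_cohort(cfg: SyntheticConfig) -> list[Session]:
    """``n_subjects x len(doses)`` sessions, dose order randomized per subject.

    The same ``(cfg, cfg.seed)`` always reproduces the identical cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    sessions: list[Session] = []
    for i in range(cfg.n_subjects):
        subject = f"m{i + 1:02d}"
        order = rng.permutation(len(cfg.doses))
        for pos, j in enumerate(order):
            sessions.append(
                simulate_session(subject, cfg.doses[j], cfg, rng, session_order=pos + 1)
            )
    return sessions
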