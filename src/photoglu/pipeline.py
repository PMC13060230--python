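"""Cohort driver: run the full per-session analysis and assemble the
session table consumed by the report builder and the coupling analyses."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .early_model import EarlyModelConfig, EarlyModelFit, fit_early_model, residual_metrics
from .glucose import CleanConfig, GlucoseMetrics, OnsetConfig, analyze_glucose
from .photometry import FPConfig, PhotometryMetrics, analyze_fp
from .session_io import Session


@dataclass
class CohortAnalysis:
    """Everything the cohort-level statistics and coupling analyses need."""

    sessions: list[Session]
    table: pd.DataFrame                      # one row per session
    glucose_traces: list[dict[str, np.ndarray]]  # clean / delta / deriv
    z_traces: list[np.ndarray]               # Z_FP per session
    early: EarlyModelFit
    glucose_metrics: list[GlucoseMetrics] = field(default_factory=list)
    fp_metrics: list[PhotometryMetrics] = field(default_factory=list)


def analyze_cohort(
    sessions: list[Session],
    clean_cfg: CleanConfig | None = None,
    onset_cfg: OnsetConfig | None = None,
    fp_cfg: FPConfig | None = None,
    early_cfg: EarlyModelConfig | None = None,
    rng: np.random.Generator | None = None,
    spectral: bool = True,
) -> CohortAnalysis:
    """Glucose metrics, photometry metrics, and the early-model decomposition
    for every session, collected into one tidy table.

    ``spectral=False`` skips the pseudo-event spectral onset and PSD slope
    (the slowest per-session metrics) when only trace-level outputs are
    needed.
    """
    rng = rng or np.random.default_rng()
    fp_cfg = fp_cfg or FPConfig()
    early_cfg = early_cfg or EarlyModelConfig()

    glucose_metrics, glucose_traces, z_traces, fp_metrics = [], [], [], []
    for s in sessions:
        gm, traces = analyze_glucose(s, clean_cfg, onset_cfg)
        glucose_metrics.append(gm)
        glucose_traces.append(traces)
        if spectral:
            pm, z = analyze_fp(s, gm.peak_dG_time, fp_cfg, rng)
        else:
            from .photometry import preprocess_fp, response_metrics

            z = preprocess_fp(s, fp_cfg)
            pm = response_metrics(z, s.t, gm.peak_dG_time, fp_cfg)
        fp_metrics.append(pm)
        z_traces.append(z)

    early = fit_early_model(
        z_traces,
        [s.subject_id for s in sessions],
        [s.dose for s in sessions],
        sessions[0].t,
        early_cfg,
        rng,
    )

    rows = []
    for i, s in enumerate(sessions):
        gm, pm = glucose_metrics[i], fp_metrics[i]
        fit_row = early.session_fits.iloc[i]
        try:
            r_peak, r_time, r_neg = residual_metrics(early.residuals[i], s.t)
        except Exception:
            r_peak = r_time = r_neg = np.nan
        row = {
            "subject": s.subject_id,
            "dose": s.dose,
            "session_order": s.session_order,
            "baseline": gm.baseline,
            "beta0": fit_row["beta0"],
            "beta1": fit_row["beta1"],
            "early_r2": fit_row["r2"],
            "residual_peak": r_peak,
            "residual_peak_time": r_time,
            "residual_neg_auc": r_neg,
        }
        gm_dict = asdict(gm)
        gm_dict.pop("baseline")
        gm_dict.pop("reason")
        row.update(gm_dict)
        pm_dict = asdict(pm)
        pm_dict.pop("lf_p_curve")
        row.update(pm_dict)
        rows.append(row)

    return CohortAnalysis(
        sessions=sessions,
        table=pd.DataFrame(rows),
        glucose_traces=glucose_traces,
        z_traces=z_traces,
        early=early,
        glucose_metrics=glucose_metrics,
        fp_metrics=fp_metrics,
    )
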