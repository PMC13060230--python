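"""Session-level cohort statistics.

Two-sided Wilcoxon tests (signed-rank for paired, rank-sum / Mann-Whitney U
for unpaired comparisons), a one-sample Student t-test that also accepts
printed summary statistics (mean, SEM, n), ordinary least squares with
subject fixed effects and heteroskedasticity-consistent (HC3) standard
errors, and a report builder that assembles the dose / BG-metric /
photometry-metric comparison tables. The experimental unit is the subject;
subject fixed effects absorb between-animal offsets so slopes are
within-subject estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("photoglu")


@dataclass
class TestResult:
    statistic: float
    p: float
    df: float | None = None


# -- simple tests -----------------------------------------------------------


def one_sample_t(
    mean: float | None = None,
    sem: float | None = None,
    n: int | None = None,
    samples: np.ndarray | None = None,
) -> TestResult:
    """Two-sided one-sample Student t-test against zero.

    Accepts either raw ``samples`` or the printed summary statistics
    ``(mean, sem, n)``; in the latter case t = mean/sem with n - 1 degrees
    of freedom.
    """
    if samples is not None:
        samples = np.asarray(samples, dtype=float)
        if samples.size < 2:
            raise ValueError("need n >= 2 samples")
        t, p = stats.ttest_1samp(samples, 0.0)
        return TestResult(float(t), float(p), df=samples.size - 1)
    if mean is None or sem is None or n is None:
        raise ValueError("provide samples or all of (mean, sem, n)")
    if n < 2:
        raise ValueError("need n >= 2")
    if sem <= 0:
        raise ValueError("sem must be > 0")
    t = mean / sem
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(p), df=df)


def wilcoxon_paired(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal lengths")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult(0.0, 1.0)
    if nz.size < 3:
        raise ValueError("need >= 3 non-zero differences")
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return TestResult(float(res.statistic), float(res.pvalue))


def wilcoxon_unpaired(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test."""
    res = stats.mannwhitneyu(
        np.asarray(a, dtype=float), np.asarray(b, dtype=float), alternative="two-sided"
    )
    return TestResult(float(res.statistic), float(res.pvalue))


# -- OLS with subject fixed effects -----------------------------------------


@dataclass
class OLSResult:
    slope: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    r2: float
    n: int


def ols_fixed_effects(
    y: np.ndarray,
    x: np.ndarray,
    subject: np.ndarray,
    covariates: pd.DataFrame | dict | None = None,
) -> OLSResult:
    """Within-subject OLS slope of y on x with HC3 robust standard errors.

    Subject enters as indicator variables (fixed effects); optional
    covariate columns (e.g. dose, baseline glucose) are added untransformed.
    Raises on rank deficiency, naming the collinear column.
    """
    frame = pd.DataFrame({"y": np.asarray(y, float), "x": np.asarray(x, float)})
    frame["subject"] = np.asarray(subject)
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            frame[c] = np.asarray(cov[c], dtype=float)
    frame = frame.dropna()
    if frame["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects for fixed effects")

    dummies = pd.get_dummies(frame["subject"], prefix="subj", drop_first=True, dtype=float)
    cov_cols = [c for c in frame.columns if c not in ("y", "x", "subject")]
    X = pd.concat([frame[["x"] + cov_cols], dummies], axis=1)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # locate the first column whose removal restores full rank
        for c in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank:
                raise ValueError(f"design matrix is rank deficient: column {c!r} is collinear")
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(frame["y"].to_numpy(), X.to_numpy()).fit(cov_type="HC3")
    ix = list(X.columns).index("x")
    ci = fit.conf_int()[ix]
    return OLSResult(
        slope=float(fit.params[ix]),
        se=float(fit.bse[ix]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[ix]),
        r2=float(fit.rsquared),
        n=int(fit.nobs),
    )


# -- report builder ---------------------------------------------------------

#: (family, response, predictor, covariates) comparisons mirroring the
#: dose-response, early-invariance, residual and baseline-state analyses.
REPORT_PLAN: tuple[tuple[str, str, str, tuple[str, ...]], ...] = (
    ("dose_response", "peak_dG", "dose", ()),
    ("dose_response", "peak_deriv", "dose", ()),
    ("dose_response", "fall_rate", "dose", ()),
    ("dose_response", "iauc", "dose", ()),
    ("early_invariance", "peak_inhibition", "dose", ()),
    ("early_invariance", "peak_inhibition", "peak_dG", ()),
    ("early_invariance", "peak_inhibition", "peak_deriv", ()),
    ("early_invariance", "peak_inhibition", "fall_rate", ()),
    ("early_invariance", "neg_auc", "dose", ()),
    ("residual", "residual_peak", "peak_dG", ()),
    ("residual", "residual_peak", "peak_deriv", ()),
    ("residual", "residual_peak", "fall_rate", ()),
    ("baseline_state", "peak_deriv", "beta1", ("dose", "baseline")),
    ("baseline_state", "fall_rate", "beta1", ("dose", "baseline")),
)


def build_report(
    table: pd.DataFrame,
    plan: tuple = REPORT_PLAN,
    adjust_within_family: bool = False,
) -> pd.DataFrame:
    """Per-comparison slopes with robust SEs, CIs and p values.

    ``table`` is a session table with one row per session (subject, dose,
    glucose and photometry metrics, early-model coefficients). Comparisons
    with fewer than 3 complete rows, or without dose variation where dose is
    the predictor, are reported with NaN estimates. Session-level p values
    are unadjusted by default; ``adjust_within_family`` applies
    Benjamini-Hochberg within each declared family.
    """
    rows = []
    for family, response, predictor, covs in plan:
        cols = [response, predictor, "subject", *covs]
        if any(c not in table.columns for c in cols):
            continue
        sub = table[cols].dropna()
        row = {
            "family": family,
            "response": response,
            "predictor": predictor,
            "n": len(sub),
            "slope": np.nan, "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
            "r2": np.nan, "p": np.nan,
        }
        if len(sub) >= 3 and sub[predictor].nunique() > 1 and sub["subject"].nunique() >= 2:
            try:
                res = ols_fixed_effects(
                    sub[response], sub[predictor], sub["subject"],
                    covariates=sub[list(covs)] if covs else None,
                )
                row.update(
                    slope=res.slope, se=res.se, ci_low=res.ci_low,
                    ci_high=res.ci_high, r2=res.r2, p=res.p,
                )
            except ValueError as exc:
                logger.warning("comparison %s ~ %s skipped: %s", response, predictor, exc)
        rows.append(row)
    report = pd.DataFrame(rows)
    report["p_adj"] = report["p"]
    if adjust_within_family:
        for fam, idx in report.groupby("family").groups.items():
            mask = report.loc[idx, "p"].notna()
            if mask.any():
                _, adj, _, _ = multipletests(
                    report.loc[idx[mask], "p"], method="fdr_bh"
                )
                report.loc[idx[mask], "p_adj"] = adj
    return report
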