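"""Lagged Spearman cross-correlation with pseudosession nulls.

Per-session rank (Spearman) correlations between a photometry-derived
series and a glucose series are computed over a symmetric lag grid; lag
convention: positive lag means the photometry series *follows* the glucose
series. Group curves aggregate sessions through Fisher's z transform, and
per-lag significance is evaluated against pseudosession nulls (the
photometry trace paired with circular shifts of other sessions' glucose)
with Benjamini-Hochberg correction across the full lag family.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glucose import TraceError

logger = logging.getLogger("photoglu")


@dataclass
class CouplingConfig:
    max_lag: float = 20.0      # min, lags span [-max_lag, +max_lag]
    lag_step: float = 1.0      # s
    n_null: int = 200          # pseudosession pairings per session
    min_shift: float = 20.0    # min, minimum circular offset
    fdr_q: float = 0.05
    min_overlap: float = 10.0  # min, required overlap after shifting
    #: analysis window (min) applied by the cohort driver before
    #: correlating: the post-event response period. None = full session.
    window_min: tuple[float, float] | None = (0.0, 60.0)

    def __post_init__(self) -> None:
        if self.max_lag <= 0:
            raise ValueError("max_lag must be > 0")
        if self.min_shift < self.max_lag:
            logger.warning(
                "min_shift (%.0f min) below max_lag (%.0f min); null lags may "
                "overlap the true alignment", self.min_shift, self.max_lag,
            )

    @property
    def lags_s(self) -> np.ndarray:
        L = int(round(self.max_lag * 60.0))
        step = int(round(self.lag_step))
        return np.arange(-L, L + 1, step, dtype=int)


@dataclass
class CouplingResult:
    lags: np.ndarray                   # s
    rho: np.ndarray                    # (n_sessions, n_lags)
    rho_group: np.ndarray              # (n_lags,)
    null_rho: np.ndarray | None        # (n_null_total, n_lags)
    p_adj: np.ndarray | None           # BH-adjusted p per lag
    significant: np.ndarray | None     # p_adj < fdr_q
    peak_lag_s: float                  # lag of most negative group rho
    peak_rho: float


# -- per-lag Spearman -------------------------------------------------------


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def spearman_lagged_xcorr(
    x: np.ndarray, y: np.ndarray, cfg: CouplingConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """rho(lag) between x(t) and y(t - lag) on their overlapping support.

    A positive lag means x follows y. Lags where either overlapping slice is
    constant yield NaN. Returns ``(lags_s, rho)``.
    """
    cfg = cfg or CouplingConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise TraceError("series must share one time grid")
    n = x.size
    lags = cfg.lags_s
    need = int(cfg.min_overlap * 60.0)
    if n - lags[-1] < need:
        raise TraceError(
            f"series of {n} samples leave < {cfg.min_overlap:g} min overlap at "
            f"the largest lag"
        )
    rho = np.empty(lags.size)
    for j, lam in enumerate(lags):
        # pair x[i] with y[i - lam]
        if lam >= 0:
            xs, ys = x[lam:], y[: n - lam]
        else:
            xs, ys = x[: n + lam], y[-lam:]
        rho[j] = _spearman(xs, ys)
    return lags.astype(float), rho


# -- pseudosession nulls ----------------------------------------------------


def pseudosession_null(
    x: np.ndarray,
    glucose_pool: list[np.ndarray],
    cfg: CouplingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null rho(lag) samples: x paired with circularly shifted pool traces.

    Each of ``n_null`` pairings draws a partner trace uniformly from the
    pool and circularly shifts it by a uniform offset of at least
    ``min_shift`` minutes (in either direction around the circle).
    """
    cfg = cfg or CouplingConfig()
    rng = rng or np.random.default_rng()
    if not glucose_pool:
        raise TraceError("pseudosession pool is empty")
    n = x.size
    lo = int(cfg.min_shift * 60.0)
    hi = n - lo
    if hi <= lo:
        raise TraceError(
            f"pool traces of {n} samples too short for a {cfg.min_shift:g} min "
            "minimum circular shift"
        )
    out = np.empty((cfg.n_null, cfg.lags_s.size))
    for k in range(cfg.n_null):
        y = glucose_pool[int(rng.integers(len(glucose_pool)))]
        if y.size != n:
            raise TraceError("pool traces must share the session grid")
        shift = int(rng.integers(lo, hi))
        _, out[k] = spearman_lagged_xcorr(x, np.roll(y, shift), cfg)
    return out


# -- aggregation and significance -------------------------------------------


def aggregate_fisher(per_session_rho: np.ndarray) -> np.ndarray:
    """Group rho per lag: mean in Fisher z space mapped back with tanh."""
    r = np.atleast_2d(np.asarray(per_session_rho, dtype=float))
    if np.nanmax(np.abs(r)) >= 1.0:
        warnings.warn("clipping |rho| = 1 before the Fisher transform")
        r = np.clip(r, -1.0 + 1e-6, 1.0 - 1e-6)
    with np.errstate(invalid="ignore"):
        return np.tanh(np.nanmean(np.arctanh(r), axis=0))


def significance_per_lag(
    observed: np.ndarray,
    null: np.ndarray,
    cfg: CouplingConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided rank-sum test of observed vs null rho at each lag, with
    Benjamini-Hochberg adjustment across the whole lag grid as one family.

    Returns ``(p_adj, significant)``.
    """
    cfg = cfg or CouplingConfig()
    observed = np.atleast_2d(observed)
    if observed.shape[0] < 3:
        raise TraceError("need >= 3 observed sessions for the rank-sum test")
    if null.shape[0] < 20:
        raise TraceError("need >= 20 null samples per lag")
    n_lags = observed.shape[1]
    p = np.empty(n_lags)
    for j in range(n_lags):
        obs = observed[:, j]
        nul = null[:, j]
        obs = obs[np.isfinite(obs)]
        nul = nul[np.isfinite(nul)]
        if obs.size < 3 or nul.size < 20:
            p[j] = 1.0
            continue
        p[j] = stats.mannwhitneyu(obs, nul, alternative="two-sided").pvalue
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj, p_adj < cfg.fdr_q


def peak_lag(lags: np.ndarray, rho_group: np.ndarray) -> tuple[float, float]:
    """Lag of the most negative group rho (couplings here are inhibitory).

    Ties break toward the smallest |lag|; an exact +/-|lag| tie returns the
    negative lag.
    """
    finite = np.isfinite(rho_group)
    if not finite.any():
        raise TraceError("group rho is undefined at every lag")
    vmin = np.min(rho_group[finite])
    cands = lags[finite][rho_group[finite] == vmin]
    order = sorted(cands, key=lambda l: (abs(l), l))
    return float(order[0]), float(vmin)


# -- cohort driver ----------------------------------------------------------


def compute_coupling(
    fp_series: list[np.ndarray],
    glucose_series: list[np.ndarray],
    cfg: CouplingConfig | None = None,
    rng: np.random.Generator | None = None,
    with_null: bool = True,
    t: np.ndarray | None = None,
) -> CouplingResult:
    """Group lagged-coupling analysis for a set of paired sessions.

    ``fp_series[i]`` is correlated with ``glucose_series[i]`` at every lag;
    nulls pair each photometry trace with circular shifts of the *other*
    sessions' glucose traces. When the shared time axis ``t`` is given,
    every series is first restricted to ``cfg.window_min`` (the post-event
    response period by default) so slow pre-event and end-of-session
    structure does not dilute the response coupling.
    """
    cfg = cfg or CouplingConfig()
    rng = rng or np.random.default_rng()
    if len(fp_series) != len(glucose_series) or not fp_series:
        raise TraceError("need matching, non-empty fp and glucose session lists")
    if t is not None and cfg.window_min is not None:
        lo, hi = (60.0 * w for w in cfg.window_min)
        m = (t >= lo - 1e-9) & (t <= hi + 1e-9)
        fp_series = [x[m] for x in fp_series]
        glucose_series = [y[m] for y in glucose_series]
    lags = None
    rho = []
    for x, y in zip(fp_series, glucose_series):
        lags, r = spearman_lagged_xcorr(x, y, cfg)
        rho.append(r)
    rho = np.vstack(rho)
    rho_group = aggregate_fisher(rho)
    pk, pv = peak_lag(lags, rho_group)

    null_rho = p_adj = significant = None
    if with_null and len(fp_series) >= 2:
        nulls = []
        for i, x in enumerate(fp_series):
            pool = [y for j, y in enumerate(glucose_series) if j != i]
            nulls.append(pseudosession_null(x, pool, cfg, rng))
        null_rho = np.vstack(nulls)
        if rho.shape[0] >= 3:
            p_adj, significant = significance_per_lag(rho, null_rho, cfg)

    return CouplingResult(
        lags=lags,
        rho=rho,
        rho_group=rho_group,
        null_rho=null_rho,
        p_adj=p_adj,
        significant=significant,
        peak_lag_s=pk,
        peak_rho=pv,
    )
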