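"""Per-CpG ordinal trend testing across Gleason groups.

The trend statistic is the least-squares slope of β on the ordinal group
score (0/1/2), optionally adjusted for covariates, with a t test on
residual degrees of freedom. A rank-based Jonckheere–Terpstra variant is
available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

DMC_P_LADDER = (0.05, 0.01, 1e-3, 1e-4, 1e-5)

_DEGENERATE_TOL = 1e-14


class TrendError(ValueError):
    pass


@dataclass(frozen=True)
class TrendResult:
    cpg_id: str
    group_means: Tuple[float, ...]
    slope: float
    se: float
    t_stat: float
    p_trend: float
    direction: int
    degenerate: bool = False


@dataclass(frozen=True)
class DMCTabulation:
    """DMC counts over the fixed p-value ladder."""

    counts: Dict[float, int]
    fraction_increasing: float  # among sites passing the loosest rung
    n_total: int


def _design(scores: np.ndarray, covariates: Optional[pd.DataFrame]) -> np.ndarray:
    cols = [np.ones_like(scores, dtype=float), scores.astype(float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    return np.column_stack(cols)


def _check_scores(scores: np.ndarray, n_cov: int) -> None:
    if len(np.unique(scores)) < 2:
        raise TrendError("need at least 2 distinct ordinal scores")
    if len(scores) <= n_cov + 2:
        raise TrendError(
            f"n={len(scores)} too small for {n_cov} covariates plus trend"
        )


def trend_test_matrix(
    beta: pd.DataFrame,
    scores: Sequence[int],
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Vectorized trend test over all CpG rows sharing one design.

    Returns a DataFrame indexed by cpg_id with group means, slope, se,
    t_stat, p_trend, direction and a degenerate flag.
    """
    scores = np.asarray(scores)
    n_cov = 0 if covariates is None else np.asarray(covariates).reshape(len(scores), -1).shape[1]
    _check_scores(scores, n_cov)
    x = _design(scores, covariates)
    n, p = x.shape
    xtx = x.T @ x
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        raise TrendError("singular design matrix") from None
    if np.linalg.cond(xtx) > 1e12:
        raise TrendError("singular design matrix")

    y = beta.to_numpy(float)
    coef = y @ x @ xtx_inv  # G × p
    resid = y - coef @ x.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    slope = coef[:, 1]
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))

    degenerate = np.ptp(y, axis=1) < _DEGENERATE_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf * np.sign(slope))
    p_trend = 2.0 * stats.t.sf(np.abs(t), dof)
    p_trend = np.clip(p_trend, 1e-300, 1.0)
    slope = np.where(degenerate, 0.0, slope)
    t = np.where(degenerate, 0.0, t)
    p_trend = np.where(degenerate, 1.0, p_trend)

    out = pd.DataFrame(index=beta.index.copy())
    for level in sorted(np.unique(scores)):
        out[f"mean_s{level}"] = y[:, scores == level].mean(axis=1)
    out["slope"] = slope
    out["se"] = se
    out["t_stat"] = t
    out["p_trend"] = p_trend
    out["direction"] = np.sign(slope).astype(int)
    out["degenerate"] = degenerate
    return out


def trend_test(
    beta_row: Sequence[float],
    scores: Sequence[int],
    covariates: Optional[pd.DataFrame] = None,
    cpg_id: str = "",
) -> TrendResult:
    """Single-row convenience wrapper around :func:`trend_test_matrix`."""
    row = pd.DataFrame([np.asarray(beta_row, dtype=float)], index=[cpg_id or "row"])
    res = trend_test_matrix(row, scores, covariates).iloc[0]
    means = tuple(res[c] for c in res.index if str(c).startswith("mean_s"))
    return TrendResult(
        cpg_id=cpg_id,
        group_means=means,
        slope=float(res["slope"]),
        se=float(res["se"]),
        t_stat=float(res["t_stat"]),
        p_trend=float(res["p_trend"]),
        direction=int(res["direction"]),
        degenerate=bool(res["degenerate"]),
    )


def jonckheere_terpstra(beta_row: Sequence[float], scores: Sequence[int]) -> float:
    """Two-sided normal-approximation Jonckheere–Terpstra p value
    (rank-based sensitivity alternative to the slope test)."""
    y = np.asarray(beta_row, dtype=float)
    s = np.asarray(scores)
    levels = np.sort(np.unique(s))
    if len(levels) < 2:
        raise TrendError("need at least 2 distinct ordinal scores")
    j_stat = 0.0
    groups = [y[s == lv] for lv in levels]
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i], groups[j]
            gt = (b[None, :] > a[:, None]).sum()
            eq = (b[None, :] == a[:, None]).sum()
            j_stat += gt + 0.5 * eq
    ns = np.array([len(g) for g in groups])
    n = ns.sum()
    mean = (n**2 - (ns**2).sum()) / 4.0
    var = (n**2 * (2 * n + 3) - (ns**2 * (2 * ns + 3)).sum()) / 72.0
    z = (j_stat - mean) / np.sqrt(var)
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))


def global_trend(
    beta: pd.DataFrame, scores: Sequence[int]
) -> Tuple[Dict[int, float], float]:
    """Trend in per-sample grand-mean methylation.

    Returns ({score: group mean of per-sample mean β}, two-sided p).
    """
    scores = np.asarray(scores)
    sample_means = beta.to_numpy(float).mean(axis=0)
    levels = sorted(np.unique(scores))
    if any((scores == lv).sum() == 0 for lv in levels):
        raise TrendError("empty Gleason group")
    res = trend_test(sample_means, scores, covariates=None)
    group_means = {int(lv): float(sample_means[scores == lv].mean()) for lv in levels}
    return group_means, res.p_trend


def tabulate_dmcs(results: pd.DataFrame) -> DMCTabulation:
    """Count significant sites along the fixed threshold ladder and the
    fraction increasing among sites passing the loosest rung."""
    if len(results) == 0:
        raise TrendError("no trend results to tabulate")
    p = results["p_trend"].to_numpy(float)
    direction = results["direction"].to_numpy(int)
    counts = {thr: int((p < thr).sum()) for thr in DMC_P_LADDER}
    loose = p < max(DMC_P_LADDER)
    frac = float((direction[loose] > 0).mean()) if loose.any() else float("nan")
    return DMCTabulation(counts=counts, fraction_increasing=frac, n_total=len(results))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise TrendError(f"n_tests must be >= 1, got {n_tests}")
    if not 0.0 < alpha < 1.0:
        raise TrendError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / n_tests


def round_sigfigs(x: float, sigfigs: int) -> float:
    """Round to a number of significant figures (for printed thresholds)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sigfigs - 1)
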