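"""Cox proportional-hazards association of dichotomized methylation with
biochemical recurrence.

The partial likelihood (Efron tie correction by default, Breslow
available) is maximized by Newton iterations with step halving. Wald
inference throughout: CI = exp(coef ± 1.96·se).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

Z95 = stats.norm.ppf(0.975)

PSA_LEVELS = ("lt10", "10to20", "ge20")
STAGE_COLLAPSED = ("T1", "T2", "T3T4")
TREATMENT_LEVELS = ("surgery", "radiation", "other")
GLEASON_LEVELS = ("GS6", "GS7", "GS8plus")


class SurvivalError(ValueError):
    pass


@dataclass(frozen=True)
class CoxResult:
    cpg_id: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    n_events: int
    converged: bool
    degenerate: bool = False


def dichotomize(beta_row: Sequence[float]) -> Tuple[np.ndarray, bool]:
    """High/low split at the sample median.

    High means strictly above the median; ties at the median fall in the
    low (reference) group. Returns (0/1 vector, degenerate flag); a
    constant row is all-low and flagged.
    """
    v = np.asarray(beta_row, dtype=float)
    if len(v) < 2:
        raise SurvivalError("need at least 2 samples to dichotomize")
    high = (v > np.median(v)).astype(int)
    return high, bool(high.sum() == 0 or high.sum() == len(v))


def _partial_loglik(
    beta: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    x: np.ndarray,
    ties: str,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and Hessian.

    Processes times from largest to smallest, maintaining running risk-set
    sums S0 = Σ w, S1 = Σ w·x, S2 = Σ w·xxᵀ.
    """
    order = np.argsort(-times, kind="mergesort")
    t, d, xs = times[order], events[order], x[order]
    eta = xs @ beta
    eta = eta - eta.max()  # guard overflow; cancels in ratios below
    w = np.exp(eta)
    p = x.shape[1]
    s0, s1 = 0.0, np.zeros(p)
    s2 = np.zeros((p, p))
    ll, grad = 0.0, np.zeros(p)
    hess = np.zeros((p, p))
    i, n = 0, len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        block = slice(i, j)
        wb = w[block]
        s0 += wb.sum()
        s1 += wb @ xs[block]
        s2 += (xs[block] * wb[:, None]).T @ xs[block]
        ev = d[block] == 1
        nd = int(ev.sum())
        if nd > 0:
            xd = xs[block][ev]
            wd = wb[ev]
            ll += float(eta[block][ev].sum())
            grad += xd.sum(axis=0)
            d0 = wd.sum()
            d1 = wd @ xd
            d2 = (xd * wd[:, None]).T @ xd
            for el in range(nd):
                if ties == "efron":
                    f = el / nd
                else:  # breslow
                    f = 0.0
                r0 = s0 - f * d0
                r1 = s1 - f * d1
                r2 = s2 - f * d2
                ll -= float(np.log(r0))
                mu = r1 / r0
                grad -= mu
                hess -= r2 / r0 - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def fit_cox(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
    ties: str = "efron",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Fit the Cox model and return per-covariate Wald summaries.

    Returns a DataFrame indexed by covariate name with columns coef, se,
    hr, ci_low, ci_high, p, plus ``attrs``: converged, n_events, loglik.
    Monotone likelihood (complete separation) is reported via
    converged=False, never an exception; a singular design is an error.
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown ties method {ties!r}")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = covariates.to_numpy(dtype=float)
    if x.ndim != 2 or x.shape[0] != len(times):
        raise SurvivalError("covariate table must be n × p")
    if events.sum() < 1:
        raise SurvivalError("need at least one event")
    constant = [c for c in covariates.columns if covariates[c].nunique() <= 1]
    if constant:
        raise SurvivalError(f"constant covariate(s): {constant}")

    p = x.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _partial_loglik(beta, times, events, x, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            raise SurvivalError("singular design in Cox fit") from None
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new, grad_new, hess_new = _partial_loglik(candidate, times, events, x, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, rel = candidate, abs(ll_new - ll) / (abs(ll) + 1.0)
        ll, grad, hess = ll_new, grad_new, hess_new
        if rel < tol:
            converged = True
            break
    if np.abs(beta).max() > 15.0 or not np.all(np.isfinite(beta)):
        converged = False  # monotone likelihood / separation

    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        if np.nanmax(se) > 50.0:  # flat likelihood: separation symptom
            converged = False
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.nan)
        pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        out = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - Z95 * se),
                "ci_high": np.exp(beta + Z95 * se),
                "p": pvals,
            },
            index=covariates.columns,
        )
    out.attrs["converged"] = converged
    out.attrs["n_events"] = int(events.sum())
    out.attrs["loglik"] = float(ll)
    return out


def _dummies(values: pd.Series, levels: Sequence[str], prefix: str) -> pd.DataFrame:
    """Drop-first dummy encoding with a fixed level order."""
    out = {}
    for level in levels[1:]:
        out[f"{prefix}_{level}"] = (values == level).astype(float)
    return pd.DataFrame(out, index=values.index)


def clinical_covariates(
    cohort: pd.DataFrame,
    variables: Sequence[str] = ("age", "psa_class", "gleason_group", "stage", "treatment"),
) -> pd.DataFrame:
    """Encode clinical adjustment covariates.

    age continuous; PSA class, Gleason group and treatment as drop-first
    dummies; stage collapsed to T1/T2/T3+T4 (T3 and T4 are sparse).
    """
    parts: List[pd.DataFrame] = []
    for var in variables:
        if var == "age":
            parts.append(cohort[["age"]].astype(float))
        elif var == "psa_class":
            parts.append(_dummies(cohort["psa_class"], PSA_LEVELS, "psa"))
        elif var == "gleason_group":
            parts.append(_dummies(cohort["gleason_group"], GLEASON_LEVELS, "gs"))
        elif var == "stage":
            collapsed = cohort["stage"].replace({"T3": "T3T4", "T4": "T3T4"})
            parts.append(_dummies(collapsed, STAGE_COLLAPSED, "stage"))
        elif var == "treatment":
            parts.append(_dummies(cohort["treatment"], TREATMENT_LEVELS, "treat"))
        else:
            raise SurvivalError(f"unknown clinical variable {var!r}")
    return pd.concat(parts, axis=1)


def bcr_association(
    beta: pd.DataFrame,
    dmc_ids: Sequence[str],
    cohort: pd.DataFrame,
    adjust: Sequence[str] = ("age", "psa_class", "gleason_group", "stage", "treatment"),
    ties: str = "efron",
) -> List[CoxResult]:
    """Median-dichotomized Cox association of each candidate CpG with BCR.

    Per-CpG non-convergence and degenerate (constant) rows are reported as
    flags on the result, not raised.
    """
    for col in ("bcr_time", "bcr_event"):
        if col not in cohort.columns:
            raise SurvivalError(f"cohort lacks {col!r}")
    clin = clinical_covariates(cohort, variables=adjust) if adjust else None
    times = cohort["bcr_time"].to_numpy(float)
    events = cohort["bcr_event"].to_numpy(int)
    results: List[CoxResult] = []
    for cid in dmc_ids:
        if cid not in beta.index:
            raise SurvivalError(f"CpG {cid!r} not in beta matrix")
        row = beta.loc[cid, cohort.index].to_numpy(float)
        high, degenerate = dichotomize(row)
        if degenerate:
            results.append(
                CoxResult(cid, float("nan"), float("nan"), float("nan"), 1.0,
                          float("nan"), float("nan"), int(events.sum()),
                          converged=False, degenerate=True)
            )
            continue
        cov = pd.DataFrame({"high_methylation": high.astype(float)}, index=cohort.index)
        if clin is not None:
            extra = clin.loc[:, clin.nunique() > 1]  # drop empty categories
            cov = pd.concat([cov, extra], axis=1)
        fit = fit_cox(times, events, cov, ties=ties)
        r = fit.loc["high_methylation"]
        results.append(
            CoxResult(
                cpg_id=cid,
                hr=float(r["hr"]),
                ci_low=float(r["ci_low"]),
                ci_high=float(r["ci_high"]),
                p=float(r["p"]),
                coef=float(r["coef"]),
                se=float(r["se"]),
                n_events=fit.attrs["n_events"],
                converged=bool(fit.attrs["converged"]),
            )
        )
    return results


def cox_results_to_frame(results: List[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cpg_id": [r.cpg_id for r in results],
            "hr": [r.hr for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p": [r.p for r in results],
            "coef": [r.coef for r in results],
            "se": [r.se for r in results],
            "n_events": [r.n_events for r in results],
            "converged": [r.converged for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    ).set_index("cpg_id")
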