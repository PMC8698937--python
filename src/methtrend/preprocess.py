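"""Batch-effect adjustment and reference-based cell-type deconvolution.

The batch adjustment is a parametric empirical-Bayes location/scale
correction performed on logit(β) and back-transformed, so output stays in
[0, 1]. Deconvolution solves a nonnegativity- and sum-constrained least
squares projection of each sample onto reference cell-type signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from scipy.special import expit, logit

from .synthetic_data import BETA_CLIP, DEFAULT_CELL_TYPES, cell_proportion_columns


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

def _eb_iterate(
    z: np.ndarray,
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    gamma_bar: float,
    tau2: float,
    a_prior: float,
    b_prior: float,
    n_b: int,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> Tuple[np.ndarray, np.ndarray]:
    """Iterative solution of the parametric posterior (normal location,
    inverse-gamma scale) for one batch. z is CpG × batch-samples."""
    gamma = gamma_hat.copy()
    delta = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n_b * tau2 * gamma_hat + delta * gamma_bar) / (n_b * tau2 + delta)
        resid2 = ((z - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (b_prior + 0.5 * resid2) / (n_b / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(gamma_new - gamma).max() / (np.abs(gamma).max() + 1e-12),
            np.abs(delta_new - delta).max() / (np.abs(delta).max() + 1e-12),
        )
        gamma, delta = gamma_new, delta_new
        if change < tol:
            break
    return gamma, delta


def adjust_batch(
    beta: pd.DataFrame,
    batch: Sequence[str],
    parametric: bool = True,
) -> pd.DataFrame:
    """Remove additive/multiplicative batch effects from a β matrix.

    Per CpG, logit values are standardized against the batch-size-weighted
    grand mean and pooled variance; per-batch location and scale estimates
    are shrunk toward their across-CpG moments under parametric priors and
    divided out. The weighted grand mean on the logit scale is restored
    exactly, so balanced designs keep their per-CpG average.
    """
    if not parametric:
        raise NotImplementedError("nonparametric priors are not implemented")
    batch = np.asarray(batch)
    if len(batch) != beta.shape[1]:
        raise PreprocessError(
            f"batch labels ({len(batch)}) do not match samples ({beta.shape[1]})"
        )
    levels, inverse = np.unique(batch, return_inverse=True)
    counts = np.bincount(inverse)
    if len(levels) < 2:
        warnings.warn("single batch: adjust_batch is the identity", UserWarning)
        return beta.copy()
    if counts.min() < 2:
        small = levels[np.argmin(counts)]
        raise PreprocessError(f"batch {small!r} has fewer than 2 samples")

    y = logit(np.clip(beta.to_numpy(float), BETA_CLIP, 1 - BETA_CLIP))
    n = y.shape[1]
    weights = counts / n

    batch_means = np.stack(
        [y[:, inverse == b].mean(axis=1) for b in range(len(levels))], axis=1
    )
    grand = batch_means @ weights  # per-CpG weighted grand mean
    fitted = batch_means[:, inverse]
    var_pooled = ((y - fitted) ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)
    z = (y - grand[:, None]) / sd[:, None]

    z_adj = np.empty_like(z)
    for b in range(len(levels)):
        cols = inverse == b
        zb = z[:, cols]
        n_b = int(counts[b])
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1)) if len(gamma_hat) > 1 else 1.0
        tau2 = max(tau2, 1e-12)
        m = float(delta_hat.mean())
        s2 = float(delta_hat.var(ddof=1)) if len(delta_hat) > 1 else 1.0
        s2 = max(s2, 1e-12)
        a_prior = (2.0 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        gamma_star, delta_star = _eb_iterate(
            zb, gamma_hat, delta_hat, gamma_bar, tau2, a_prior, b_prior, n_b
        )
        delta_star = np.maximum(delta_star, 1e-12)  # constant rows → δ*=0
        z_adj[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    y_adj = z_adj * sd[:, None] + grand[:, None]
    # restore the grand mean exactly (shrinkage leaves a tiny drift); the
    # batch-size-weighted mean of batch means is the plain sample mean
    drift = y_adj.mean(axis=1) - grand
    y_adj -= drift[:, None]
    out = np.clip(expit(y_adj), BETA_CLIP, 1 - BETA_CLIP)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# Cell-type deconvolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellReference:
    """Reference β signature: marker CpGs × cell types."""

    signature: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.signature.to_numpy(float)
        if s.shape[0] < s.shape[1]:
            raise PreprocessError(
                f"need at least as many markers ({s.shape[0]}) as cell types ({s.shape[1]})"
            )
        if (s < 0).any() or (s > 1).any():
            raise PreprocessError("reference signature entries must lie in [0, 1]")
        if np.linalg.matrix_rank(s) < s.shape[1]:
            raise PreprocessError("reference signature is rank deficient")

    @property
    def marker_ids(self) -> List[str]:
        return list(self.signature.index)

    @property
    def cell_types(self) -> List[str]:
        return list(self.signature.columns)


def synthetic_reference(
    n_markers: int = 100,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    seed: int = 2024,
) -> CellReference:
    """Deterministic synthetic reference panel (stand-in for real sorted-cell
    methylomes, which are out of scope). Each marker is highly methylated in
    one discriminating type and lowly in the rest, plus mild jitter."""
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    sig = rng.uniform(0.05, 0.25, size=(n_markers, k))
    owner = np.arange(n_markers) % k
    sig[np.arange(n_markers), owner] = rng.uniform(0.7, 0.95, size=n_markers)
    sig = np.clip(sig + rng.normal(0, 0.02, size=sig.shape), 0.01, 0.99)
    index = pd.Index([f"mk{i + 1:05d}" for i in range(n_markers)], name="cpg_id")
    return CellReference(pd.DataFrame(sig, index=index, columns=list(cell_types)))


def _project_simplex(s: np.ndarray, r: np.ndarray) -> np.ndarray:
    """argmin ‖r − S w‖² s.t. w ≥ 0, Σw ≤ 1."""
    w, _ = nnls(s, r)
    if w.sum() <= 1.0 + 1e-9:
        return w
    k = s.shape[1]
    x0 = w / w.sum()

    def objective(x):
        d = s @ x - r
        return float(d @ d), 2.0 * s.T @ d

    res = minimize(
        objective,
        x0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                      "jac": lambda x: -np.ones(k)}],
        options={"ftol": 1e-14, "maxiter": 500},
    )
    return np.maximum(res.x, 0.0)


def estimate_cell_proportions(beta: pd.DataFrame, reference: CellReference) -> pd.DataFrame:
    """Constrained-least-squares leukocyte composition per sample.

    Returns samples × cell types; 1 − row sum is the unexplained residual.
    Deterministic and invariant to sample order.
    """
    missing = [m for m in reference.marker_ids if m not in beta.index]
    if missing:
        raise PreprocessError(f"beta matrix missing marker CpGs: {missing[:5]}...")
    s = reference.signature.to_numpy(float)
    sub = beta.loc[reference.marker_ids].to_numpy(float)
    w = np.stack([_project_simplex(s, sub[:, j]) for j in range(sub.shape[1])])
    return pd.DataFrame(w, index=beta.columns, columns=reference.cell_types)


def build_covariate_matrix(
    cohort: pd.DataFrame,
    proportions: Optional[pd.DataFrame] = None,
    clinical: Sequence[str] = (),
) -> pd.DataFrame:
    """Assemble the covariate table used by the trend model.

    Cell proportions contribute K−1 columns (the largest-mean type is
    dropped against collinearity with the simplex constraint); requested
    clinical variables are encoded as in the survival module (age
    continuous, categories as drop-first dummies). Constant columns are
    kept but flagged in ``attrs['constant_columns']``.
    """
    from .survival_analysis import clinical_covariates  # local import: avoid cycle

    parts = []
    if proportions is not None:
        props = proportions.reindex(cohort.index)
        if props.isna().any().any():
            raise PreprocessError("sample ids in proportions do not match cohort")
        drop = props.mean().idxmax()
        parts.append(props.drop(columns=[drop]))
    if clinical:
        parts.append(clinical_covariates(cohort, variables=clinical))
    if not parts:
        out = pd.DataFrame(index=cohort.index)
    else:
        out = pd.concat(parts, axis=1)
    constant = [c for c in out.columns if out[c].nunique() <= 1]
    out.attrs["constant_columns"] = constant
    return out
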