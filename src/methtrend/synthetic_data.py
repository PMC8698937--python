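"""Synthetic EPIC-like data generator.

Produces manifests, cohorts, β matrices with spiked trend effects and
clustered region blocks, batch shifts, cell-type mixtures and linked
survival outcomes — everything the downstream analysis assumes, fully
deterministic given a seed.

Effects are injected on the logit scale so β stays inside (0, 1); the
analysis modules consume β directly and are agnostic to how effects were
injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .manifest_io import (
    CANONICAL_CHROMS,
    GENE_REGIONS,
    ISLAND_RELATIONS,
    CpGSite,
    Manifest,
)

# ---------------------------------------------------------------------------
# Cohort defaults: category counts for a 280-patient cohort
# ---------------------------------------------------------------------------

GLEASON_GROUPS = ("GS6", "GS7", "GS8plus")
GLEASON_SCORES = {"GS6": 0, "GS7": 1, "GS8plus": 2}

DEFAULT_GROUP_COUNTS = {"GS6": 82, "GS7": 162, "GS8plus": 36}
SMOKING_COUNTS = {"never": 162, "former": 84, "current": 34}
BMI_COUNTS = {"lt25": 33, "25to30": 86, "ge30": 115}
STAGE_COUNTS = {"T1": 162, "T2": 101, "T3": 11, "T4": 6}
PSA_COUNTS = {"lt10": 216, "10to20": 39, "ge20": 25}
TREATMENT_FREQS = {"surgery": 0.6, "radiation": 0.3, "other": 0.1}

DEFAULT_CELL_TYPES = ("Gran", "CD4T", "CD8T", "Bcell", "NK", "Mono")
DEFAULT_CELL_MEANS = (0.55, 0.15, 0.10, 0.08, 0.05, 0.07)

# calibration targets: grand mean β per annotation category
ISLAND_RELATION_MEANS = {
    "Island": 0.189,
    "Shore": 0.420,
    "Shelf": 0.645,
    "OpenSea": 0.625,
}
GENE_REGION_MEANS = {
    "TSS200": 0.187,
    "Exon1": 0.218,
    "TSS1500": 0.378,
    "UTR5": 0.417,
    "IGR": 0.566,
    "Body": 0.608,
    "UTR3": 0.653,
}

DEFAULT_ISLAND_PROPORTIONS = {"Island": 0.19, "Shore": 0.25, "Shelf": 0.10, "OpenSea": 0.46}
DEFAULT_REGION_PROPORTIONS = {
    "TSS200": 0.12,
    "TSS1500": 0.16,
    "Exon1": 0.10,
    "UTR5": 0.16,
    "Body": 0.27,
    "UTR3": 0.03,
    "IGR": 0.16,
}

# mean intra-run spacing (bp) per island relation; islands are tight so
# gap-pass region scenarios arise naturally, open sea is sparse so gap-fail
# scenarios arise too
DEFAULT_GAP_MEANS = {"Island": 80.0, "Shore": 400.0, "Shelf": 1500.0, "OpenSea": 5000.0}

DEFAULT_SITE_SD = 1.2  # per-CpG baseline spread on the logit scale
DEFAULT_NOISE_SD = 0.3  # per-observation logit noise

BETA_CLIP = 1e-6  # keep β away from exact 0/1


def category_percent(counts: Mapping[str, int], key: str, ndigits: int = 1) -> float:
    """Percentage of one category among the recorded counts, rounded."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return round(100.0 * counts[key] / total, ndigits)


# ---------------------------------------------------------------------------
# Context-offset calibration
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)


def _mean_expit(m: np.ndarray, sd: float) -> np.ndarray:
    """E[expit(m + sd·Z)], Z ~ N(0,1), by Gauss–Hermite quadrature."""
    m = np.asarray(m, dtype=float)
    z = np.sqrt(2.0) * sd * _GH_NODES
    vals = expit(m[..., None] + z)
    return vals @ _GH_WEIGHTS / np.sqrt(np.pi)


def _solve_offset(target: float, extra: np.ndarray, weights: np.ndarray, sd: float) -> float:
    """Solve m such that Σ w_c · E[expit(m + extra_c + sd·Z)] = target."""

    def f(m: float) -> float:
        return float(weights @ _mean_expit(m + extra, sd)) - target

    return brentq(f, -25.0, 25.0, xtol=1e-12)


@lru_cache(maxsize=32)
def calibrate_context_offsets(
    island_props: tuple,
    region_props: tuple,
    island_targets: tuple,
    region_targets: tuple,
    sd: float,
    n_iter: int = 30,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Jointly calibrate additive logit offsets per island relation and gene
    region so that marginal mean β matches the targets under N(0, sd²)
    site/noise spread.

    Alternates marginal solves (island-relation pass last, so those targets
    are matched exactly in expectation). Inputs are tuples of (name, value)
    pairs for hashability.
    """
    ip = dict(island_props)
    rp = dict(region_props)
    it = dict(island_targets)
    rt = dict(region_targets)
    isl_names = list(ip)
    reg_names = list(rp)
    w_isl = np.array([ip[k] for k in isl_names])
    w_reg = np.array([rp[k] for k in reg_names])
    a = {k: float(logit(it[k])) for k in isl_names}
    d = {k: 0.0 for k in reg_names}
    for _ in range(n_iter):
        a_vec = np.array([a[k] for k in isl_names])
        for r in reg_names:
            d[r] = _solve_offset(rt[r], a_vec, w_isl, sd)
        d_vec = np.array([d[k] for k in reg_names])
        for i in isl_names:
            a[i] = _solve_offset(it[i], d_vec, w_reg, sd)
    return a, d


# ---------------------------------------------------------------------------
# Manifest generation
# ---------------------------------------------------------------------------

def generate_manifest(
    n_cpgs: int,
    chrom_count: int = 22,
    context_proportions: Optional[Mapping[str, float]] = None,
    region_proportions: Optional[Mapping[str, float]] = None,
    gap_means: Optional[Mapping[str, float]] = None,
    mean_run_length: float = 8.0,
    between_run_gap: int = 20_000,
    seed: int = 0,
) -> Manifest:
    """Generate an EPIC-like manifest with clustered annotation context.

    Sites are laid down in runs of a shared island relation; intra-run
    spacing is geometric with a context-specific mean so island CpGs sit
    closer together than open-sea CpGs. Positions are strictly increasing
    per chromosome.
    """
    if n_cpgs < 1:
        raise ValueError(f"n_cpgs must be >= 1, got {n_cpgs}")
    if not 1 <= chrom_count <= len(CANONICAL_CHROMS):
        raise ValueError(f"chrom_count must be in [1, {len(CANONICAL_CHROMS)}]")
    ctx = dict(context_proportions or DEFAULT_ISLAND_PROPORTIONS)
    reg = dict(region_proportions or DEFAULT_REGION_PROPORTIONS)
    gaps = dict(gap_means or DEFAULT_GAP_MEANS)
    for props, names in ((ctx, ISLAND_RELATIONS), (reg, GENE_REGIONS)):
        if set(props) != set(names):
            raise ValueError(f"proportions must cover exactly {names}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")

    rng = np.random.default_rng(seed)
    isl_names = list(ctx)
    isl_p = np.array([ctx[k] for k in isl_names])
    reg_names = list(reg)
    reg_p = np.array([reg[k] for k in reg_names])

    # spread sites across chromosomes as evenly as possible
    per_chrom = np.full(chrom_count, n_cpgs // chrom_count)
    per_chrom[: n_cpgs % chrom_count] += 1

    sites: List[CpGSite] = []
    counter = 0
    run_index = 0
    for ci in range(chrom_count):
        chrom = CANONICAL_CHROMS[ci]
        remaining = int(per_chrom[ci])
        pos = 10_000
        while remaining > 0:
            run_index += 1
            relation = isl_names[rng.choice(len(isl_names), p=isl_p)]
            length = min(remaining, 1 + rng.geometric(1.0 / mean_run_length))
            symbol = f"G{chrom}R{run_index}"
            pos += between_run_gap + int(rng.integers(0, between_run_gap))
            for j in range(length):
                if j > 0:
                    pos += int(rng.geometric(1.0 / gaps[relation]))
                region = reg_names[rng.choice(len(reg_names), p=reg_p)]
                counter += 1
                sites.append(
                    CpGSite(
                        cpg_id=f"cg{counter:08d}",
                        chrom=chrom,
                        pos=pos,
                        island_relation=relation,
                        gene_region=region,
                        gene_symbol=None if region == "IGR" else symbol,
                    )
                )
            remaining -= length
    return Manifest(sites)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Sizes and structure of a simulated cohort."""

    n_samples: int = 280
    group_counts: Tuple[int, int, int] = (82, 162, 36)  # GS6, GS7, GS8plus
    n_batches: int = 2
    cell_types: Tuple[str, ...] = DEFAULT_CELL_TYPES
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.group_counts) != self.n_samples:
            raise ValueError(
                f"group_counts {self.group_counts} sum to {sum(self.group_counts)}, "
                f"expected n_samples={self.n_samples}"
            )
        if len(self.cell_types) < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


def _draw_categories(rng, counts: Mapping[str, int], n: int) -> np.ndarray:
    names = list(counts)
    p = np.array([counts[k] for k in names], dtype=float)
    p /= p.sum()
    return np.array(names)[rng.choice(len(names), size=n, p=p)]


def generate_cohort(
    spec: CohortSpec,
    cell_means: Optional[Sequence[float]] = None,
    cell_concentration: float = 50.0,
    baseline_event_rate: float = 1 / 60.0,
    baseline_censor_rate: float = 1 / 90.0,
) -> pd.DataFrame:
    """Simulate a sample sheet with exact Gleason-group sizes.

    Clinical covariates are drawn from the default category frequencies;
    cell proportions are Dirichlet around ``cell_means``. BCR time/event
    start as a null (methylation-independent) survival outcome; use
    :func:`generate_survival` to link them to a CpG.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    groups = np.repeat(GLEASON_GROUPS, spec.group_counts)
    scores = np.array([GLEASON_SCORES[g] for g in groups])
    perm = rng.permutation(n)
    groups, scores = groups[perm], scores[perm]

    means = np.asarray(
        cell_means if cell_means is not None else DEFAULT_CELL_MEANS[: len(spec.cell_types)],
        dtype=float,
    )
    if len(means) != len(spec.cell_types):
        raise ValueError("cell_means length must match cell_types")
    means = means / means.sum()
    props = rng.dirichlet(cell_concentration * means, size=n)

    age = np.clip(np.round(rng.normal(58.0, 8.0, size=n)), 39, 83).astype(int)
    treat_names = list(TREATMENT_FREQS)
    treat_p = np.array([TREATMENT_FREQS[k] for k in treat_names])
    event_t = rng.exponential(1.0 / baseline_event_rate, size=n)
    censor_t = rng.exponential(1.0 / baseline_censor_rate, size=n)

    df = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "gleason_group": groups,
            "score": scores,
            "age": age,
            "smoking": _draw_categories(rng, SMOKING_COUNTS, n),
            "bmi_class": _draw_categories(rng, BMI_COUNTS, n),
            "stage": _draw_categories(rng, STAGE_COUNTS, n),
            "psa_class": _draw_categories(rng, PSA_COUNTS, n),
            "treatment": np.array(treat_names)[rng.choice(len(treat_names), size=n, p=treat_p)],
            "batch": [f"B{1 + i % spec.n_batches}" for i in rng.permutation(n)],
            "bcr_time": np.minimum(event_t, censor_t),
            "bcr_event": (event_t <= censor_t).astype(int),
        }
    )
    for k, name in enumerate(spec.cell_types):
        df[f"cell_{name}"] = props[:, k]
    return df.set_index("sample_id", drop=False)


def cell_proportion_columns(cohort: pd.DataFrame) -> List[str]:
    return [c for c in cohort.columns if c.startswith("cell_")]


# ---------------------------------------------------------------------------
# Effect spiking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DmrBlock:
    chrom: str
    cpg_ids: Tuple[str, ...]
    sign: int
    delta: float


@dataclass
class EffectMap:
    """Truth table of spiked effects: isolated DMCs plus clustered blocks."""

    dmc_effects: Dict[str, float] = field(default_factory=dict)
    dmr_blocks: List[DmrBlock] = field(default_factory=list)

    def delta_vector(self, manifest: Manifest) -> np.ndarray:
        """Per-site slope δ aligned to manifest order (0 for null sites)."""
        delta = {cid: 0.0 for cid in manifest.cpg_ids}
        delta.update(self.dmc_effects)
        for block in self.dmr_blocks:
            for cid in block.cpg_ids:
                delta[cid] = block.sign * block.delta
        return np.array([delta[cid] for cid in manifest.cpg_ids])

    def spiked_ids(self) -> set:
        ids = set(self.dmc_effects)
        for block in self.dmr_blocks:
            ids.update(block.cpg_ids)
        return ids

    def to_frame(self, manifest: Manifest) -> pd.DataFrame:
        rows = []
        for cid, delta in sorted(self.dmc_effects.items()):
            rows.append({"cpg_id": cid, "kind": "dmc", "block": "", "delta": delta})
        for b, block in enumerate(self.dmr_blocks):
            for cid in block.cpg_ids:
                rows.append(
                    {
                        "cpg_id": cid,
                        "kind": "dmr",
                        "block": f"{block.chrom}:{b}",
                        "delta": block.sign * block.delta,
                    }
                )
        return pd.DataFrame(rows, columns=["cpg_id", "kind", "block", "delta"])


def _eligible_segments(manifest: Manifest, max_gap: int) -> List[Tuple[int, int]]:
    """Maximal index ranges [i, j] with adjacent same-chromosome gaps <= max_gap."""
    segments = []
    sites = manifest.sites
    start = 0
    for i in range(1, len(sites) + 1):
        boundary = i == len(sites) or (
            sites[i].chrom != sites[i - 1].chrom
            or sites[i].pos - sites[i - 1].pos > max_gap
        )
        if boundary:
            segments.append((start, i - 1))
            start = i
    return segments


def spike_effects(
    manifest: Manifest,
    n_dmcs: int = 100,
    n_dmrs: int = 5,
    dmr_size_range: Tuple[int, int] = (7, 12),
    delta_range: Tuple[float, float] = (0.05, 0.15),
    sign_mix: float = 0.8,
    max_gap: int = 500,
    seed: int = 0,
    max_retries: int = 200,
) -> EffectMap:
    """Place isolated DMC effects and consecutive region blocks.

    Blocks land only in stretches whose adjacent gaps all satisfy the
    ``max_gap`` constraint; DMC and block site sets are disjoint. ~80 % of
    spiked slopes are positive by default.
    """
    if n_dmcs < 0 or n_dmrs < 0:
        raise ValueError("counts must be nonnegative")
    if dmr_size_range[0] < 7 or dmr_size_range[1] < dmr_size_range[0]:
        raise ValueError(f"invalid dmr_size_range {dmr_size_range}")
    rng = np.random.default_rng(seed)
    sites = manifest.sites
    used = np.zeros(len(sites), dtype=bool)
    blocks: List[DmrBlock] = []
    segments = _eligible_segments(manifest, max_gap)
    for _ in range(n_dmrs):
        size = int(rng.integers(dmr_size_range[0], dmr_size_range[1] + 1))
        placed = False
        for _ in range(max_retries):
            candidates = [(a, b) for a, b in segments if b - a + 1 >= size]
            if not candidates:
                break
            a, b = candidates[rng.integers(len(candidates))]
            start = int(rng.integers(a, b - size + 2))
            if used[start : start + size].any():
                continue
            used[start : start + size] = True
            sign = 1 if rng.random() < sign_mix else -1
            delta = float(rng.uniform(*delta_range))
            blocks.append(
                DmrBlock(
                    chrom=sites[start].chrom,
                    cpg_ids=tuple(s.cpg_id for s in sites[start : start + size]),
                    sign=sign,
                    delta=delta,
                )
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could only place {len(blocks)} of {n_dmrs} blocks of size {size} "
                f"under max_gap={max_gap}"
            )
    free = np.flatnonzero(~used)
    if n_dmcs > len(free):
        raise ValueError(f"manifest too small for {n_dmcs} DMCs ({len(free)} free sites)")
    dmc_idx = rng.choice(free, size=n_dmcs, replace=False)
    dmc_effects = {}
    for i in dmc_idx:
        sign = 1 if rng.random() < sign_mix else -1
        dmc_effects[sites[i].cpg_id] = sign * float(rng.uniform(*delta_range))
    return EffectMap(dmc_effects=dmc_effects, dmr_blocks=blocks)


# ---------------------------------------------------------------------------
# β matrix generation
# ---------------------------------------------------------------------------

def generate_beta(
    manifest: Manifest,
    cohort: pd.DataFrame,
    effects: Optional[EffectMap] = None,
    sigma_noise: float = DEFAULT_NOISE_SD,
    batch_shifts: Optional[Mapping[str, float]] = None,
    cell_signatures: Optional[pd.DataFrame] = None,
    site_sd: float = DEFAULT_SITE_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a β matrix (CpG × sample).

    logit β_ij = μ_i + b_batch(j) + Σ_k γ_ik p_jk + δ_i s_j + ε_ij, with
    ε ~ N(0, σ²). μ_i is an additive island-relation + gene-region offset
    (calibrated so category grand means match the configured targets) plus
    a per-site N(0, site_sd²) deviation. Output is inverse-logit, clipped
    to [1e-6, 1−1e-6].
    """
    if sigma_noise < 0:
        raise ValueError(f"sigma_noise must be >= 0, got {sigma_noise}")
    if site_sd < 0:
        raise ValueError(f"site_sd must be >= 0, got {site_sd}")
    rng = np.random.default_rng(seed)
    g, n = len(manifest), len(cohort)
    spread = float(np.hypot(site_sd, sigma_noise))
    a_off, d_off = calibrate_context_offsets(
        tuple(DEFAULT_ISLAND_PROPORTIONS.items()),
        tuple(DEFAULT_REGION_PROPORTIONS.items()),
        tuple(ISLAND_RELATION_MEANS.items()),
        tuple(GENE_REGION_MEANS.items()),
        spread,
    )
    mu = np.array(
        [a_off[s.island_relation] + d_off[s.gene_region] for s in manifest.sites]
    )
    mu = mu + rng.normal(0.0, site_sd, size=g)

    eta = np.tile(mu[:, None], (1, n))
    if batch_shifts:
        shift = cohort["batch"].map(lambda b: batch_shifts.get(b, 0.0)).to_numpy(float)
        eta += shift[None, :]
    if cell_signatures is not None:
        prop_cols = cell_proportion_columns(cohort)
        gamma = cell_signatures.reindex(index=manifest.cpg_ids).to_numpy(float)
        if np.isnan(gamma).any():
            raise ValueError("cell_signatures must cover every manifest CpG")
        props = cohort[prop_cols].to_numpy(float)
        if gamma.shape[1] != props.shape[1]:
            raise ValueError("cell_signatures columns must match cohort cell types")
        eta += gamma @ props.T
    if effects is not None:
        delta = effects.delta_vector(manifest)
        eta += delta[:, None] * cohort["score"].to_numpy(float)[None, :]
    if sigma_noise > 0:
        eta += rng.normal(0.0, sigma_noise, size=(g, n))
    beta = np.clip(expit(eta), BETA_CLIP, 1.0 - BETA_CLIP)
    return pd.DataFrame(beta, index=pd.Index(manifest.cpg_ids, name="cpg_id"),
                        columns=cohort.index)


# ---------------------------------------------------------------------------
# Survival generation
# ---------------------------------------------------------------------------

def generate_survival(
    cohort: pd.DataFrame,
    beta: pd.DataFrame,
    linked_cpg: str,
    log_hr: float = 0.0,
    baseline_rate: float = 1 / 60.0,
    censor_rate: float = 1 / 90.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Return a cohort copy with BCR outcomes linked to one CpG.

    Event times are exponential with hazard baseline_rate ×
    exp(log_hr · I(β > median)); censoring is independent exponential
    (censor_rate = 0 → no censoring).
    """
    if linked_cpg not in beta.index:
        raise ValueError(f"linked_cpg {linked_cpg!r} not in beta matrix")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be > 0")
    if censor_rate < 0:
        raise ValueError("censor_rate must be >= 0")
    rng = np.random.default_rng(seed)
    row = beta.loc[linked_cpg, cohort.index].to_numpy(float)
    high = row > np.median(row)
    hazard = baseline_rate * np.exp(log_hr * high)
    event_t = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=len(cohort))
    else:
        censor_t = np.full(len(cohort), np.inf)
    out = cohort.copy()
    out["bcr_time"] = np.minimum(event_t, censor_t)
    out["bcr_event"] = (event_t <= censor_t).astype(int)
    return out
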