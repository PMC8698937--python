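"""End-to-end orchestration: simulate → preprocess → trend → DMR → context
→ survival → enrichment, with a machine-readable run summary.

All randomness flows from one root seed through spawned child seeds, so a
run directory is reproducible byte for byte from its config.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .context_summary import summarize_context
from .dmr_scanner import (
    ScannerConfig,
    annotate_dmrs,
    classify_sites,
    dmrs_to_frame,
    scan_dmrs,
    score_against_truth,
    write_bed,
)
from .enrichment import enrich_table, example_gene_sets, read_gmt
from .manifest_io import write_manifest, write_matrix, write_sample_sheet
from .preprocess import adjust_batch
from .survival_analysis import bcr_association, cox_results_to_frame
from .synthetic_data import (
    CohortSpec,
    EffectMap,
    generate_beta,
    generate_cohort,
    generate_manifest,
    generate_survival,
    spike_effects,
)
from .trend_analysis import global_trend, tabulate_dmcs, trend_test_matrix


class ConfigError(ValueError):
    pass


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_cpgs: int = 20_000
    chrom_count: int = 22
    group_counts: Tuple[int, int, int] = (82, 162, 36)
    n_batches: int = 2
    sigma_noise: float = 0.3
    site_sd: float = 1.2
    n_dmcs: int = 100
    n_dmrs: int = 5
    dmr_size_range: Tuple[int, int] = (7, 12)
    delta_range: Tuple[float, float] = (0.08, 0.15)
    sign_mix: float = 0.8
    batch_shift: float = 0.0  # extra logit shift applied to batch B2
    survival_log_hr: float = 0.0  # hazard link for the first spiked site


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    sim: SimConfig = Field(default_factory=SimConfig)
    min_cpgs: int = 7
    max_gap: int = 500
    site_p_threshold: float = 0.05
    adjust_batches: bool = True
    use_cell_covariates: bool = False
    cox_select_p: float = 1e-4
    cox_max_sites: int = 100
    gmt: Optional[str] = None


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from None


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return f"methtrend v{__version__} seed={config.seed} config_sha={config_hash(config)}"


def run_pipeline(config: RunConfig, outdir) -> Dict:
    """Execute every stage and write the run directory.

    Returns the summary dict (also written to summary.json). Stage
    failures raise :class:`PipelineStageError` after marking the summary
    incomplete on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _header(config)
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    seed_ints = [int(s.generate_state(1)[0]) for s in seeds]
    summary: Dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha": config_hash(config),
        "status": "incomplete",
    }
    stage = "simulate"
    try:
        sim = config.sim
        manifest = generate_manifest(sim.n_cpgs, sim.chrom_count, seed=seed_ints[0])
        cohort = generate_cohort(
            CohortSpec(
                n_samples=sum(sim.group_counts),
                group_counts=sim.group_counts,
                n_batches=sim.n_batches,
                seed=seed_ints[1],
            )
        )
        if sim.n_dmcs or sim.n_dmrs:
            effects = spike_effects(
                manifest,
                n_dmcs=sim.n_dmcs,
                n_dmrs=sim.n_dmrs,
                dmr_size_range=sim.dmr_size_range,
                delta_range=sim.delta_range,
                sign_mix=sim.sign_mix,
                max_gap=config.max_gap,
                seed=seed_ints[2],
            )
        else:
            effects = EffectMap()
        batch_shifts = (
            {"B2": sim.batch_shift} if sim.n_batches >= 2 and sim.batch_shift else None
        )
        beta = generate_beta(
            manifest,
            cohort,
            effects=effects,
            sigma_noise=sim.sigma_noise,
            site_sd=sim.site_sd,
            batch_shifts=batch_shifts,
            seed=seed_ints[3],
        )
        if sim.survival_log_hr:
            linked = sorted(effects.spiked_ids())[0] if effects.spiked_ids() else beta.index[0]
            cohort = generate_survival(
                cohort, beta, linked, log_hr=sim.survival_log_hr, seed=seed_ints[4]
            )
            summary["survival_linked_cpg"] = linked
        write_manifest(manifest, outdir / "manifest.tsv", header)
        write_matrix(beta, outdir / "beta.tsv", header)
        write_sample_sheet(cohort, outdir / "samples.tsv", header)
        write_matrix(
            effects.to_frame(manifest).set_index("cpg_id"),
            outdir / "truth_effects.tsv",
            header,
        )

        stage = "preprocess"
        if config.adjust_batches and sim.n_batches >= 2:
            analysis_beta = adjust_batch(beta, cohort["batch"].to_numpy())
            write_matrix(analysis_beta, outdir / "adj_beta.tsv", header)
        else:
            analysis_beta = beta
        covariates = None
        if config.use_cell_covariates:
            from .synthetic_data import cell_proportion_columns

            props = cohort[cell_proportion_columns(cohort)]
            covariates = props.drop(columns=[props.mean().idxmax()])

        stage = "trend"
        scores = cohort["score"].to_numpy(int)
        trend = trend_test_matrix(analysis_beta, scores, covariates=covariates)
        write_matrix(trend, outdir / "trend.tsv", header)
        tab = tabulate_dmcs(trend)
        group_means, global_p = global_trend(analysis_beta, scores)
        summary["dmc_ladder"] = {f"{thr:g}": c for thr, c in tab.counts.items()}
        summary["fraction_increasing"] = tab.fraction_increasing
        summary["global_trend"] = {
            "group_means": {str(k): v for k, v in group_means.items()},
            "p": global_p,
        }

        stage = "dmr"
        scanner = ScannerConfig(
            min_cpgs=config.min_cpgs,
            max_gap=config.max_gap,
            site_p_threshold=config.site_p_threshold,
        )
        labels = classify_sites(trend, scanner, manifest)
        dmrs = annotate_dmrs(
            scan_dmrs(manifest, labels, scanner, trend_results=trend), manifest
        )
        write_matrix(dmrs_to_frame(dmrs).rename_axis("idx"), outdir / "dmrs.tsv", header)
        write_bed(dmrs, outdir / "dmrs.bed")
        summary["n_dmrs"] = len(dmrs)
        if effects.dmr_blocks:
            summary["dmr_recovery"] = score_against_truth(dmrs, effects.dmr_blocks)

        stage = "context"
        groups = cohort["gleason_group"].to_numpy()
        ctx = pd.concat(
            [
                summarize_context(analysis_beta, manifest, groups, axis=ax)
                for ax in ("island_relation", "gene_region")
            ]
        )
        write_matrix(ctx.set_index("category"), outdir / "context.tsv", header)

        stage = "cox"
        candidates = trend[trend["p_trend"] < config.cox_select_p].sort_values("p_trend")
        ids = list(candidates.index[: config.cox_max_sites])
        cox = cox_results_to_frame(bcr_association(analysis_beta, ids, cohort))
        write_matrix(cox, outdir / "cox.tsv", header)
        summary["n_cox_tested"] = len(ids)
        summary["n_cox_significant"] = int((cox["p"] < 0.05).sum()) if len(cox) else 0

        stage = "enrich"
        gene_sets = read_gmt(config.gmt) if config.gmt else example_gene_sets()
        universe = sorted(
            {s.gene_symbol for s in manifest.sites if s.gene_symbol}
        )
        hits = sorted({g for d in dmrs for g in d.genes})
        if universe and hits:
            enr = enrich_table(hits, gene_sets, universe)
            write_matrix(enr, outdir / "enrich.tsv", header)
            summary["top_enriched_set"] = str(enr.index[0])
    except Exception as exc:  # noqa: BLE001 — annotate and re-raise with stage
        summary["failed_stage"] = stage
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        raise PipelineStageError(stage, exc) from exc

    summary["status"] = "complete"
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
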