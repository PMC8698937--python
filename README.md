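# methtrend

An ordinal-trend EWAS toolkit for Illumina-EPIC-like methylation data.
It implements, end to end and on fully synthetic data, a leukocyte
methylation analysis of tumor-grade groups:

- **β computation** from methylated/unmethylated intensity matrices
  (`β = M / (M + U + offset)`), with TSV readers/writers for manifests,
  matrices and sample sheets (`methtrend.manifest_io`).
- **Synthetic data generation** (`methtrend.synthetic_data`): EPIC-like
  manifests with clustered island context, cohorts with exact ordinal
  grade-group sizes and realistic covariate frequencies, logit-scale
  spiked per-CpG trend effects and consecutive region blocks, batch
  shifts, Dirichlet cell mixtures, and CpG-linked survival outcomes.
  Category grand means are calibrated against published island-relation
  and gene-region methylation profiles.
- **Preprocessing** (`methtrend.preprocess`): parametric empirical-Bayes
  batch adjustment on logit(β) (ComBat-style), and reference-based
  cell-type deconvolution by nonnegativity/sum-constrained least squares.
- **Trend analysis** (`methtrend.trend_analysis`): per-CpG least-squares
  slope test on ordinal group scores (0/1/2) with optional covariates,
  a rank-based Jonckheere–Terpstra alternative, global mean-methylation
  trend, DMC threshold-ladder tabulation, and Bonferroni thresholds.
- **DMR scanning** (`methtrend.dmr_scanner`): maximal runs of ≥7
  manifest-consecutive, direction-consistent significant CpGs with
  adjacent gaps ≤500 bp (inclusive), plus a brute-force window-
  enumeration oracle that the scanner must match exactly; BED6 export.
- **Context summaries** (`methtrend.context_summary`): mean β by island
  relation and gene region, overall and per group.
- **Survival analysis** (`methtrend.survival_analysis`): median-
  dichotomized multivariable Cox proportional hazards (own Newton
  maximizer of the Efron/Breslow partial likelihood, Wald inference)
  against biochemical recurrence.
- **Enrichment** (`methtrend.enrichment`): hypergeometric gene-set
  over-representation with GMT input and BH adjustment.
- **Pipeline + CLI** (`methtrend.pipeline`, `methtrend.cli`):
  simulate → preprocess → trend → DMR → context → Cox → enrich, fully
  deterministic from one seed, with a machine-readable `summary.json`.

## CLI

```bash
# full synthetic pipeline
cat > run.yaml <<'YAML'
seed: 5
sim:
  n_cpgs: 20000
  n_dmrs: 5
  delta_range: [0.15, 0.15]
  batch_shift: 0.3
  survival_log_hr: 1.2
YAML
methtrend run --config run.yaml --outdir out/

# individual stages
methtrend beta --m M.tsv --u U.tsv --offset 100 -o beta.tsv
methtrend preprocess --beta beta.tsv --samples samples.tsv -o adj_beta.tsv
methtrend trend --beta adj_beta.tsv --samples samples.tsv --manifest manifest.tsv -o trend.tsv
methtrend dmr --trend trend.tsv --manifest manifest.tsv --min-cpgs 7 --max-gap 500 -o dmrs.tsv --bed dmrs.bed
methtrend context --beta beta.tsv --manifest manifest.tsv --samples samples.tsv -o context.tsv
methtrend cox --beta beta.tsv --samples samples.tsv --dmcs top.tsv -o cox.tsv
methtrend enrich --dmrs dmrs.tsv --universe manifest.tsv -o enrich.tsv
```

Exit codes for `run`: 0 success, 2 config error, 3 stage failure.

## Conventions

- Coordinates are 1-based inclusive in manifests/TSV; BED output is
  0-based half-open.
- β is kept in [0, 1] everywhere; synthetic effects act on the logit
  scale and output is clipped to [1e-6, 1−1e-6].
- All generators and the pipeline are deterministic given their seed.
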