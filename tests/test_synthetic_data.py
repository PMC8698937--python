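import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest

from methtrend.survival_analysis import fit_cox
from methtrend.synthetic_data import (
    BMI_COUNTS,
    DEFAULT_GROUP_COUNTS,
    PSA_COUNTS,
    SMOKING_COUNTS,
    STAGE_COUNTS,
    CohortSpec,
    category_percent,
    generate_beta,
    generate_cohort,
    generate_manifest,
    generate_survival,
    spike_effects,
)
from methtrend.trend_analysis import trend_test_matrix

from .conftest import dense_manifest


class TestCohortDefaults:
    def test_table_percentages(self):
        assert category_percent(SMOKING_COUNTS, "never") == 57.9
        assert category_percent(DEFAULT_GROUP_COUNTS, "GS8plus") == 12.9
        assert category_percent(BMI_COUNTS, "ge30") == 49.1
        assert category_percent(STAGE_COUNTS, "T2") == 36.1
        assert category_percent(PSA_COUNTS, "lt10") == 77.1  # 216/280

    def test_exact_group_counts(self):
        cohort = generate_cohort(CohortSpec(seed=5))
        counts = cohort["gleason_group"].value_counts()
        assert counts["GS6"] == 82 and counts["GS7"] == 162 and counts["GS8plus"] == 36

    def test_score_is_group_rank(self):
        cohort = generate_cohort(CohortSpec(seed=5))
        mapping = cohort.groupby("gleason_group")["score"].unique()
        assert list(mapping["GS6"]) == [0]
        assert list(mapping["GS7"]) == [1]
        assert list(mapping["GS8plus"]) == [2]

    def test_seed_determinism(self):
        a = generate_cohort(CohortSpec(seed=9))
        b = generate_cohort(CohortSpec(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError, match="group_counts"):
            CohortSpec(n_samples=100, group_counts=(82, 162, 36))

    def test_cell_proportions_simplex(self):
        cohort = generate_cohort(CohortSpec(seed=5))
        props = cohort[[c for c in cohort.columns if c.startswith("cell_")]].to_numpy()
        assert (props >= 0).all()
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_high_concentration_limit(self):
        spec = CohortSpec(n_samples=50, group_counts=(20, 20, 10),
                          cell_types=("A", "B"), seed=3)
        cohort = generate_cohort(spec, cell_means=(0.7, 0.3), cell_concentration=1e7)
        assert np.allclose(cohort["cell_A"], 0.7, atol=1e-3)


class TestGenerateManifest:
    def test_seed_determinism(self):
        assert generate_manifest(100, seed=7) == generate_manifest(100, seed=7)

    def test_distinct_seeds_differ(self):
        assert generate_manifest(100, seed=7) != generate_manifest(100, seed=8)

    def test_single_chromosome_sorted(self):
        manifest = generate_manifest(200, chrom_count=1, seed=2)
        chroms = {s.chrom for s in manifest}
        assert chroms == {"1"}
        pos = [s.pos for s in manifest]
        assert pos == sorted(pos) and len(set(pos)) == len(pos)

    def test_island_fraction_near_target(self):
        manifest = generate_manifest(50_000, seed=4)
        frac = np.mean([s.island_relation == "Island" for s in manifest])
        assert abs(frac - 0.19) < 0.02

    def test_islands_tighter_than_open_sea(self):
        manifest = generate_manifest(20_000, chrom_count=4, seed=6)
        sites = manifest.sites
        gaps = {"Island": [], "OpenSea": []}
        for a, b in zip(sites, sites[1:]):
            if a.chrom == b.chrom and a.island_relation == b.island_relation:
                gaps.setdefault(a.island_relation, []).append(b.pos - a.pos)
        assert np.median(gaps["Island"]) < np.median(gaps["OpenSea"])

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            generate_manifest(0)


class TestSpikeEffects:
    def test_single_block_contract(self):
        manifest = dense_manifest(200, gap=100)
        effects = spike_effects(manifest, n_dmcs=0, n_dmrs=1,
                                dmr_size_range=(8, 8), max_gap=500, seed=1)
        assert len(effects.dmr_blocks) == 1
        block = effects.dmr_blocks[0]
        assert len(block.cpg_ids) == 8
        idx = [manifest.cpg_ids.index(c) for c in block.cpg_ids]
        assert idx == list(range(idx[0], idx[0] + 8))  # consecutive in manifest
        pos = [manifest.sites[i].pos for i in idx]
        assert max(np.diff(pos)) <= 500

    def test_empty_map(self):
        manifest = dense_manifest(50)
        effects = spike_effects(manifest, n_dmcs=0, n_dmrs=0, seed=1)
        assert not effects.dmc_effects and not effects.dmr_blocks

    def test_sign_mix(self):
        manifest = generate_manifest(20_000, seed=3)
        effects = spike_effects(manifest, n_dmcs=1000, n_dmrs=0, sign_mix=0.8, seed=4)
        frac_pos = np.mean([d > 0 for d in effects.dmc_effects.values()])
        assert abs(frac_pos - 0.8) < 0.05

    def test_disjoint_sites(self):
        manifest = generate_manifest(20_000, seed=3)
        effects = spike_effects(manifest, n_dmcs=500, n_dmrs=10, seed=5)
        block_ids = {c for b in effects.dmr_blocks for c in b.cpg_ids}
        assert not block_ids & set(effects.dmc_effects)

    def test_infeasible_placement_errors(self):
        manifest = dense_manifest(20, gap=1000)  # every gap exceeds max_gap
        with pytest.raises(ValueError, match="could only place"):
            spike_effects(manifest, n_dmcs=0, n_dmrs=1, max_gap=500, seed=1)


class TestGenerateBeta:
    def test_noiseless_rows_constant(self, cohort280):
        manifest = dense_manifest(20)
        beta = generate_beta(manifest, cohort280, sigma_noise=0.0, seed=1)
        assert np.allclose(np.ptp(beta.to_numpy(), axis=1), 0.0)

    def test_spiked_site_monotone_in_score(self, cohort280):
        manifest = dense_manifest(20)
        effects = spike_effects(manifest, n_dmcs=0, n_dmrs=1,
                                dmr_size_range=(8, 8), delta_range=(0.2, 0.2),
                                sign_mix=1.0, seed=1)
        beta = generate_beta(manifest, cohort280, effects, sigma_noise=0.0, seed=2)
        cid = effects.dmr_blocks[0].cpg_ids[0]
        row = beta.loc[cid]
        scores = cohort280["score"]
        means = [row[scores == s].mean() for s in (0, 1, 2)]
        assert means[0] < means[1] < means[2]

    def test_determinism_and_seed_sensitivity(self, cohort280):
        manifest = dense_manifest(30)
        a = generate_beta(manifest, cohort280, seed=5)
        b = generate_beta(manifest, cohort280, seed=5)
        c = generate_beta(manifest, cohort280, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert not np.allclose(a.to_numpy(), c.to_numpy())

    def test_range(self, cohort280):
        manifest = dense_manifest(30)
        beta = generate_beta(manifest, cohort280, sigma_noise=2.0, seed=5)
        vals = beta.to_numpy()
        assert vals.min() > 0.0 and vals.max() < 1.0

    def test_negative_sigma_rejected(self, cohort280):
        with pytest.raises(ValueError):
            generate_beta(dense_manifest(5), cohort280, sigma_noise=-1.0)

    def test_batch_shift_applied(self, cohort280):
        manifest = dense_manifest(30)
        beta = generate_beta(manifest, cohort280, batch_shifts={"B2": 1.0},
                             sigma_noise=0.0, seed=5)
        b = cohort280["batch"].to_numpy()
        diff = beta.to_numpy()[:, b == "B2"].mean() - beta.to_numpy()[:, b == "B1"].mean()
        assert diff > 0.03  # +1 logit, attenuated by extreme-β sites

    def test_null_trend_p_uniform(self, null_dataset, cohort280):
        # KS uniformity of per-CpG trend p on a 10k-site null matrix
        _, beta = null_dataset
        res = trend_test_matrix(beta, cohort280["score"])
        assert kstest(res["p_trend"], "uniform").pvalue > 0.01


class TestGenerateSurvival:
    @pytest.fixture(scope="class")
    @staticmethod
    def beta20(cohort280):
        return generate_beta(dense_manifest(20), cohort280, seed=8)

    def test_no_censoring(self, cohort280, beta20):
        out = generate_survival(cohort280, beta20, beta20.index[0],
                                censor_rate=0.0, seed=1)
        assert (out["bcr_event"] == 1).all()
        assert (out["bcr_time"] > 0).all()

    def test_null_hr_recovered(self, cohort280, beta20):
        hrs = []
        for rep in range(40):
            out = generate_survival(cohort280, beta20, beta20.index[0],
                                    log_hr=0.0, seed=rep)
            high = (beta20.loc[beta20.index[0]] >
                    beta20.loc[beta20.index[0]].median()).astype(float)
            fit = fit_cox(out["bcr_time"], out["bcr_event"],
                          pd.DataFrame({"high": high}))
            hrs.append(fit.loc["high", "coef"])
        assert abs(np.mean(hrs)) < 0.1

    def test_large_hr_inside_ci(self, cohort280, beta20):
        # CI covers the generating log-HR in >= 90% of 200 replicates
        log_hr = np.log(3.66)
        cid = beta20.index[0]
        high = (beta20.loc[cid] > beta20.loc[cid].median()).astype(float)
        covered = 0
        for rep in range(200):
            out = generate_survival(cohort280, beta20, cid, log_hr=log_hr, seed=rep)
            fit = fit_cox(out["bcr_time"], out["bcr_event"],
                          pd.DataFrame({"high": high}))
            lo, hi = fit.loc["high", "ci_low"], fit.loc["high", "ci_high"]
            covered += lo <= np.exp(log_hr) <= hi
        assert covered >= 180

    def test_bad_inputs(self, cohort280, beta20):
        with pytest.raises(ValueError):
            generate_survival(cohort280, beta20, "nope")
        with pytest.raises(ValueError):
            generate_survival(cohort280, beta20, beta20.index[0], baseline_rate=0.0)
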