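import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from methtrend.preprocess import (
    CellReference,
    PreprocessError,
    adjust_batch,
    build_covariate_matrix,
    estimate_cell_proportions,
    synthetic_reference,
)
from methtrend.synthetic_data import CohortSpec, generate_beta, generate_cohort

from .conftest import dense_manifest


def _beta_df(values, prefix="cg"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


class TestAdjustBatch:
    def test_no_batch_signal_identity(self):
        # exchangeable noiseless data: constant per CpG, permuted labels
        beta = _beta_df(np.tile([[0.2], [0.5], [0.8]], (1, 8)))
        out = adjust_batch(beta, ["A", "B"] * 4)
        assert np.allclose(out.to_numpy(), beta.to_numpy(), atol=1e-6)

    def test_injected_shift_removed(self):
        rng = np.random.default_rng(0)
        g, n = 400, 60
        batch = np.array(["A"] * 30 + ["B"] * 30)
        y = rng.normal(0.0, 0.4, size=(g, n))
        y[:, batch == "B"] += 0.5
        beta = _beta_df(expit(y))
        out = adjust_batch(beta, batch)
        ya = logit(out.to_numpy())
        before = np.abs(y[:, batch == "B"].mean(1) - y[:, batch == "A"].mean(1))
        after = np.abs(ya[:, batch == "B"].mean(1) - ya[:, batch == "A"].mean(1))
        assert np.median(1.0 - after / before) >= 0.9

    def test_hand_worked_eb_example(self):
        # two batches of two samples, two CpGs: transcribe the estimator
        # step by step with scalars and compare to the implementation
        y = np.array([[0.30, 0.35, 0.55, 0.60],
                      [0.20, 0.22, 0.40, 0.38]])
        batch = np.array(["A", "A", "B", "B"])
        beta = _beta_df(y)
        z_full = logit(y)

        batch_means = np.stack([z_full[:, :2].mean(1), z_full[:, 2:].mean(1)], axis=1)
        grand = 0.5 * batch_means[:, 0] + 0.5 * batch_means[:, 1]
        var_pooled = ((z_full - batch_means[:, [0, 0, 1, 1]]) ** 2).mean(1)
        sd = np.sqrt(var_pooled)
        z = (z_full - grand[:, None]) / sd[:, None]

        expected = np.empty_like(z)
        for cols in (slice(0, 2), slice(2, 4)):
            zb = z[:, cols]
            gamma_hat = zb.mean(1)
            delta_hat = zb.var(1, ddof=1)
            gamma_bar = gamma_hat.mean()
            tau2 = max(gamma_hat.var(ddof=1), 1e-12)
            m, s2 = delta_hat.mean(), max(delta_hat.var(ddof=1), 1e-12)
            a_prior = (2 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            gamma, delta = gamma_hat.copy(), delta_hat.copy()
            for _ in range(2000):
                gamma_new = (2 * tau2 * gamma_hat + delta * gamma_bar) / (2 * tau2 + delta)
                delta_new = (b_prior + 0.5 * ((zb - gamma_new[:, None]) ** 2).sum(1)) / (
                    1.0 + a_prior - 1.0
                )
                if np.allclose(gamma_new, gamma, rtol=1e-12) and np.allclose(
                    delta_new, delta, rtol=1e-12
                ):
                    break
                gamma, delta = gamma_new, delta_new
            expected[:, cols] = (zb - gamma[:, None]) / np.sqrt(delta)[:, None]
        y_exp = expected * sd[:, None] + grand[:, None]
        w = np.full(4, 0.25)
        y_exp -= ((y_exp * w).sum(1) - grand)[:, None]

        out = adjust_batch(beta, batch)
        assert np.allclose(logit(out.to_numpy()), y_exp, atol=1e-6)

    def test_grand_mean_preserved_on_logit_scale(self):
        rng = np.random.default_rng(3)
        beta = _beta_df(expit(rng.normal(0, 0.5, size=(50, 40))))
        batch = np.array(["A"] * 20 + ["B"] * 20)
        out = adjust_batch(beta, batch)
        assert np.allclose(
            logit(out.to_numpy()).mean(1), logit(beta.to_numpy()).mean(1), atol=1e-8
        )

    def test_preserves_shape_and_range(self):
        rng = np.random.default_rng(4)
        beta = _beta_df(rng.uniform(0.01, 0.99, size=(30, 12)))
        out = adjust_batch(beta, ["A"] * 6 + ["B"] * 6)
        assert out.shape == beta.shape
        assert out.to_numpy().min() >= 0.0 and out.to_numpy().max() <= 1.0

    def test_single_sample_batch_rejected(self):
        beta = _beta_df(np.full((3, 3), 0.5))
        with pytest.raises(PreprocessError, match="fewer than 2"):
            adjust_batch(beta, ["A", "A", "B"])

    def test_single_batch_identity_with_warning(self):
        beta = _beta_df(np.full((3, 4), 0.4))
        with pytest.warns(UserWarning, match="single batch"):
            out = adjust_batch(beta, ["A"] * 4)
        assert np.allclose(out.to_numpy(), beta.to_numpy())

    def test_nonparametric_not_implemented(self):
        beta = _beta_df(np.full((3, 4), 0.4))
        with pytest.raises(NotImplementedError):
            adjust_batch(beta, ["A", "A", "B", "B"], parametric=False)


class TestDeconvolution:
    @pytest.fixture(scope="class")
    @staticmethod
    def reference():
        return synthetic_reference(n_markers=100, seed=2024)

    def test_reference_column_is_unit_vector(self, reference):
        sig = reference.signature
        beta = pd.DataFrame({"s1": sig.iloc[:, 2]}, index=sig.index)
        w = estimate_cell_proportions(beta, reference)
        expected = np.zeros(6)
        expected[2] = 1.0
        assert np.allclose(w.iloc[0].to_numpy(), expected, atol=1e-8)

    def test_noiseless_mixture_recovery(self, reference):
        rng = np.random.default_rng(1)
        w_true = rng.dirichlet(np.ones(6), size=20)
        mixed = reference.signature.to_numpy() @ w_true.T
        beta = pd.DataFrame(mixed, index=reference.marker_ids,
                            columns=[f"s{i}" for i in range(20)])
        w = estimate_cell_proportions(beta, reference)
        assert np.abs(w.to_numpy() - w_true).max() < 1e-6

    def test_noisy_recovery(self, reference):
        rng = np.random.default_rng(2)
        n = 500
        w_true = rng.dirichlet(np.ones(6) * 3, size=n)
        mixed = reference.signature.to_numpy() @ w_true.T
        mixed = mixed + rng.normal(0.0, 0.01, size=mixed.shape)
        beta = pd.DataFrame(mixed, index=reference.marker_ids,
                            columns=[f"s{i}" for i in range(n)])
        w = estimate_cell_proportions(beta, reference)
        max_err = np.abs(w.to_numpy() - w_true).max(axis=1)
        assert (max_err < 0.05).mean() >= 0.95

    def test_order_invariance(self, reference):
        rng = np.random.default_rng(3)
        w_true = rng.dirichlet(np.ones(6), size=6)
        mixed = reference.signature.to_numpy() @ w_true.T
        beta = pd.DataFrame(mixed, index=reference.marker_ids,
                            columns=[f"s{i}" for i in range(6)])
        shuffled = beta[beta.columns[::-1]]
        a = estimate_cell_proportions(beta, reference)
        b = estimate_cell_proportions(shuffled, reference).loc[a.index]
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_constraints_hold(self, reference):
        rng = np.random.default_rng(4)
        beta = pd.DataFrame(rng.uniform(0, 1, size=(100, 10)),
                            index=reference.marker_ids,
                            columns=[f"s{i}" for i in range(10)])
        w = estimate_cell_proportions(beta, reference)
        assert (w.to_numpy() >= -1e-12).all()
        assert (w.to_numpy().sum(axis=1) <= 1.0 + 1e-6).all()

    def test_rank_deficient_reference_rejected(self):
        sig = pd.DataFrame(np.tile(np.linspace(0.1, 0.9, 10)[:, None], (1, 3)),
                           index=[f"mk{i}" for i in range(10)],
                           columns=["A", "B", "C"])
        with pytest.raises(PreprocessError, match="rank deficient"):
            CellReference(sig)

    def test_missing_markers_rejected(self, reference):
        beta = pd.DataFrame(np.full((5, 2), 0.5),
                            index=[f"other{i}" for i in range(5)],
                            columns=["s1", "s2"])
        with pytest.raises(PreprocessError, match="missing marker"):
            estimate_cell_proportions(beta, reference)


class TestCovariateMatrix:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        return generate_cohort(CohortSpec(n_samples=60, group_counts=(20, 30, 10), seed=7))

    def test_k_minus_one_columns(self, cohort):
        props = cohort[[c for c in cohort.columns if c.startswith("cell_")]]
        out = build_covariate_matrix(cohort, props)
        assert out.shape[1] == 5
        assert "cell_Gran" not in out.columns  # largest-mean type dropped

    def test_constant_columns_flagged(self, cohort):
        props = pd.DataFrame(
            np.tile([0.5, 0.3, 0.2], (len(cohort), 1)),
            index=cohort.index, columns=["A", "B", "C"],
        )
        out = build_covariate_matrix(cohort, props)
        assert set(out.attrs["constant_columns"]) == set(out.columns)

    def test_order_invariance(self, cohort):
        props = cohort[[c for c in cohort.columns if c.startswith("cell_")]]
        shuffled = cohort.sample(frac=1.0, random_state=0)
        a = build_covariate_matrix(cohort, props)
        b = build_covariate_matrix(shuffled, props.loc[shuffled.index]).loc[a.index]
        pd.testing.assert_frame_equal(a, b)

    def test_id_mismatch_rejected(self, cohort):
        props = cohort[[c for c in cohort.columns if c.startswith("cell_")]].iloc[:10]
        with pytest.raises(PreprocessError, match="do not match"):
            build_covariate_matrix(cohort, props)

    def test_clinical_encoding(self, cohort):
        out = build_covariate_matrix(cohort, None, clinical=("age", "psa_class"))
        assert "age" in out.columns
        assert {"psa_10to20", "psa_ge20"} <= set(out.columns)
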