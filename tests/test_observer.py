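"""CHO training, decision variable, detectability index."""

import numpy as np
import pytest
import scipy.linalg

from choct import (
    CHOTemplate,
    Category,
    NoiseModel,
    channel_outputs,
    decision_variable,
    decision_variables,
    detectability_index,
    generate_category_dataset,
    run_afc,
    train_from_channel_outputs,
    train_template,
)


def samples_with_exact_stats(rng, n, mean, cov=None):
    """Draws whose *sample* mean and covariance equal the requested values
    exactly (whitening construction); cov defaults to the identity."""
    dim = len(mean)
    raw = rng.normal(size=(n, dim))
    centred = raw - raw.mean(axis=0)
    sample_cov = np.cov(centred, rowvar=False)
    white = centred @ np.linalg.inv(np.linalg.cholesky(sample_cov)).T
    if cov is not None:
        white = white @ np.linalg.cholesky(cov).T
    return white + np.asarray(mean)


class TestTrainTemplate:
    def test_identity_covariance_recovers_mean_difference(self):
        """With K_cs = K_cn = I and mean difference e1, the template is e1."""
        rng = np.random.default_rng(0)
        e1 = np.array([1.0, 0.0, 0.0])
        gcs = samples_with_exact_stats(rng, 12, e1)
        gcn = samples_with_exact_stats(rng, 12, np.zeros(3))
        template = train_from_channel_outputs(gcs, gcn)
        np.testing.assert_allclose(template.w_cho, e1, atol=1e-10)

    def test_identical_classes_give_zero_template(self, bank9):
        rng = np.random.default_rng(1)
        rois = rng.normal(size=(10, 9, 9))
        template = train_template(rois, rois, bank9)
        np.testing.assert_allclose(template.w_cho, 0.0, atol=1e-10)

    def test_solve_matches_explicit_inversion(self):
        """Linear-solve route agrees with a dense explicit matrix inverse."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            gcs = rng.normal(size=(40, 10)) + rng.normal(size=10)
            gcn = rng.normal(size=(40, 10))
            template = train_from_channel_outputs(gcs, gcn)
            mean_cov = 0.5 * (np.cov(gcs, rowvar=False) + np.cov(gcn, rowvar=False))
            expected = np.linalg.inv(mean_cov) @ (gcs.mean(0) - gcn.mean(0))
            np.testing.assert_allclose(template.w_cho, expected, rtol=1e-8)

    def test_too_few_rois_rejected(self, bank9):
        rois = np.zeros((1, 9, 9))
        with pytest.raises(ValueError, match="at least 2"):
            train_template(rois, np.zeros((5, 9, 9)), bank9)

    def test_non_finite_outputs_rejected(self):
        gcs = np.ones((5, 3))
        gcs[2, 1] = np.inf
        with pytest.raises(ValueError, match="finite"):
            train_from_channel_outputs(gcs, np.random.default_rng(0).normal(size=(5, 3)))

    def test_singular_covariance_warns_and_applies_ridge(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(20, 2))
        # third channel duplicates the first: exactly singular covariance
        gcs = np.column_stack([base + [1.0, 0.0], base[:, :1] + 1.0])
        gcn = np.column_stack([base, base[:, :1]])
        with pytest.warns(RuntimeWarning, match="singular"):
            template = train_from_channel_outputs(gcs, gcn)
        assert np.all(np.isfinite(template.w_cho))

    def test_channel_space_covariance_equals_projected_image_covariance(self, bank9):
        """cov(U^T g) computed from channel outputs equals
        U^T cov(g) U computed in image space."""
        rng = np.random.default_rng(4)
        rois = rng.normal(size=(20, 9, 9))
        gc = channel_outputs(rois, bank9)
        direct = np.cov(gc, rowvar=False)
        image_cov = np.cov(rois.reshape(20, -1), rowvar=False)
        projected = bank9.matrix_U.T @ image_cov @ bank9.matrix_U
        np.testing.assert_allclose(direct, projected, rtol=1e-6)


class TestDecisionVariable:
    def test_zero_template_scores_zero(self, bank9):
        template = _trivial_template(np.zeros(bank9.n_channels))
        rng = np.random.default_rng(5)
        assert decision_variable(rng.normal(size=(9, 9)), template, bank9) == 0.0

    def test_constant_roi_scores_zero(self, bank9):
        template = _trivial_template(np.arange(float(bank9.n_channels)))
        assert decision_variable(np.full((9, 9), 37.0), template, bank9) == pytest.approx(0.0, abs=1e-10)

    def test_offset_invariance(self, bank9):
        rng = np.random.default_rng(6)
        roi = rng.normal(size=(9, 9))
        template = _trivial_template(rng.normal(size=bank9.n_channels))
        lam = decision_variable(roi, template, bank9)
        lam_shifted = decision_variable(roi + 123.4, template, bank9)
        assert lam_shifted == pytest.approx(lam, abs=1e-8)

    def test_class_mean_identity(self, bank9):
        """mean(lambda_s) - mean(lambda_n) = w^T (g_cs - g_cn)."""
        rng = np.random.default_rng(7)
        signal = rng.normal(size=(30, 9, 9)) + 0.5
        noise = rng.normal(size=(30, 9, 9))
        template = train_template(signal, noise, bank9)
        lam_s = decision_variables(signal, template, bank9)
        lam_n = decision_variables(noise, template, bank9)
        expected = template.w_cho @ (template.mean_signal_c - template.mean_noise_c)
        assert lam_s.mean() - lam_n.mean() == pytest.approx(expected, rel=1e-8)


class TestDetectability:
    def test_zero_mean_difference_gives_zero(self):
        template = CHOTemplate(
            w_cho=np.zeros(3),
            mean_signal_c=np.ones(3),
            mean_noise_c=np.ones(3),
            cov_signal_c=np.eye(3),
            cov_noise_c=np.eye(3),
            n_train_signal=10,
            n_train_noise=10,
        )
        assert detectability_index(template) == 0.0

    def test_identity_covariance_is_euclidean_norm(self):
        delta = np.array([3.0, 4.0, 0.0, 0.0])
        template = CHOTemplate(
            w_cho=delta,
            mean_signal_c=delta,
            mean_noise_c=np.zeros(4),
            cov_signal_c=np.eye(4),
            cov_noise_c=np.eye(4),
            n_train_signal=10,
            n_train_noise=10,
        )
        assert detectability_index(template) == pytest.approx(5.0)

    def test_singular_covariance_advises_ridge(self):
        template = CHOTemplate(
            w_cho=np.zeros(2),
            mean_signal_c=np.array([1.0, 0.0]),
            mean_noise_c=np.zeros(2),
            cov_signal_c=np.zeros((2, 2)),
            cov_noise_c=np.zeros((2, 2)),
            n_train_signal=10,
            n_train_noise=10,
        )
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            detectability_index(template)

    def test_matches_monte_carlo_snr_of_lambda(self):
        """d' equals (mean separation / pooled SD) of lambda on Gaussian
        channel outputs, estimated from 1e5 draws."""
        rng = np.random.default_rng(8)
        dim = 6
        A = rng.normal(size=(dim, dim))
        cov = A @ A.T + dim * np.eye(dim)
        delta = rng.normal(size=dim)
        w = scipy.linalg.solve(cov, delta, assume_a="pos")
        template = CHOTemplate(
            w_cho=w,
            mean_signal_c=delta,
            mean_noise_c=np.zeros(dim),
            cov_signal_c=cov,
            cov_noise_c=cov.copy(),
            n_train_signal=100,
            n_train_noise=100,
        )
        n = 100_000
        lam_s = rng.multivariate_normal(delta, cov, size=n) @ w
        lam_n = rng.multivariate_normal(np.zeros(dim), cov, size=n) @ w
        pooled_sd = np.sqrt(0.5 * (lam_s.var(ddof=1) + lam_n.var(ddof=1)))
        empirical = (lam_s.mean() - lam_n.mean()) / pooled_sd
        assert empirical == pytest.approx(detectability_index(template), rel=0.02)


class TestScaleInvariance:
    def test_rescaled_training_rescales_template_and_preserves_decisions(self, bank9):
        category = Category(1.0, 1, 5.0, 3.0)
        ds = generate_category_dataset(
            category, NoiseModel("white", 5.0), 40, 120, seed=9, roi_side=9
        )
        template = train_template(ds.signal_present, ds.signal_absent, bank9)
        k = 7.0
        scaled_tpl = train_template(k * ds.signal_present, k * ds.signal_absent, bank9)
        np.testing.assert_allclose(scaled_tpl.w_cho, template.w_cho / k, rtol=1e-8)

        out = run_afc(template, bank9, ds, seed=3)
        scaled_ds = type(ds)(
            category=ds.category,
            signal_present=k * ds.signal_present,
            signal_absent=k * ds.signal_absent,
            truth_profile=ds.truth_profile,
            seed=ds.seed,
            pixel_pitch=ds.pixel_pitch,
        )
        out_scaled = run_afc(scaled_tpl, bank9, scaled_ds, seed=3)
        assert out.trial_log["correct"].equals(out_scaled.trial_log["correct"])
        assert out.pc == out_scaled.pc


def _trivial_template(w):
    w = np.asarray(w, dtype=float)
    n = w.size
    return CHOTemplate(
        w_cho=w,
        mean_signal_c=np.zeros(n),
        mean_noise_c=np.zeros(n),
        cov_signal_c=np.eye(n),
        cov_noise_c=np.eye(n),
        n_train_signal=2,
        n_train_noise=2,
    )
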