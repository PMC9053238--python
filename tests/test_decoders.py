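"""Decoder tests: lagged design assembly, ridge recovery against
normal-equations and sklearn oracles, Kalman conjugate-Gaussian closed
form, pooled-covariance LDA, and the two-stage cursor calibration."""

import numpy as np
import pytest

import bciloop as b
from bciloop.decoders import DEFAULT_LAGS


class TestAssembleFeatureMatrix:
    def test_single_lag_keeps_all_bins(self, rng):
        F = rng.normal(size=(3, 10))
        X, y, off = b.assemble_feature_matrix(F, lags=(0,), target=np.arange(10))
        assert X.shape == (10, 3) and off == 0
        assert np.array_equal(y, np.arange(10))

    def test_history_trimming(self, rng):
        F = rng.normal(size=(3, 10))
        X, y, off = b.assemble_feature_matrix(F, lags=DEFAULT_LAGS, target=np.arange(10))
        assert X.shape == (6, 15) and off == 4
        assert np.array_equal(y, np.arange(4, 10))

    def test_empty_lags_rejected(self):
        with pytest.raises(ValueError):
            b.assemble_feature_matrix(np.zeros((2, 5)), lags=())

    def test_permutation_equivariant_predictions(self, rng):
        """Permuting channel order before fitting leaves predictions
        unchanged (the model is channel-label-free)."""
        F = rng.normal(size=(4, 200))
        target = rng.normal(size=200)
        perm = rng.permutation(4)
        X1, y1, _ = b.assemble_feature_matrix(F, DEFAULT_LAGS, target)
        X2, y2, _ = b.assemble_feature_matrix(F[perm], DEFAULT_LAGS, target)
        m1 = b.fit_linear_filter(X1, y1, ridge=1e-3, n_channels=4)
        m2 = b.fit_linear_filter(X2, y2, ridge=1e-3, n_channels=4)
        p1 = b.predict_linear(m1, F)
        p2 = b.predict_linear(m2, F[perm])
        assert np.allclose(p1, p2, atol=1e-8)


class TestLinearFilter:
    def test_noiseless_exact_recovery(self, rng):
        X = rng.normal(size=(100, 2))
        y = 2.0 * X[:, 0] - X[:, 1]
        m = b.fit_linear_filter(X, y, ridge=0.0, lags=(0,), n_channels=2)
        assert np.allclose(m.weights, [2.0, -1.0], atol=1e-8)
        assert m.intercept == pytest.approx(0.0, abs=1e-8)
        assert m.train_r2 == pytest.approx(1.0)

    def test_constant_feature_without_ridge_is_singular(self, rng):
        X = np.column_stack([rng.normal(size=50), np.ones(50)])
        with pytest.raises(ValueError, match="singular"):
            b.fit_linear_filter(X, rng.normal(size=50), ridge=0.0)

    def test_null_target_shrinks_weights(self, rng):
        X = rng.normal(size=(10_000, 5))
        y = rng.normal(size=10_000)  # independent of X
        m = b.fit_linear_filter(X, y, ridge=1.0, lags=(0,), n_channels=5)
        assert np.all(np.abs(m.weights) < 0.1)

    def test_matches_normal_equations_oracle(self, rng):
        """Ridge solution vs brute-force normal equations on standardized
        features, small problems, 1e-8."""
        for _ in range(5):
            X = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            lam = 0.37
            m = b.fit_linear_filter(X, y, ridge=lam, lags=(0,), n_channels=5)
            mu, sd = X.mean(0), X.std(0)
            Z = (X - mu) / sd
            w_std = np.linalg.inv(Z.T @ Z + lam * np.eye(5)) @ Z.T @ (y - y.mean())
            assert np.allclose(m.weights, w_std / sd, atol=1e-8)

    def test_matches_sklearn_ridge(self, rng):
        """Cross-check against sklearn Ridge on pre-standardized data."""
        from sklearn.linear_model import Ridge

        X = rng.normal(size=(200, 4))
        y = rng.normal(size=200)
        Z = (X - X.mean(0)) / X.std(0)
        lam = 0.8
        m = b.fit_linear_filter(Z, y, ridge=lam, lags=(0,), n_channels=4)
        sk = Ridge(alpha=lam, fit_intercept=True).fit(Z, y)
        assert np.allclose(m.weights, sk.coef_, atol=1e-6)

    def test_predict_zero_features(self):
        m = b.LinearFilterModel(
            weights=np.zeros(4), intercept=0.0, lags=(0, 1), n_channels=2,
            ridge=0.0, feature_mean=np.zeros(4), feature_scale=np.ones(4),
        )
        out = b.predict_linear(m, np.zeros((2, 10)))
        assert np.all(out == 0.0) and len(out) == 9

    def test_training_predictions_consistent(self, rng):
        F = rng.normal(size=(3, 100))
        target = rng.normal(size=100)
        X, y, off = b.assemble_feature_matrix(F, DEFAULT_LAGS, target)
        m = b.fit_linear_filter(X, y, ridge=1e-3, n_channels=3)
        assert np.allclose(b.predict_linear(m, F), X @ m.weights + m.intercept)

    def test_doubling_weights_doubles_output(self, rng):
        F = rng.normal(size=(2, 30))
        X, y, _ = b.assemble_feature_matrix(F, (0,), rng.normal(size=30))
        m = b.fit_linear_filter(X, y, ridge=1e-3, lags=(0,), n_channels=2)
        out1 = b.predict_linear(m, F) - m.intercept
        m.weights = 2.0 * m.weights
        out2 = b.predict_linear(m, F) - m.intercept
        assert np.allclose(out2, 2.0 * out1)

    def test_channel_mismatch_rejected(self, rng):
        F = rng.normal(size=(3, 50))
        X, y, _ = b.assemble_feature_matrix(F, (0,), rng.normal(size=50))
        m = b.fit_linear_filter(X, y, ridge=1e-3, n_channels=3)
        with pytest.raises(ValueError, match="channel mismatch"):
            b.predict_linear(m, rng.normal(size=(4, 50)))

    def test_json_round_trip(self, rng):
        F = rng.normal(size=(2, 60))
        X, y, _ = b.assemble_feature_matrix(F, (0, 1), rng.normal(size=60))
        m = b.fit_linear_filter(X, y, ridge=1e-2, lags=(0, 1), n_channels=2)
        back = b.LinearFilterModel.from_json(m.to_json())
        assert np.allclose(back.weights, m.weights)
        assert np.allclose(b.predict_linear(back, F), b.predict_linear(m, F))


class TestKalman:
    def test_infinite_observation_noise_ignores_observation(self):
        m = b.KalmanModel(A=[[1.0]], W=[[0.0]], H=[[1.0]], Q=[[1e12]])
        mean, cov = b.kalman_step(m, [2.0], [[1.0]], [100.0])
        assert mean[0] == pytest.approx(2.0, abs=1e-6)

    def test_scalar_conjugate_gaussian_closed_form(self):
        """Posterior matches the textbook Gaussian product to 1e-10."""
        A, W, H, Q = 0.9, 0.3, 1.4, 0.5
        m = b.KalmanModel(A=[[A]], W=[[W]], H=[[H]], Q=[[Q]])
        mu0, P0, z = 1.2, 0.8, 3.3
        mean, cov = b.kalman_step(m, [mu0], [[P0]], [z])
        mp, Pp = A * mu0, A * P0 * A + W
        # conjugate update: precision-weighted combination
        P_post = 1.0 / (1.0 / Pp + H * H / Q)
        mu_post = P_post * (mp / Pp + H * z / Q)
        assert mean[0] == pytest.approx(mu_post, abs=1e-10)
        assert cov[0, 0] == pytest.approx(P_post, abs=1e-10)

    def test_noiseless_constant_velocity_tracking(self):
        """With exact kinematics and noiseless observations the tracked
        position error vanishes over time."""
        dt = 0.2
        A = np.array([[1.0, dt], [0.0, 1.0]])
        m = b.KalmanModel(A=A, W=1e-12 * np.eye(2), H=np.eye(2), Q=1e-12 * np.eye(2))
        true = np.array([0.0, 1.0])
        mean, cov = np.array([5.0, 0.0]), np.eye(2)
        for _ in range(50):
            true = A @ true
            mean, cov = b.kalman_step(m, mean, cov, true)
        assert abs(mean[0] - true[0]) < 1e-6

    def test_fit_recovers_known_dynamics(self, rng):
        dt = 0.2
        A_true = np.array([[1.0, dt], [0.0, 0.95]])
        H_true = rng.normal(size=(6, 2))
        x = np.array([0.0, 1.0])
        states, obs = [], []
        for _ in range(2000):
            x = A_true @ x + rng.normal(0, 0.05, 2)
            states.append(x)
            obs.append(H_true @ x + rng.normal(0, 0.1, 6))
        m = b.fit_kalman(np.array(states), np.array(obs))
        assert np.allclose(m.A, A_true, atol=0.05)
        assert np.allclose(m.H, H_true, atol=0.05)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            b.KalmanModel(A=[[1.0]], W=[[-1.0]], H=[[1.0]], Q=[[1.0]])
        m = b.KalmanModel(A=[[1.0]], W=[[0.1]], H=[[1.0]], Q=[[0.1]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            b.kalman_step(m, [0.0], [[-1.0]], [0.0])


class TestLda:
    def test_separated_clouds(self, rng):
        X = np.vstack([rng.normal(0, 1, (200, 3)), rng.normal(6, 1, (200, 3))])
        y = np.array([0] * 200 + [1] * 200)
        m = b.fit_lda(X, y)
        acc = np.mean(b.predict_lda(m, X) == y)
        assert acc > 0.99

    def test_equidistant_point_ties_to_first_class(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 1.0], [3.0, 0.0]])
        y = np.array(["a", "a", "b", "b"])
        m = b.fit_lda(X, y)
        # (1.5, 0.5) is the midpoint of the class means: exact tie
        assert b.predict_lda(m, np.array([[1.5, 0.5]])) == "a"

    def test_matches_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(1.5, 1, (100, 4))])
        y = np.array([0] * 100 + [1] * 100)
        ours = b.predict_lda(b.fit_lda(X, y), X)
        theirs = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert np.mean(ours == theirs) > 0.995

    def test_singular_covariance_suggests_shrinkage(self):
        # second feature collinear with the first: rank-1 pooled covariance
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="shrinkage"):
            b.fit_lda(X, y)
        m = b.fit_lda(X, y, shrinkage=0.5)  # regularized fit succeeds
        assert m.pooled_cov.shape == (2, 2)

    def test_insufficient_classes_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            b.fit_lda(X, np.zeros(10))

    def test_classifier_factory(self):
        for kind in ("lda", "tree", "svm", "knn"):
            clf = b.discrete_classifier(kind)
            assert hasattr(clf, "fit") and hasattr(clf, "predict")
        with pytest.raises(ValueError):
            b.discrete_classifier("mlp")


class TestTwoStageCalibration:
    def test_deterministic_given_seed(self):
        p = b.SyntheticParticipant(seed=21)
        m1 = b.two_stage_calibration(p, seed=21)
        m2 = b.two_stage_calibration(p, seed=21)
        assert np.array_equal(m1.weights, m2.weights)

    @staticmethod
    def _stage1_model(m2):
        return b.LinearFilterModel(
            weights=np.asarray(m2.meta["stage1_weights"]),
            intercept=m2.intercept, lags=m2.lags, n_channels=m2.n_channels,
            ridge=m2.ridge, feature_mean=m2.feature_mean, feature_scale=m2.feature_scale,
        )

    def test_feedback_free_participant_stages_equivalent(self):
        """Without feedback coupling, stage-2 estimates the same mapping as
        stage-1 up to independent training noise: on a fresh open-loop
        block both track the target equally well and their outputs agree
        beyond what either shares with the target alone."""
        p = b.SyntheticParticipant(seed=22, feedback_coupling=0.0)
        m2 = b.two_stage_calibration(p, seed=22)
        m1 = self._stage1_model(m2)
        rng = np.random.default_rng(77)
        _, target = b.make_cursor_training_block(dt=p.bin_width)
        counts = p.respond(target, rng=rng)
        p1, p2 = b.predict_linear(m1, counts), b.predict_linear(m2, counts)
        c1 = np.corrcoef(p1, target[4:])[0, 1]
        c2 = np.corrcoef(p2, target[4:])[0, 1]
        assert abs(c1 - c2) < 0.05 and min(c1, c2) > 0.8
        assert np.corrcoef(p1, p2)[0, 1] > c1 * c2  # shared structure, not chance
        assert m2.meta["stage2_r2"] > 0.9

    @pytest.mark.parametrize("seed", [23, 41, 57])
    def test_feedback_coupled_participant_improves_with_stage2(self, seed):
        """When the participant reacts to the prediction cursor, the
        open-loop filter's gain is wrong once deployed in closed loop;
        retraining on closed-loop data lowers the held-out tracking error."""
        p = b.SyntheticParticipant(seed=seed, feedback_coupling=0.6)
        m2 = b.two_stage_calibration(p, seed=seed)
        m1 = self._stage1_model(m2)
        e2 = b.closed_loop_tracking_error(p, m2, seed=seed + 100)
        e1 = b.closed_loop_tracking_error(p, m1, seed=seed + 100)
        assert e2 < e1

    def test_held_out_tracking_quality(self):
        p = b.SyntheticParticipant(seed=24)
        m = b.two_stage_calibration(p, seed=24)
        assert b.closed_loop_tracking_corr(p, m, seed=25) > 0.7

    def test_parameter_recovery_improves_with_data(self):
        """Weight-estimate variability shrinks as the training block grows
        (1, 2, 4 minutes)."""
        errs = []
        for dur in (60.0, 120.0, 240.0):
            ws = []
            for seed in (31, 32, 33):
                p = b.SyntheticParticipant(seed=40)
                m = b.two_stage_calibration(p, duration=dur, seed=seed)
                ws.append(m.weights)
            ws = np.array(ws)
            errs.append(np.mean(np.var(ws, axis=0)))
        assert errs[2] < errs[0]
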