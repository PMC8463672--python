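import numpy as np
import pytest

from spikewac.decoders import (KalmanModel, WienerModel, fit_kalman, fit_wiener,
                               kalman_filter, predict_wiener)
from spikewac.io import KinematicSeries
from spikewac.wac import FeatureMatrix


def make_features(X, labels=None):
    labels = labels or [("n0", 1, f"f{j}") for j in range(X.shape[1])]
    return FeatureMatrix(X, labels, first_valid_bin=0)


class TestWienerFit:
    def test_noiseless_generative_recovery(self, rng):
        X = rng.normal(size=(400, 6))
        w_true = rng.normal(size=(6, 2))
        b_true = np.array([1.5, -2.0])
        Y = X @ w_true + b_true
        m = fit_wiener(make_features(X), Y)
        np.testing.assert_allclose(m.weights[:-1], w_true, atol=1e-6)
        np.testing.assert_allclose(m.weights[-1], b_true, atol=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS weights equal the brute-force (X'X)^-1 X'Y solution."""
        X = rng.normal(size=(300, 5))
        Y = X @ rng.normal(size=(5, 2)) + rng.normal(size=(300, 2))
        m = fit_wiener(make_features(X), Y)
        Xa = np.hstack([X, np.ones((300, 1))])
        ref = np.linalg.solve(Xa.T @ Xa, Xa.T @ Y)
        np.testing.assert_allclose(m.weights, ref, rtol=1e-6)

    def test_all_zero_features_fit_intercept_only(self, rng):
        Y = rng.normal(size=(50, 2)) + [3.0, -1.0]
        with pytest.warns(UserWarning, match="rank-deficient"):
            m = fit_wiener(make_features(np.zeros((50, 4))), Y)
        np.testing.assert_allclose(m.weights[:-1], 0.0, atol=1e-10)
        np.testing.assert_allclose(m.weights[-1], Y.mean(axis=0))

    def test_training_error_beats_random_alternatives(self, rng):
        """OLS optimality: no random weight vector achieves lower SSE."""
        X = rng.normal(size=(200, 4))
        Y = X @ rng.normal(size=(4, 1)) + 0.5 * rng.normal(size=(200, 1))
        m = fit_wiener(make_features(X), Y)
        Xa = np.hstack([X, np.ones((200, 1))])
        sse_fit = np.sum((Xa @ m.weights - Y) ** 2)
        for _ in range(100):
            alt = m.weights + rng.normal(scale=0.05, size=m.weights.shape)
            assert np.sum((Xa @ alt - Y) ** 2) >= sse_fit

    def test_ridge_shrinks_coefficients(self, rng):
        X = rng.normal(size=(100, 5))
        Y = X @ rng.normal(size=(5, 1))
        w0 = fit_wiener(make_features(X), Y, ridge=0.0).weights[:-1]
        w1 = fit_wiener(make_features(X), Y, ridge=100.0).weights[:-1]
        assert np.linalg.norm(w1) < np.linalg.norm(w0)


class TestWienerPredict:
    def test_training_data_reproduced_in_noiseless_case(self, rng):
        X = rng.normal(size=(100, 3))
        Y = X @ rng.normal(size=(3, 2)) + 1.0
        F = make_features(X)
        m = fit_wiener(F, Y)
        np.testing.assert_allclose(predict_wiener(m, F).data, Y, atol=1e-8)

    def test_zero_features_predict_intercept(self, rng):
        X = rng.normal(size=(100, 3))
        m = fit_wiener(make_features(X), rng.normal(size=(100, 1)))
        pred = predict_wiener(m, make_features(np.zeros((5, 3))))
        np.testing.assert_allclose(pred.data, m.weights[-1][None, :].repeat(5, 0))

    def test_linearity_doubling_features_doubles_centered_output(self, rng):
        X = rng.normal(size=(100, 3))
        m = fit_wiener(make_features(X), rng.normal(size=(100, 1)))
        p1 = predict_wiener(m, make_features(X)).data - m.weights[-1]
        p2 = predict_wiener(m, make_features(2 * X)).data - m.weights[-1]
        np.testing.assert_allclose(p2, 2 * p1, atol=1e-10)

    def test_label_mismatch_names_offending_column(self, rng):
        X = rng.normal(size=(50, 2))
        m = fit_wiener(make_features(X), rng.normal(size=(50, 1)))
        bad = FeatureMatrix(X, [("n0", 1, "f0"), ("n9", 2, "f1")], 0)
        with pytest.raises(ValueError, match="column 1"):
            predict_wiener(m, bad)


def simulate_lds(A, C, n, rng, w_scale=0.0, v_scale=0.0):
    s = A.shape[0]
    Z = np.zeros((n, s))
    z = rng.normal(size=s)
    for t in range(n):
        Z[t] = z
        z = A @ z + w_scale * rng.normal(size=s)
    F = Z @ C.T + v_scale * rng.normal(size=(n, C.shape[0]))
    return Z, F


class TestKalmanFit:
    def test_noiseless_parameter_recovery(self, rng):
        A = np.array([[0.9, 0.1], [-0.1, 0.9]])
        C = rng.normal(size=(4, 2))
        Z, F = simulate_lds(A, C, 200, rng, w_scale=0.3, v_scale=0.0)
        m = fit_kalman(make_features(F), Z, standardize_features=False)
        # observation map is exact (no observation noise)
        np.testing.assert_allclose(m.C, C, atol=1e-6)

    def test_consistency_on_long_noisy_simulation(self, rng):
        """A-hat, C-hat within 5% Frobenius relative error at 100k steps."""
        A = np.array([[0.95, 0.05], [-0.05, 0.95]])
        C = np.array([[1.0, 0.2], [0.3, -1.0], [0.5, 0.5]])
        Z, F = simulate_lds(A, C, 100_000, rng, w_scale=0.5, v_scale=0.5)
        m = fit_kalman(make_features(F), Z, standardize_features=False)
        assert np.linalg.norm(m.A - A) / np.linalg.norm(A) < 0.05
        assert np.linalg.norm(m.C - C) / np.linalg.norm(C) < 0.05

    def test_residual_covariances_are_symmetric_psd(self, rng):
        Z = rng.normal(size=(300, 3))
        F = rng.normal(size=(300, 6))
        m = fit_kalman(make_features(F), Z)
        for M in (m.W, m.V):
            np.testing.assert_allclose(M, M.T)
            assert np.linalg.eigvalsh(M).min() >= -1e-10

    def test_too_few_steps_rejected(self, rng):
        with pytest.raises(ValueError, match="steps"):
            fit_kalman(make_features(rng.normal(size=(3, 2))), rng.normal(size=(3, 4)))


class TestKalmanFilter:
    def test_exact_observation_limit_inverts_square_c(self, rng):
        """With V -> 0 and invertible C, the filtered state equals C^-1 f."""
        A = 0.9 * np.eye(2)
        C = np.array([[2.0, 0.5], [0.3, 1.5]])
        model = KalmanModel(A, C, W=0.2 * np.eye(2), V=1e-14 * np.eye(2),
                            x0=np.zeros(2), P0=np.eye(2),
                            state_names=["a", "b"],
                            feature_labels=[("n0", 1, "f0"), ("n0", 1, "f1")])
        F = rng.normal(size=(20, 2))
        out = kalman_filter(model, make_features(F))
        expected = np.linalg.solve(C, F.T).T
        np.testing.assert_allclose(out.data[1:], expected[1:], atol=1e-6)

    def test_steady_state_covariance_matches_riccati_fixed_point(self, rng):
        """Predicted covariance converges to the Riccati fixed point found
        by an independent brute-force iteration."""
        A = np.array([[0.9, 0.2], [0.0, 0.8]])
        C = rng.normal(size=(3, 2))
        W = np.diag([0.3, 0.1])
        V = np.diag([0.5, 0.4, 0.2])
        model = KalmanModel(A, C, W, V, np.zeros(2), np.eye(2),
                            ["a", "b"], [("n0", 1, f"f{j}") for j in range(3)])
        F = rng.normal(size=(300, 3))
        _, P_hist = kalman_filter(model, make_features(F), return_covariances=True)
        P = W.copy()
        for _ in range(10_000):
            K = P @ C.T @ np.linalg.inv(C @ P @ C.T + V)
            P = A @ (P - K @ C @ P) @ A.T + W
            P = (P + P.T) / 2
        np.testing.assert_allclose(P_hist[-1], P, atol=1e-8)

    def test_noiseless_model_tracks_true_state(self, rng):
        """With W = 0 and exact observations the state error decays to zero
        after a burn-in from a wrong initial state."""
        A = 0.98 * np.array([[np.cos(0.1), -np.sin(0.1)], [np.sin(0.1), np.cos(0.1)]])
        C = rng.normal(size=(4, 2))
        Z, F = simulate_lds(A, C, 300, rng)
        model = KalmanModel(A, C, W=np.zeros((2, 2)), V=0.5 * np.eye(4),
                            x0=Z[0] + 5.0 * rng.normal(size=2), P0=np.eye(2),
                            state_names=["a", "b"],
                            feature_labels=[("n0", 1, f"f{j}") for j in range(4)])
        out = kalman_filter(model, make_features(F))
        err = np.linalg.norm(out.data - Z, axis=1)
        checkpoints = err[[0, 50, 150, 299]]
        assert np.all(np.diff(checkpoints) < 0)
        assert err[-1] < 1e-2 * err[0]

    def test_covariance_stays_symmetric_psd(self, rng):
        Z = rng.normal(size=(200, 2))
        F = Z @ rng.normal(size=(2, 5)) + 0.1 * rng.normal(size=(200, 5))
        model = fit_kalman(make_features(F), Z)
        _, P_hist = kalman_filter(model, make_features(F), return_covariances=True)
        for P in P_hist[::20]:
            np.testing.assert_allclose(P, P.T, atol=1e-10)
            assert np.linalg.eigvalsh(P).min() >= -1e-10


class TestSerialization:
    def test_wiener_round_trip_bit_faithful(self, rng, tmp_path):
        X = rng.normal(size=(60, 3))
        m = fit_wiener(make_features(X), rng.normal(size=(60, 2)))
        path = tmp_path / "model.json"
        m.save(path)
        back = WienerModel.load(path)
        np.testing.assert_array_equal(back.weights, m.weights)
        assert back.feature_labels == m.feature_labels
        assert back.output_names == m.output_names

    def test_kalman_round_trip_bit_faithful(self, rng, tmp_path):
        Z = rng.normal(size=(80, 2))
        F = Z @ rng.normal(size=(2, 4)) + 0.1 * rng.normal(size=(80, 4))
        m = fit_kalman(make_features(F), Z)
        path = tmp_path / "model.json"
        m.save(path)
        back = KalmanModel.load(path)
        for k in ("A", "C", "W", "V", "x0", "P0"):
            np.testing.assert_array_equal(getattr(back, k), getattr(m, k))

    def test_loading_wrong_kind_rejected(self, rng, tmp_path):
        m = fit_wiener(make_features(rng.normal(size=(30, 2))), rng.normal(size=(30, 1)))
        path = tmp_path / "model.json"
        m.save(path)
        with pytest.raises(ValueError, match="wiener"):
            KalmanModel.load(path)
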