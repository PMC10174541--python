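import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sterilopt.models import (
    GRNNConfig,
    MLPConfig,
    RBFConfig,
    lm_step,
    load_model,
    predict,
    save_model,
    train_grnn,
    train_mlp,
    train_rbf,
)

SMALL_MLP = MLPConfig(hidden=(16, 8), max_iter=40, seed=0)


def _random_regression(rng, n=40, d=3):
    X = rng.uniform(0, 1, size=(n, d))
    y = rng.uniform(0, 100, size=n)
    return X, y


class TestMLP:
    def test_constant_target(self, rng):
        X = rng.uniform(0, 1, size=(20, 3))
        y = np.full(20, 37.5)
        m = train_mlp(X, y, SMALL_MLP)
        pred = m.predict(X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-3

    def test_noiseless_linear_function(self, rng):
        X = rng.uniform(0, 1, size=(60, 3))
        y = 3.0 * X[:, 0] + 2.0
        m = train_mlp(X, y, SMALL_MLP)
        pred = m.predict(X)
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_deterministic(self, rng):
        X, y = _random_regression(rng)
        a = train_mlp(X, y, SMALL_MLP)
        b = train_mlp(X, y, SMALL_MLP)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)
        for ba, bb in zip(a.biases, b.biases):
            assert np.array_equal(ba, bb)

    def test_rejects_nonfinite(self):
        X = np.ones((12, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_mlp(X, np.ones(12), SMALL_MLP)

    def test_lm_step_high_damping_is_scaled_gradient(self, rng):
        """With infinite damping the LM update tends to the gradient
        direction J^T r scaled by 1/lambda."""
        J = rng.standard_normal((10, 25))
        r = rng.standard_normal(10)
        lam = 1e9
        step = lm_step(J, r, lam)
        assert np.allclose(step, (J.T @ r) / lam, rtol=1e-6)


class TestRBF:
    def test_full_centers_interpolate(self, rng):
        X = rng.uniform(0, 1, size=(25, 2))  # distinct points a.s.
        y = rng.uniform(0, 100, size=25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = train_rbf(X, y, RBFConfig(n_centers=None, bias=False))
        assert np.allclose(m.predict(X), y, atol=1e-5)

    def test_single_center_constant_target(self):
        X = np.array([[0.5, 0.5]] * 4)
        y = np.full(4, 12.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = train_rbf(X, y, RBFConfig(n_centers=1, bias=False))
        assert np.allclose(m.predict(np.array([[0.5, 0.5]])), 12.0)

    def test_weights_match_normal_equations_oracle(self, rng):
        """Least-squares weights agree with an independent normal-equations
        solve of the same Gaussian basis system (5-point 1-D instance)."""
        X = np.array([[0.0], [0.3], [0.45], [0.7], [1.0]])
        y = np.array([10.0, 40.0, 35.0, 80.0, 55.0])
        m = train_rbf(X, y, RBFConfig(n_centers=3, seed=1, bias=True))
        # oracle: rebuild the basis from the fitted centers/width by hand
        D2 = ((X[:, None, :] - m.centers[None, :, :]) ** 2).sum(-1)
        Phi = np.column_stack([np.exp(-D2 / (2 * m.width**2)), np.ones(len(X))])
        w_oracle = np.linalg.solve(Phi.T @ Phi, Phi.T @ y)
        assert np.allclose(m.weights, w_oracle, atol=1e-8)

    def test_too_many_centers(self, rng):
        X, y = _random_regression(rng, n=10)
        with pytest.raises(ValueError):
            train_rbf(X, y, RBFConfig(n_centers=11))


class TestGRNN:
    def test_small_sigma_recovers_training_point(self, rng):
        X, y = _random_regression(rng)
        m = train_grnn(X, y)
        m.sigma = 1e-4
        assert np.allclose(m.predict(X[:5]), y[:5])

    def test_large_sigma_predicts_mean(self, rng):
        X, y = _random_regression(rng)
        m = train_grnn(X, y)
        m.sigma = 1e6
        assert np.allclose(m.predict(X[:3]), y.mean())

    def test_equidistant_symmetry(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0.0, 100.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = train_grnn(X, y)
        assert np.allclose(m.predict(np.array([[0.5]])), 50.0)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), sigma=st.floats(1e-3, 1e3))
    def test_bounded_by_training_targets(self, seed, sigma):
        r = np.random.default_rng(seed)
        X = r.uniform(0, 1, size=(15, 4))
        y = r.uniform(0, 100, size=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = train_grnn(X, y)
        m.sigma = sigma
        pred = m.predict(r.uniform(-0.5, 1.5, size=(10, 4)))
        assert np.all(pred >= y.min() - 1e-9) and np.all(pred <= y.max() + 1e-9)

    def test_sigma_to_zero_is_nearest_neighbour(self, rng):
        """As sigma -> 0 the GRNN reduces to 1-NN regression (brute-force
        nearest-neighbour oracle on random small instances)."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.uniform(0, 1, size=(20, 3))
            y = r.uniform(0, 100, size=20)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                m = train_grnn(X, y)
            m.sigma = 1e-5
            Q = r.uniform(0, 1, size=(8, 3))
            d = ((Q[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            nn = y[np.argmin(d, axis=1)]
            assert np.allclose(m.predict(Q), nn)

    def test_loo_sigma_selection_beats_neighbours(self, rng):
        """The selected sigma attains the minimal LOO RMSE over the grid."""
        X, y = _random_regression(rng, n=30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = train_grnn(X, y)
        from sterilopt.models import _grnn_loo_rmse
        from scipy.spatial.distance import cdist
        D2 = cdist(X, X, "sqeuclidean")
        scores = [_grnn_loo_rmse(D2, y, s) for s in m.config.sigma_grid]
        assert m.loo_rmse_ == pytest.approx(min(scores))

    def test_boundary_sigma_warns(self):
        # two identical x with different targets force maximal smoothing
        X = np.array([[0.0], [0.0], [0.0], [0.0]])
        y = np.array([0.0, 100.0, 0.0, 100.0])
        with pytest.warns(RuntimeWarning, match="grid boundary"):
            train_grnn(X, y)


class TestSharedSurface:
    def test_predict_shape_and_single_row(self, rng):
        X, y = _random_regression(rng)
        m = train_grnn(X, y)
        out = predict(m, X[0])
        assert out.shape == (1,)

    def test_untrained_rejected(self):
        with pytest.raises(ValueError):
            predict(None, np.zeros((1, 7)))

    @pytest.mark.parametrize("kind", ["MLP", "RBF", "GRNN"])
    def test_json_round_trip(self, tmp_path, rng, kind):
        X, y = _random_regression(rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if kind == "MLP":
                m = train_mlp(X, y, SMALL_MLP)
            elif kind == "RBF":
                m = train_rbf(X, y, RBFConfig(n_centers=5))
            else:
                m = train_grnn(X, y)
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        assert np.allclose(m.predict(X), m2.predict(X))
        assert m2.data_fingerprint == m.data_fingerprint
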