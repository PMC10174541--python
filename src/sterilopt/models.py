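"""Surrogate regressors: MLP (Levenberg-Marquardt), RBF network, GRNN.

Each regressor maps a scaled 7-entry feature vector to one response on
the raw percent scale; one model is trained per response.

* ``MLPModel`` — feed-forward 7 -> 128 -> 64 -> 1 network with tanh hidden
  activations and a linear output, trained by damped Gauss-Newton
  (Levenberg-Marquardt) on the mean squared error, with an inner
  validation split for early stopping.  With fewer observations than
  parameters the LM system is solved in its dual form,
  ``delta = J^T (J J^T + lambda I)^{-1} r``, which is exactly the ridge
  Gauss-Newton step but costs O(n^2 p) instead of O(p^3).
* ``RBFModel`` — Gaussian basis functions ``exp(-||x - c_k||^2 / (2 sigma^2))``
  on k-means centers, output weights solved by linear least squares.
* ``GRNNModel`` — generalized regression neural network (Nadaraya-Watson
  kernel regression): stores the training patterns and returns
  ``Y = Sd / Ss`` with ``Ss = sum_i exp(-||x - x_i||^2 / (2 sigma^2))`` and
  ``Sd`` the target-weighted analogue; the smoothing width sigma is picked
  by leave-one-out grid search.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "MLPConfig",
    "RBFConfig",
    "GRNNConfig",
    "MLPModel",
    "RBFModel",
    "GRNNModel",
    "train_mlp",
    "train_rbf",
    "train_grnn",
    "predict",
    "lm_step",
    "save_model",
    "load_model",
]


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(X, dtype=float).tobytes())
    h.update(np.ascontiguousarray(y, dtype=float).tobytes())
    return h.hexdigest()


def _check_training_inputs(X: np.ndarray, y: np.ndarray, min_rows: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per target")
    if X.shape[0] < min_rows:
        raise ValueError(f"need at least {min_rows} training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    return X, y


# ---------------------------------------------------------------------------
# MLP with Levenberg-Marquardt training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPConfig:
    """Training configuration for the MLP surrogate."""

    hidden: tuple[int, int] = (128, 64)
    seed: int = 0
    max_iter: int = 60
    val_fraction: float = 0.1
    patience: int = 8
    lambda_init: float = 1e-2
    lambda_up: float = 2.5
    lambda_down: float = 3.0
    max_escalations: int = 16  # consecutive rejected steps before declaring divergence


def lm_step(J: np.ndarray, r: np.ndarray, lam: float) -> np.ndarray:
    """One damped Gauss-Newton update ``(J^T J + lam I)^{-1} J^T r``.

    Solved in the dual form so the factorized system is n x n rather
    than p x p.  As lam -> infinity the step tends to ``J^T r / lam``,
    i.e. a gradient-descent step scaled by 1/lam.
    """
    n = J.shape[0]
    A = J @ J.T
    A[np.diag_indices_from(A)] += lam
    u = np.linalg.solve(A, r)
    return J.T @ u


class MLPModel:
    """Two-hidden-layer perceptron with tanh activations and linear output."""

    kind = "MLP"

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray], config: MLPConfig):
        self.weights = weights  # [d x h1, h1 x h2, h2 x 1]
        self.biases = biases  # [h1, h2, 1]
        self.config = config
        self.data_fingerprint: Optional[str] = None
        self.train_mse_: Optional[float] = None

    # -- forward pass -------------------------------------------------
    def _forward(self, X: np.ndarray, cache: bool = False):
        a1 = np.tanh(X @ self.weights[0] + self.biases[0])
        a2 = np.tanh(a1 @ self.weights[1] + self.biases[1])
        y = a2 @ self.weights[2][:, 0] + self.biases[2][0]
        if cache:
            return y, a1, a2
        return y

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.weights[0].shape[0]:
            raise ValueError("feature matrix has wrong number of columns")
        return self._forward(X)

    # -- parameter vector packing --------------------------------------
    def _pack(self) -> np.ndarray:
        return np.concatenate([w.ravel() for w in self.weights] + [b.ravel() for b in self.biases])

    def _unpack(self, theta: np.ndarray) -> None:
        pos = 0
        new_w = []
        for w in self.weights:
            new_w.append(theta[pos: pos + w.size].reshape(w.shape))
            pos += w.size
        new_b = []
        for b in self.biases:
            new_b.append(theta[pos: pos + b.size].reshape(b.shape))
            pos += b.size
        self.weights, self.biases = new_w, new_b

    def _jacobian(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Residual vector Jacobian d y_hat / d theta, rows = samples."""
        y, a1, a2 = self._forward(X, cache=True)
        n = X.shape[0]
        g2 = (1.0 - a2 ** 2) * self.weights[2][:, 0]  # n x h2
        g1 = (g2 @ self.weights[1].T) * (1.0 - a1 ** 2)  # n x h1
        dW1 = (X[:, :, None] * g1[:, None, :]).reshape(n, -1)
        dW2 = (a1[:, :, None] * g2[:, None, :]).reshape(n, -1)
        dw3 = a2
        J = np.concatenate([dW1, dW2, dw3, g1, g2, np.ones((n, 1))], axis=1)
        return J, y

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "hidden": list(self.config.hidden),
            "seed": self.config.seed,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "data_fingerprint": self.data_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        cfg = MLPConfig(hidden=tuple(d["hidden"]), seed=d["seed"])
        m = cls([np.asarray(w) for w in d["weights"]], [np.asarray(b) for b in d["biases"]], cfg)
        m.data_fingerprint = d.get("data_fingerprint")
        return m


def _init_mlp(n_features: int, y: np.ndarray, config: MLPConfig, rng: np.random.Generator) -> MLPModel:
    h1, h2 = config.hidden
    weights = [
        rng.standard_normal((n_features, h1)) / np.sqrt(n_features),
        rng.standard_normal((h1, h2)) / np.sqrt(h1),
        rng.standard_normal((h2, 1)) / np.sqrt(h2),
    ]
    biases = [np.zeros(h1), np.zeros(h2), np.array([float(np.mean(y))])]
    return MLPModel(weights, biases, config)


def train_mlp(X: np.ndarray, y: np.ndarray, config: MLPConfig = MLPConfig()) -> MLPModel:
    """Fit the MLP by Levenberg-Marquardt with validation early stopping."""
    X, y = _check_training_inputs(X, y, min_rows=10)
    rng = np.random.default_rng(config.seed)

    # inner validation split for early stopping
    n = X.shape[0]
    n_val = max(1, int(np.floor(config.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xt, yt, Xv, yv = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    model = _init_mlp(X.shape[1], yt, config, rng)
    lam = config.lambda_init
    theta = model._pack()
    train_mse = float(np.mean((yt - model._forward(Xt)) ** 2))
    best_val = float(np.mean((yv - model._forward(Xv)) ** 2))
    best_theta = theta.copy()
    stall = 0

    for _ in range(config.max_iter):
        if train_mse < 1e-12:
            break
        J, y_hat = model._jacobian(Xt)
        r = yt - y_hat
        A = J @ J.T
        accepted = False
        for _esc in range(config.max_escalations):
            B = A.copy()
            B[np.diag_indices_from(B)] += lam
            try:
                u = np.linalg.solve(B, r)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up
                continue
            delta = J.T @ u
            model._unpack(theta + delta)
            new_mse = float(np.mean((yt - model._forward(Xt)) ** 2))
            if np.isfinite(new_mse) and new_mse < train_mse:
                theta = theta + delta
                train_mse = new_mse
                lam = max(lam / config.lambda_down, 1e-12)
                accepted = True
                break
            lam *= config.lambda_up
        if not accepted:
            warnings.warn("LM training diverged; returning best parameters so far", RuntimeWarning)
            break
        val_mse = float(np.mean((yv - model._forward(Xv)) ** 2))
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best_theta = theta.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    # keep the parameters with the best validation error unless the final
    # train fit is an exact solution (degenerate noiseless targets)
    if train_mse >= 1e-12:
        model._unpack(best_theta)
    else:
        model._unpack(theta)
    model.train_mse_ = float(np.mean((yt - model._forward(Xt)) ** 2))
    model.data_fingerprint = _fingerprint(X, y)
    return model


# ---------------------------------------------------------------------------
# RBF network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RBFConfig:
    """Training configuration for the RBF surrogate.

    ``n_centers=None`` uses every distinct training point as a center
    (exact interpolation regime).  The shared width follows the
    d_max / sqrt(2 p) heuristic with a positive floor.
    """

    n_centers: Optional[int] = 120
    seed: int = 0
    bias: bool = True
    width_floor: float = 1e-6
    ridge: float = 1e-8


class RBFModel:
    """Gaussian radial basis function network with a linear output layer."""

    kind = "RBF"

    def __init__(self, centers: np.ndarray, width: float, weights: np.ndarray, config: RBFConfig):
        self.centers = centers
        self.width = width
        self.weights = weights  # (p,) or (p+1,) with trailing bias
        self.config = config
        self.data_fingerprint: Optional[str] = None

    def _basis(self, X: np.ndarray) -> np.ndarray:
        D2 = cdist(X, self.centers, "sqeuclidean")
        Phi = np.exp(-D2 / (2.0 * self.width ** 2))
        if self.config.bias:
            Phi = np.column_stack([Phi, np.ones(len(X))])
        return Phi

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.centers.shape[1]:
            raise ValueError("feature matrix has wrong number of columns")
        return self._basis(X) @ self.weights

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "centers": self.centers.tolist(),
            "width": self.width,
            "weights": self.weights.tolist(),
            "bias": self.config.bias,
            "seed": self.config.seed,
            "data_fingerprint": self.data_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFModel":
        cfg = RBFConfig(bias=d["bias"], seed=d["seed"])
        m = cls(np.asarray(d["centers"]), float(d["width"]), np.asarray(d["weights"]), cfg)
        m.data_fingerprint = d.get("data_fingerprint")
        return m


def train_rbf(X: np.ndarray, y: np.ndarray, config: RBFConfig = RBFConfig()) -> RBFModel:
    """Fit the RBF network: k-means centers, shared width, least-squares weights."""
    X, y = _check_training_inputs(X, y, min_rows=2)
    if config.n_centers is None:
        centers = np.unique(X, axis=0)
    else:
        if config.n_centers > X.shape[0]:
            raise ValueError("cannot place more centers than training rows")
        distinct = np.unique(X, axis=0)
        if config.n_centers >= len(distinct):
            centers = distinct
        else:
            km = KMeans(n_clusters=config.n_centers, n_init=4, random_state=config.seed)
            km.fit(X)
            centers = km.cluster_centers_

    p = len(centers)
    if p > 1:
        d_max = cdist(centers, centers).max()
        width = d_max / np.sqrt(2.0 * p)
    else:
        width = 0.0
    if width <= config.width_floor:
        width = max(width, config.width_floor)

    model = RBFModel(centers, width, np.zeros(p + int(config.bias)), config)
    Phi = model._basis(X)
    w, _res, rank, _sv = np.linalg.lstsq(Phi, y, rcond=None)
    if rank < Phi.shape[1]:
        warnings.warn("rank-deficient RBF basis; falling back to ridge solve", RuntimeWarning)
        G = Phi.T @ Phi
        G[np.diag_indices_from(G)] += config.ridge
        w = np.linalg.solve(G, Phi.T @ y)
    model.weights = w
    model.data_fingerprint = _fingerprint(X, y)
    return model


# ---------------------------------------------------------------------------
# GRNN
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GRNNConfig:
    """Training configuration for the GRNN surrogate.

    The smoothing width sigma is chosen from ``sigma_grid`` (log-spaced on
    the scaled-input metric) by minimizing the leave-one-out RMSE on the
    training set.
    """

    sigma_grid: tuple[float, ...] = tuple(np.logspace(-2, 1, 25))
    seed: int = 0


class GRNNModel:
    """Normalized Gaussian kernel regression over stored training patterns."""

    kind = "GRNN"

    def __init__(self, X: np.ndarray, y: np.ndarray, sigma: float, config: GRNNConfig):
        self.X = X
        self.y = y
        self.sigma = sigma
        self.config = config
        self.data_fingerprint: Optional[str] = None
        self.loo_rmse_: Optional[float] = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.X.shape[1]:
            raise ValueError("feature matrix has wrong number of columns")
        D2 = cdist(X, self.X, "sqeuclidean")
        # subtract the per-query minimum before exponentiating: the shared
        # factor cancels in Sd/Ss, and the prediction tends exactly to the
        # nearest stored target as sigma -> 0 instead of underflowing
        m = D2.min(axis=1, keepdims=True)
        W = np.exp(-(D2 - m) / (2.0 * self.sigma ** 2))
        return (W @ self.y) / W.sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "sigma": self.sigma,
            "seed": self.config.seed,
            "data_fingerprint": self.data_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GRNNModel":
        m = cls(np.asarray(d["X"]), np.asarray(d["y"]), float(d["sigma"]), GRNNConfig(seed=d["seed"]))
        m.data_fingerprint = d.get("data_fingerprint")
        return m


def _grnn_loo_rmse(D2: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Leave-one-out RMSE of kernel regression at a given width."""
    n = len(y)
    # stabilize with the off-diagonal row minimum (shared factor cancels)
    off = D2 + np.diag(np.full(n, np.inf))
    m = off.min(axis=1, keepdims=True)
    with np.errstate(over="ignore"):
        W = np.exp(-(off - m) / (2.0 * sigma ** 2))
    W[~np.isfinite(W)] = 0.0
    denom = W.sum(axis=1)
    pred = np.empty(n)
    ok = denom > 0
    pred[ok] = (W[ok] @ y) / denom[ok]
    if np.any(~ok):  # pragma: no cover - stabilization keeps denom > 0
        nn = np.argmin(off, axis=1)
        pred[~ok] = y[nn[~ok]]
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def train_grnn(X: np.ndarray, y: np.ndarray, config: GRNNConfig = GRNNConfig()) -> GRNNModel:
    """Store the training set and pick sigma by leave-one-out grid search."""
    X, y = _check_training_inputs(X, y, min_rows=2)
    grid = np.asarray(config.sigma_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("sigma grid must be strictly positive")
    D2 = cdist(X, X, "sqeuclidean")
    scores = np.array([_grnn_loo_rmse(D2, y, s) for s in grid])
    best = int(np.argmin(scores))
    if best in (0, len(grid) - 1):
        warnings.warn(
            "GRNN sigma selected at the grid boundary; the fit may be under- or over-smoothed",
            RuntimeWarning,
        )
    model = GRNNModel(X, y, float(grid[best]), config)
    model.loo_rmse_ = float(scores[best])
    model.data_fingerprint = _fingerprint(X, y)
    return model


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

SurrogateModel = MLPModel | RBFModel | GRNNModel
_MODEL_CLASSES = {"MLP": MLPModel, "RBF": RBFModel, "GRNN": GRNNModel}


def predict(model: SurrogateModel, X: np.ndarray) -> np.ndarray:
    """Predict one response for each row of ``X`` with a trained model."""
    if model is None or not hasattr(model, "predict"):
        raise ValueError("model is not trained")
    return model.predict(np.atleast_2d(np.asarray(X, dtype=float)))


def save_model(model: SurrogateModel, path: str | Path) -> None:
    """Write a self-describing JSON artifact (architecture + parameters)."""
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path) -> SurrogateModel:
    d = json.loads(Path(path).read_text())
    return _MODEL_CLASSES[d["kind"]].from_dict(d)
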