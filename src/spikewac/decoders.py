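"""Wiener and Kalman decoding of kinematics from sliding-window features.

**Wiener filter.**  A linear map from the feature row at step n (WAC
entries or spike counts over all neurons and taps) to the kinematic
covariates at step n, fitted by ordinary least squares with an optional
ridge penalty.  Features are z-scored and targets centred with training
statistics before solving -- WAC entries at different levels live on very
different scales -- and the returned weight matrix is expressed back in the
original units with an explicit intercept row, so prediction is a plain
affine map.

**Kalman filter.**  A linear-Gaussian state-space decoder in the standard
neural-decoding direction: the kinematic vector z[n] is the hidden state,
the feature row f[n] the observation,

    z[n+1] = A z[n] + w[n],      w ~ N(0, W)
    f[n]   = C z[n] + v[n],      v ~ N(0, V).

A and C are fitted by least squares on training data, W and V are the
residual covariances, and decoding runs the standard predict/update
recursion.  (Some presentations write the roles the other way around, with
the neural feature as the state; that direction cannot be run at test time,
when kinematics are unobserved, and the filtering recursion itself is the
standard one either way.)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import KinematicSeries
from .wac import FeatureMatrix


def _as_matrix(F):
    if isinstance(F, FeatureMatrix):
        return F.values, list(F.feature_labels)
    F = np.asarray(F, dtype=float)
    return F, [("f", 1, str(j)) for j in range(F.shape[1])]


def _as_targets(Y):
    if isinstance(Y, KinematicSeries):
        return Y.data, list(Y.names)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, [f"y{j}" for j in range(Y.shape[1])]


def _check_labels(model_labels, labels) -> None:
    if len(model_labels) != len(labels):
        raise ValueError(
            f"feature count mismatch: model has {len(model_labels)}, data has {len(labels)}"
        )
    for k, (a, b) in enumerate(zip(model_labels, labels)):
        if tuple(a) != tuple(b):
            raise ValueError(f"feature label mismatch at column {k}: model {a!r}, data {b!r}")


@dataclass
class WienerModel:
    """Fitted linear decoder; ``weights`` is (features+1) x covariates with
    the intercept in the last row, in original feature/target units."""

    weights: np.ndarray
    feature_labels: list
    output_names: list
    step_ms: float = 5.0
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.feature_labels) + 1, len(self.output_names)):
            raise ValueError("weights must be (features+1) x outputs")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def save(self, path) -> None:
        _save_json(path, {
            "kind": "wiener",
            "weights": self.weights.tolist(),
            "feature_labels": [list(l) for l in self.feature_labels],
            "output_names": list(self.output_names),
            "step_ms": self.step_ms,
            "normalization": {k: np.asarray(v).tolist() for k, v in self.normalization.items()},
        })

    @classmethod
    def load(cls, path) -> "WienerModel":
        d = _load_json(path, "wiener")
        return cls(np.array(d["weights"]), [tuple(l) for l in d["feature_labels"]],
                   d["output_names"], d["step_ms"],
                   {k: np.array(v) for k, v in d["normalization"].items()})


def fit_wiener(F, Y, ridge: float = 0.0) -> WienerModel:
    """Least-squares fit of the linear decoder.

    ``ridge`` penalizes the z-scored coefficients (0 = plain OLS).  A
    rank-deficient design with ridge 0 falls back to the minimum-norm
    solution with a warning.
    """
    X, labels = _as_matrix(F)
    Yv, names = _as_targets(Y)
    if X.shape[0] != Yv.shape[0]:
        raise ValueError(f"row mismatch: {X.shape[0]} feature rows vs {Yv.shape[0]} target rows")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    mu_x, sd_x = X.mean(axis=0), X.std(axis=0)
    sd_x = np.where(sd_x > 0, sd_x, 1.0)
    mu_y = Yv.mean(axis=0)
    Xs = (X - mu_x) / sd_x
    Yc = Yv - mu_y

    G = Xs.T @ Xs
    if ridge > 0:
        G = G + ridge * np.eye(G.shape[0])
    rhs = Xs.T @ Yc
    try:
        if ridge == 0 and np.linalg.matrix_rank(G, hermitian=True) < G.shape[0]:
            raise np.linalg.LinAlgError("rank deficient")
        B = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient design: using minimum-norm least-squares solution",
                      stacklevel=2)
        B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)

    W = B / sd_x[:, None]
    intercept = mu_y - mu_x @ W
    step_ms = F.slide_bins * F.bin_ms if isinstance(F, FeatureMatrix) else 5.0
    return WienerModel(np.vstack([W, intercept]), labels, names, step_ms,
                       {"x_mean": mu_x, "x_std": sd_x, "y_mean": mu_y})


def predict_wiener(model: WienerModel, F) -> KinematicSeries:
    """Apply a fitted Wiener decoder; output steps follow the slide grid."""
    X, labels = _as_matrix(F)
    _check_labels(model.feature_labels, labels)
    yhat = X @ model.weights[:-1] + model.weights[-1]
    return KinematicSeries(yhat, list(model.output_names), model.step_ms)


@dataclass
class KalmanModel:
    """Fitted linear-Gaussian state-space decoder (kinematics = state)."""

    A: np.ndarray
    C: np.ndarray
    W: np.ndarray
    V: np.ndarray
    x0: np.ndarray
    P0: np.ndarray
    state_names: list
    feature_labels: list
    step_ms: float = 5.0
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("A", "C", "W", "V", "x0", "P0"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        s = len(self.state_names)
        f = len(self.feature_labels)
        if self.A.shape != (s, s) or self.C.shape != (f, s):
            raise ValueError("A must be s x s and C must be f x s")
        if self.W.shape != (s, s) or self.V.shape != (f, f) or self.P0.shape != (s, s):
            raise ValueError("covariances must be square with matching dimensions")
        for M, name in ((self.W, "W"), (self.V, "V"), (self.P0, "P0")):
            if not np.allclose(M, M.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh((M + M.T) / 2).min() < -1e-8:
                raise ValueError(f"{name} must be positive semidefinite")

    def save(self, path) -> None:
        _save_json(path, {
            "kind": "kalman",
            **{k: getattr(self, k).tolist() for k in ("A", "C", "W", "V", "x0", "P0")},
            "state_names": list(self.state_names),
            "feature_labels": [list(l) for l in self.feature_labels],
            "step_ms": self.step_ms,
            "normalization": {k: np.asarray(v).tolist() for k, v in self.normalization.items()},
        })

    @classmethod
    def load(cls, path) -> "KalmanModel":
        d = _load_json(path, "kalman")
        return cls(*[np.array(d[k]) for k in ("A", "C", "W", "V", "x0", "P0")],
                   d["state_names"], [tuple(l) for l in d["feature_labels"]],
                   d["step_ms"], {k: np.array(v) for k, v in d["normalization"].items()})


def fit_kalman(F, Z, standardize_features: bool = True) -> KalmanModel:
    """Estimate the state-space parameters from aligned (features, states).

    A minimizes sum ||z[n+1] - A z[n]||^2, C minimizes sum ||f[n] - C z[n]||^2
    (both plain least squares); W and V are the residual covariances.  The
    initial state is the first training state with P0 = W.
    """
    X, labels = _as_matrix(F)
    Zv, names = _as_targets(Z)
    if X.shape[0] != Zv.shape[0]:
        raise ValueError("features and states must be row-aligned")
    n, s = Zv.shape
    if n < max(2, s + 1):
        raise ValueError(f"need at least {max(2, s + 1)} steps to fit a {s}-dim state")

    norm = {}
    if standardize_features:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
        norm = {"f_mean": mu, "f_std": sd}

    At, *_ = np.linalg.lstsq(Zv[:-1], Zv[1:], rcond=None)
    A = At.T
    Ct, *_ = np.linalg.lstsq(Zv, X, rcond=None)
    C = Ct.T
    rw = Zv[1:] - Zv[:-1] @ At
    rv = X - Zv @ Ct
    W = _sym(rw.T @ rw / rw.shape[0])
    V = _sym(rv.T @ rv / rv.shape[0])
    step_ms = F.slide_bins * F.bin_ms if isinstance(F, FeatureMatrix) else 5.0
    return KalmanModel(A, C, W, V, Zv[0], W.copy(), names, labels, step_ms, norm)


def kalman_filter(model: KalmanModel, F, return_covariances: bool = False):
    """Run the standard predict/update recursion over a feature matrix.

    predict:  x- = A x,  P- = A P A' + W
    update:   K = P- C' (C P- C' + V)^-1,
              x = x- + K (f - C x-),  P = (I - K C) P-

    P is re-symmetrized every step.  A singular innovation covariance is
    handled with the pseudo-inverse (with a warning).  Returns the filtered
    state sequence as a KinematicSeries (plus the predicted-covariance
    history if requested).
    """
    X, labels = _as_matrix(F)
    _check_labels(model.feature_labels, labels)
    if model.normalization:
        X = (X - model.normalization["f_mean"]) / model.normalization["f_std"]
    A, C, W, V = model.A, model.C, model.W, model.V
    x, P = model.x0.copy(), model.P0.copy()
    I = np.eye(len(x))
    states = np.empty((X.shape[0], len(x)))
    P_pred_hist = [] if return_covariances else None
    warned = False
    for t in range(X.shape[0]):
        x = A @ x
        P = _sym(A @ P @ A.T + W)
        if return_covariances:
            P_pred_hist.append(P.copy())
        S = C @ P @ C.T + V
        try:
            K = np.linalg.solve(S.T, (P @ C.T).T).T
        except np.linalg.LinAlgError:
            if not warned:
                warnings.warn("singular innovation covariance: using pseudo-inverse",
                              stacklevel=2)
                warned = True
            K = P @ C.T @ np.linalg.pinv(S)
        x = x + K @ (X[t] - C @ x)
        P = _sym((I - K @ C) @ P)
        states[t] = x
    out = KinematicSeries(states, list(model.state_names), model.step_ms)
    if return_covariances:
        return out, np.asarray(P_pred_hist)
    return out


def _sym(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def _save_json(path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def _load_json(path, kind: str) -> dict:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("kind") != kind:
        raise ValueError(f"{path} holds a {d.get('kind')!r} model, expected {kind!r}")
    return d
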