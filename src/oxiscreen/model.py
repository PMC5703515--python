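"""Regression multilayer perceptron estimating the AHI from oximetric features.

A single-hidden-layer feed-forward network maps the selected feature subset
x (z-scored with training-set statistics) to a continuous apnea-hypopnea
index estimate:

    y = sum_j  w_j * g(sum_i w_ij x_i + b_j) + b,       g = tanh (default)

clipped to [0, inf) at prediction time since an AHI cannot be negative.
Training minimizes the sum of squared errors plus a weight-decay penalty
nu * ||w||^2 over the connection weights, by full-batch L-BFGS from a small
seeded random initialization. Model selection — the number of hidden
neurons N_H and the decay coefficient nu — is done by leave-one-out
cross-validation repeated over random initializations, scored by the mean
intra-class correlation between held-out predictions and the reference AHI.

The architecture used for real recordings in each setting ships as a preset:
in-laboratory N_H = 12, nu = 1 over 9 features; at-home N_H = 12, nu = 4
over 8 features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .evaluate import icc
from .features import FeatureVector, extract_features
from .preprocess import preprocess

__all__ = [
    "MLPModel",
    "ModelSelectionGrid",
    "PRESET_LAB",
    "PRESET_HOME",
    "forward",
    "train",
    "loo_cv",
    "select_model",
    "predict_ahi",
]

#: feature subsets and hyperparameters selected for each recording setting
PRESET_LAB = {
    "features": ["M1t", "M2t", "M3t", "M4t", "MF", "PR", "SampEn", "CTM", "LZC"],
    "n_hidden": 12,
    "nu": 1.0,
}
PRESET_HOME = {
    "features": ["M1t", "M3t", "M4t", "SE", "PR", "SampEn", "CTM", "LZC"],
    "n_hidden": 12,
    "nu": 4.0,
}

DEFAULT_NH_GRID = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)
DEFAULT_NU_GRID = (0.1, 0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class MLPModel:
    w_in: np.ndarray        # (d, N_H)
    b_hidden: np.ndarray    # (N_H,)
    w_out: np.ndarray       # (N_H,)
    b_out: float
    nu: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    feature_names: list[str] | None = None
    activation: str = "tanh"

    @property
    def d(self) -> int:
        return self.w_in.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_in.shape[1]

    def save(self, path: str | Path) -> None:
        obj = {
            "w_in": self.w_in.tolist(), "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(), "b_out": self.b_out, "nu": self.nu,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "feature_names": self.feature_names, "activation": self.activation,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            w_in=np.asarray(obj["w_in"], float),
            b_hidden=np.asarray(obj["b_hidden"], float),
            w_out=np.asarray(obj["w_out"], float),
            b_out=float(obj["b_out"]), nu=float(obj["nu"]),
            scaler_mean=np.asarray(obj["scaler_mean"], float),
            scaler_scale=np.asarray(obj["scaler_scale"], float),
            feature_names=obj.get("feature_names"),
            activation=obj.get("activation", "tanh"),
        )


@dataclass
class ModelSelectionGrid:
    nh_values: list[int]
    nu_values: list[float]
    repetitions: int
    scores: np.ndarray      # (len(nh), len(nu)) mean ICC
    chosen: tuple[int, float]


def _activation(name: str):
    if name == "tanh":
        return np.tanh, lambda z: 1.0 - z ** 2  # derivative in terms of g(z)
    if name == "logistic":
        return (lambda a: 1.0 / (1.0 + np.exp(-a))), (lambda z: z * (1.0 - z))
    raise ValueError(f"unknown activation {name!r}")


def forward(model: MLPModel, x: np.ndarray) -> np.ndarray | float:
    """Network output for raw (unscaled) feature row(s), floored at 0."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != model.d:
        raise ValueError(f"expected {model.d} features, got {x.shape[1]}")
    xs = (x - model.scaler_mean) / model.scaler_scale
    g, _ = _activation(model.activation)
    z = g(xs @ model.w_in + model.b_hidden)
    y = np.maximum(z @ model.w_out + model.b_out, 0.0)
    return float(y[0]) if y.size == 1 else y


def _unpack(theta: np.ndarray, d: int, nh: int):
    i = 0
    w1 = theta[i : i + d * nh].reshape(d, nh); i += d * nh
    b1 = theta[i : i + nh]; i += nh
    w2 = theta[i : i + nh]; i += nh
    b2 = theta[i]
    return w1, b1, w2, b2


def train(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int = 12,
    nu: float = 1.0,
    seed: int = 0,
    activation: str = "tanh",
    max_iter: int = 500,
    tol: float = 1e-6,
    feature_names: list[str] | None = None,
) -> MLPModel:
    """Fit the network by L-BFGS on SSE + nu * ||weights||^2 (biases unpenalized).

    Features are z-scored internally with training statistics stored in the
    model. Reproducible: the same (data, seed) yields identical weights.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in training data")
    n, d = X.shape
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    g, gprime = _activation(activation)
    rng = np.random.default_rng(seed)
    theta0 = np.concatenate([
        rng.uniform(-0.5, 0.5, d * n_hidden) / np.sqrt(d),
        rng.uniform(-0.5, 0.5, n_hidden),
        rng.uniform(-0.5, 0.5, n_hidden) / np.sqrt(n_hidden),
        rng.uniform(-0.5, 0.5, 1),
    ])

    def objective(theta):
        w1, b1, w2, b2 = _unpack(theta, d, n_hidden)
        z = g(Xs @ w1 + b1)
        err = z @ w2 + b2 - y
        loss = err @ err + nu * ((w1 ** 2).sum() + (w2 ** 2).sum())
        dz = (err[:, None] * w2) * gprime(z)          # (n, nh)
        grad = np.concatenate([
            (2.0 * Xs.T @ dz + 2.0 * nu * w1).ravel(),
            2.0 * dz.sum(axis=0),
            2.0 * (z.T @ err) + 2.0 * nu * w2,
            [2.0 * err.sum()],
        ])
        return loss, grad

    res = minimize(objective, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
    w1, b1, w2, b2 = _unpack(res.x, d, n_hidden)
    return MLPModel(w_in=w1, b_hidden=b1, w_out=w2, b_out=float(b2), nu=nu,
                    scaler_mean=mean, scaler_scale=scale,
                    feature_names=feature_names, activation=activation)


def loo_cv(X: np.ndarray, y: np.ndarray, n_hidden: int, nu: float,
           seed: int = 0, **train_kwargs) -> np.ndarray:
    """Held-out predictions from n leave-one-out folds (one init seed per fold)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    fold_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        m = train(X[mask], y[mask], n_hidden, nu, seed=int(fold_seeds[i]),
                  **train_kwargs)
        preds[i] = forward(m, X[i])
    return preds


def select_model(
    X: np.ndarray,
    y: np.ndarray,
    nh_grid: tuple[int, ...] = DEFAULT_NH_GRID,
    nu_grid: tuple[float, ...] = DEFAULT_NU_GRID,
    reps: int = 100,
    seed: int = 0,
    **train_kwargs,
) -> ModelSelectionGrid:
    """Grid search over (N_H, nu) scored by repeated loo-cv mean ICC.

    Ties choose the smaller N_H, then the larger nu (the simpler, more
    regularized model).
    """
    if len(nh_grid) == 0 or len(nu_grid) == 0 or reps < 1:
        raise ValueError("grid and repetitions must be non-empty")
    y = np.asarray(y, float)
    if np.var(y) == 0:
        raise ValueError("constant target: ICC model-selection metric undefined")
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2 ** 31)
    scores = np.empty((len(nh_grid), len(nu_grid)))
    for a, nh in enumerate(nh_grid):
        for b, nu in enumerate(nu_grid):
            vals = []
            for r in range(reps):
                preds = loo_cv(X, y, nh, nu, seed=int(rep_seeds[r]), **train_kwargs)
                vals.append(icc(y, preds, ci=False)[0])
            scores[a, b] = float(np.mean(vals))
    # argmax with ties -> smaller N_H, then larger nu
    best = max(
        ((a, b) for a in range(len(nh_grid)) for b in range(len(nu_grid))),
        key=lambda ab: (scores[ab], -nh_grid[ab[0]], nu_grid[ab[1]]),
    )
    return ModelSelectionGrid(list(nh_grid), list(nu_grid), reps, scores,
                              (nh_grid[best[0]], nu_grid[best[1]]))


def predict_ahi(model: MLPModel, samples: np.ndarray, preprocessed: bool = False,
                **feature_kwargs) -> float:
    """Estimate the AHI of one recording: preprocess, featurize, run the net."""
    x = np.asarray(samples, float)
    if not preprocessed:
        x, _ = preprocess(x)
    fv = extract_features(x, **feature_kwargs)
    names = model.feature_names
    if names is None:
        raise ValueError("model has no stored feature subset")
    return float(forward(model, fv.to_array(tuple(names))))
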