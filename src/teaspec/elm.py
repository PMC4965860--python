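"""Extreme learning machine regression on selected wavenumbers.

A single-hidden-layer network whose hidden weights and biases are drawn
once, uniformly on [-1, 1], and never trained; only the output layer is
solved, by minimum-norm least squares on the realised hidden activations.
Inputs are rescaled per feature to [-1, 1] before the random layer so the
sigmoid operates in its responsive range. The hidden-node sweep mirrors the
study design: node counts from 1 to 80 scored by leave-one-out RMSECV on
the calibration set only, with the hidden layer redrawn for every fit from
one seeded stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ELMModel", "fit_elm", "predict_elm", "sweep_hidden_nodes"]

DEFAULT_NODE_RANGE = range(1, 81)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ELMModel:
    n_hidden: int
    input_weights: np.ndarray   # (h, d)
    biases: np.ndarray          # (h,)
    output_weights: np.ndarray  # (h,)
    activation: str
    feature_min: np.ndarray
    feature_max: np.ndarray
    seed: int

    def scale(self, X: np.ndarray) -> np.ndarray:
        """Map inputs to [-1, 1] with the training min/max; degenerate
        (zero-range) features pass through at 0."""
        span = self.feature_max - self.feature_min
        safe = np.where(span == 0, 1.0, span)
        Z = 2.0 * (X - self.feature_min) / safe - 1.0
        return np.where(span == 0, 0.0, Z)

    def hidden(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.scale(X) @ self.input_weights.T + self.biases)


def fit_elm(X: np.ndarray, y: np.ndarray, n_hidden: int, seed: int = 0) -> ELMModel:
    """Draw the random hidden layer and solve the output weights.

    beta = pinv(H) @ y, the minimum-norm least-squares solution on the
    realised hidden matrix H. Deterministic given the seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n_hidden < 1:
        raise ValueError(f"n_hidden must be >= 1, got {n_hidden}")
    if n < 2 or n != y.size:
        raise ValueError("need matching X rows and y length >= 2")
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    if np.any(fmin == fmax):
        warnings.warn(
            "degenerate zero-range feature(s) passed through at 0", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, d))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    model = ELMModel(
        n_hidden=n_hidden,
        input_weights=W,
        biases=b,
        output_weights=np.zeros(n_hidden),
        activation="sigmoid",
        feature_min=fmin,
        feature_max=fmax,
        seed=int(seed),
    )
    H = model.hidden(X)
    model.output_weights = np.linalg.pinv(H) @ y
    return model


def predict_elm(model: ELMModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.feature_min.size:
        raise ValueError(
            f"model was trained on {model.feature_min.size} features, "
            f"got {X.shape[1]}"
        )
    return model.hidden(X) @ model.output_weights


def sweep_hidden_nodes(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    node_range=DEFAULT_NODE_RANGE,
    seed: int = 0,
    return_predictions: bool = False,
):
    """LOO-RMSECV over hidden-node counts; the hidden layer is redrawn per
    fold fit from one seeded stream. Returns (best count, RMSECV per count),
    plus the out-of-fold prediction matrix when ``return_predictions``.

    Ties go to the smaller node count. Prediction-set data never enters the
    sweep. Node counts at or above the fold size enter the interpolation
    regime (warned, still evaluated).
    """
    X_cal = np.atleast_2d(np.asarray(X_cal, dtype=float))
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    node_range = list(node_range)
    if not node_range:
        raise ValueError("node_range must be nonempty")
    n = X_cal.shape[0]
    if max(node_range) >= n - 1:
        warnings.warn(
            f"node counts >= fold size {n - 1} reach the interpolation regime",
            stacklevel=2,
        )
    child_seeds = np.random.SeedSequence(seed).generate_state(len(node_range) * n)
    child_seeds = child_seeds % np.uint32(2**31)
    rmsecv = np.empty(len(node_range))
    preds = np.empty((len(node_range), n))
    idx = np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-fold degenerate-feature chatter
        for j, h in enumerate(node_range):
            for i in range(n):
                rows = idx != i
                m = fit_elm(
                    X_cal[rows], y_cal[rows], h, seed=int(child_seeds[j * n + i])
                )
                preds[j, i] = predict_elm(m, X_cal[i:i + 1])[0]
            rmsecv[j] = np.sqrt(np.mean((preds[j] - y_cal) ** 2))
    minima = np.flatnonzero(rmsecv == rmsecv.min())
    best = min(node_range[i] for i in minima)
    if return_predictions:
        return best, rmsecv, preds
    return best, rmsecv
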