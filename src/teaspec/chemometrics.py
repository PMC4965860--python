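"""PLS regression, leave-one-out cross-validation, PCA and the metric sextet.

PLS1 is implemented as NIPALS with single-response deflation. For one
response the inner NIPALS loop converges in a single step, so each latent
variable costs three matrix-vector products. Leave-one-out cross-validation
exploits the fact that every PLS1 quantity depends on the predictors only
through inner products in the row space: when p >> n the matrix is first
rotated onto its right singular vectors (an n-dimensional representation),
which leaves every fold's predictions unchanged but makes the n refits cheap.

Model quality is reported as the chemometrics sextet: Pearson correlation
and root-mean-square error on calibration (R_C, RMSEC), leave-one-out
cross-validation (R_CV, RMSECV) and the held-out prediction set (R_P,
RMSEP); errors are in mg adulterant per g tea.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "PLSModel",
    "ModelMetrics",
    "PCAResult",
    "LOOCVResult",
    "fit_pls",
    "predict_pls",
    "loo_cv",
    "metrics",
    "rmse",
    "pearson",
    "pca",
]

_EPS = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 model in NIPALS form.

    ``coefficients`` act on centered predictors:
    ``y_hat = (X - x_mean) @ coefficients + y_mean``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray     # (p, k)
    x_loadings: np.ndarray  # (p, k)
    y_loadings: np.ndarray  # (k,)
    scores: np.ndarray      # (n, k)
    coefficients: np.ndarray  # (p,)


@dataclass
class ModelMetrics:
    """R/RMSE on calibration, cross-validation and prediction sets."""

    r_c: float
    rmsec: float
    r_cv: float
    rmsecv: float
    r_p: float
    rmsep: float

    def as_dict(self, digits: int = 3) -> dict:
        return {
            "R_C": round(self.r_c, digits),
            "RMSEC": round(self.rmsec, digits),
            "R_CV": round(self.r_cv, digits),
            "RMSECV": round(self.rmsecv, digits),
            "R_P": round(self.r_p, digits),
            "RMSEP": round(self.rmsep, digits),
        }


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance_pct: np.ndarray
    loadings: np.ndarray


@dataclass
class LOOCVResult:
    """RMSECV per component count plus the chosen model's CV statistics."""

    rmsecv_per_component: np.ndarray  # (K,), index k-1 = k components
    n_components: int
    rmsecv: float
    r_cv: float
    predictions: np.ndarray  # out-of-fold predictions at the chosen count


def _nipals(Xc: np.ndarray, yc: np.ndarray, k_max: int):
    """Single-response NIPALS deflation; stops early on exhausted rank/fit."""
    n, p = Xc.shape
    W = np.zeros((p, k_max))
    P = np.zeros((p, k_max))
    q = np.zeros(k_max)
    T = np.zeros((n, k_max))
    Xd = Xc.copy()
    yd = yc.astype(float).copy()
    x_scale = max(np.linalg.norm(Xc), 1.0)
    y_scale = max(np.linalg.norm(yc), 1.0)
    k = 0
    while k < k_max:
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= _EPS * x_scale * y_scale:
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= (_EPS * x_scale) ** 2:
            break
        pl = Xd.T @ t / tt
        qk = (yd @ t) / tt
        Xd -= np.outer(t, pl)
        yd -= qk * t
        W[:, k], P[:, k], q[k], T[:, k] = w, pl, qk, t
        k += 1
    return W[:, :k], P[:, :k], q[:k], T[:, :k]


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 with ``n_components`` latent variables.

    A constant response yields the zero-coefficient model (predictions equal
    the mean). If deflation exhausts the predictor rank before reaching the
    requested count, the data cannot support that many components and a
    ``ValueError`` suggests fewer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size or n < 2:
        raise ValueError(f"need matching X rows and y length >= 2, got {n}, {y.size}")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W, P, q, T = _nipals(Xc, yc, n_components)
    k = W.shape[1]
    if k < n_components:
        # Distinguish a perfect/constant fit (y deflated to ~0) from rank
        # exhaustion of X, which is a user error.
        y_resid = yc - T @ q if k else yc
        if np.linalg.norm(y_resid) > 1e-8 * max(np.linalg.norm(yc), 1.0):
            raise ValueError(
                f"predictors support only {k} components; "
                f"request fewer than {n_components}"
            )
    return PLSModel(
        n_components=k if k else n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=_coefficients(W, P, q),
    )


def predict_pls(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"model was trained on {model.x_mean.size} variables, "
            f"got {X.shape[1]}"
        )
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def _predict_prefixes(W, P, q, x_mean, y_mean, x_new, k_out):
    """Predictions of one new row for every component-count prefix 1..k_out."""
    xd = x_new - x_mean
    yhat = y_mean
    out = np.full(k_out, y_mean)
    for k in range(min(W.shape[1], k_out)):
        t = xd @ W[:, k]
        yhat = yhat + q[k] * t
        xd = xd - t * P[:, k]
        out[k] = yhat
    if W.shape[1] < k_out and W.shape[1] > 0:
        out[W.shape[1]:] = out[W.shape[1] - 1]
    return out


def _loo_prediction_matrix(X: np.ndarray, y: np.ndarray, k_max: int) -> np.ndarray:
    """Out-of-fold predictions, shape (n, k_max), column k-1 = k components.

    When p > n the predictors are rotated onto the right singular vectors of
    X first; PLS1 predictions are invariant under that rotation because every
    fold's rows (including the held-out one) lie in the rotated span.
    """
    n, p = X.shape
    if p > n:
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        Z = X @ Vt.T
    else:
        Z = X
    preds = np.empty((n, k_max))
    idx = np.arange(n)
    for i in range(n):
        rows = idx != i
        Zi, yi = Z[rows], y[rows]
        x_mean = Zi.mean(axis=0)
        y_mean = yi.mean()
        W, P, q, _ = _nipals(Zi - x_mean, yi - y_mean, k_max)
        preds[i] = _predict_prefixes(W, P, q, x_mean, y_mean, Z[i], k_max)
    return preds


def loo_cv(X: np.ndarray, y: np.ndarray, max_components: int = 20) -> LOOCVResult:
    """Leave-one-out CV over component counts 1..max_components.

    The chosen component count minimises RMSECV; ties go to the smaller
    count. An infeasible ``max_components`` is clipped with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError(f"leave-one-out CV needs at least 3 samples, got {n}")
    feasible = min(n - 2, p)
    if max_components > feasible:
        warnings.warn(
            f"max_components={max_components} clipped to {feasible} "
            f"for {n} samples x {p} variables",
            stacklevel=2,
        )
        max_components = feasible
    if max_components < 1:
        raise ValueError("no feasible component count")
    preds = _loo_prediction_matrix(X, y, max_components)
    rmsecv_k = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen = int(np.argmin(rmsecv_k)) + 1  # argmin returns the first minimum
    oof = preds[:, chosen - 1]
    return LOOCVResult(
        rmsecv_per_component=rmsecv_k,
        n_components=chosen,
        rmsecv=float(rmsecv_k[chosen - 1]),
        r_cv=pearson(y, oof),
        predictions=oof,
    )


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def pearson(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("correlation needs two equal-length vectors, length >= 2")
    if np.ptp(y_true) == 0:
        raise ValueError("correlation undefined for constant y_true")
    if np.ptp(y_pred) == 0:
        return 0.0  # degenerate predictions carry no linear association
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple:
    """(Pearson R, RMSE) between measured and predicted dose."""
    return pearson(y_true, y_pred), rmse(y_true, y_pred)


def pca(X: np.ndarray) -> PCAResult:
    """Column-mean-centered PCA of the spectra matrix.

    Explained percentages are 100 * sigma_i^2 / sum(sigma^2) over all
    components, so they sum to 100.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    model = _SkPCA(n_components=min(X.shape))
    scores = model.fit_transform(X)
    return PCAResult(
        scores=scores,
        explained_variance_pct=100.0 * model.explained_variance_ratio_,
        loadings=model.components_,
    )
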