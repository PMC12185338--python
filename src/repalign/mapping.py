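"""Ridge mapping from raw features to embedding dimensions, and the
activation-maximization objective evaluated as a pure function.

An l2-regularized linear regression links an object-by-feature matrix
(e.g. penultimate-layer network activations) to a learned behavioural
embedding, so that embedding dimensions can be predicted for new stimuli.
The regularization strength is selected per embedding dimension by
cross-validated R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import softmax
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .features import FeatureMatrix
from .model import PointEmbedding

__all__ = ["LinearMap", "fit_ridge", "predict_dimensions", "am_loss"]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 7))


@dataclass
class LinearMap:
    """Fitted affine map features -> embedding with per-dimension diagnostics.

    ``ridge_lambda`` holds the per-dimension selected penalty;
    ``r2_per_dim`` the cross-validated held-out R^2 at that penalty.
    """

    weights: np.ndarray  # (d, k)
    intercept: np.ndarray  # (k,)
    ridge_lambda: np.ndarray  # (k,)
    r2_per_dim: np.ndarray  # (k,)
    dim_ids: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        k = self.weights.shape[1]
        if not (len(self.intercept) == len(self.ridge_lambda)
                == len(self.r2_per_dim) == k):
            raise ValueError("inconsistent shapes in LinearMap")
        if self.dim_ids is None:
            self.dim_ids = [f"dim_{j}" for j in range(k)]

    def save(self, path: str | Path) -> None:
        np.savez(path, weights=self.weights, intercept=self.intercept,
                 **{"lambda": self.ridge_lambda}, r2=self.r2_per_dim,
                 dim_ids=np.asarray(self.dim_ids))

    @classmethod
    def load(cls, path: str | Path) -> "LinearMap":
        with np.load(path, allow_pickle=False) as data:
            return cls(data["weights"], data["intercept"], data["lambda"],
                       data["r2"], [str(x) for x in data["dim_ids"]])

    def r2_frame(self):
        import pandas as pd

        return pd.DataFrame({"dim": self.dim_ids, "lambda": self.ridge_lambda,
                             "r2": self.r2_per_dim})


def _r2(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    ss_res = ((y - yhat) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 - ss_res / ss_tot


def fit_ridge(features: FeatureMatrix, Y: PointEmbedding,
              lambda_grid=DEFAULT_LAMBDA_GRID, folds: int = 5,
              seed: int = 0) -> LinearMap:
    """Per-dimension ridge regression with cross-validated penalty selection.

    For every lambda in the grid a multi-output ridge is fitted on each
    training fold and scored by held-out R^2 per embedding dimension; each
    dimension keeps the lambda maximizing its mean CV R^2 and is refitted
    on all objects at that lambda. ``r2_per_dim`` reports the CV (held-out)
    R^2 at the selected lambda.
    """
    X, T = features.values, Y.values
    m = X.shape[0]
    if features.m != Y.m:
        raise ValueError("features and embedding must have the same objects")
    if not m > folds or folds < 2:
        raise ValueError("need m > folds >= 2")
    lambda_grid = np.asarray(sorted(lambda_grid), dtype=float)
    if (lambda_grid <= 0).any():
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("lambda = 0 with singular design")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    k = T.shape[1]
    cv_r2 = np.zeros((len(lambda_grid), k))
    for li, lam in enumerate(lambda_grid):
        scores = np.zeros((folds, k))
        for fi, (tr, te) in enumerate(kf.split(X)):
            model = Ridge(alpha=lam).fit(X[tr], T[tr])
            scores[fi] = _r2(T[te], model.predict(X[te]))
        cv_r2[li] = scores.mean(axis=0)
    best = cv_r2.argmax(axis=0)
    weights = np.zeros((X.shape[1], k))
    intercept = np.zeros(k)
    for lam_idx in np.unique(best):
        cols = np.nonzero(best == lam_idx)[0]
        model = Ridge(alpha=lambda_grid[lam_idx]).fit(X, T[:, cols])
        weights[:, cols] = model.coef_.reshape(len(cols), -1).T
        intercept[cols] = model.intercept_
    return LinearMap(weights, intercept, lambda_grid[best],
                     cv_r2[best, np.arange(k)], list(Y.dim_ids))


def predict_dimensions(map_: LinearMap, features: FeatureMatrix,
                       rectified: bool = True) -> PointEmbedding | np.ndarray:
    """Affine prediction of embedding dimensions from features.

    Rectified by default so the output satisfies the non-negative
    embedding invariant; pass ``rectified=False`` for the raw affine
    values (e.g. to check affinity).
    """
    if features.d != map_.weights.shape[0]:
        raise ValueError("feature dimensionality does not match the map")
    pred = features.values @ map_.weights + map_.intercept
    if not rectified:
        return pred
    return PointEmbedding(np.maximum(pred, 0.0), list(features.object_ids),
                          list(map_.dim_ids))


def am_loss(y_hat: np.ndarray, j: int, alpha: float = 1.0,
            beta: float = 1.0, specificity: str = "softmax") -> float:
    """Activation-maximization objective for embedding dimension ``j``.

    loss = -alpha * y_hat[j] - beta * log p_j, where the specificity term
    p_j concentrates probability mass on dimension j; with the default
    softmax specificity p_j = exp(y_hat_j) / sum_l exp(y_hat_l). The size
    reward (alpha) favours large values on dimension j; the specificity
    reward (beta) favours dominance of j over the other dimensions. Lower
    is better; minimized over stimuli (or latent codes) by an external
    optimizer that is out of scope here.
    """
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    y_hat = np.asarray(y_hat, dtype=float)
    if specificity == "softmax":
        p_j = float(softmax(y_hat)[j])
    else:
        raise ValueError(f"unknown specificity {specificity!r}")
    if p_j == 0.0:
        warnings.warn("specificity term vanished; loss is +inf")
        return float("inf")
    return float(-alpha * y_hat[j] - beta * np.log(p_j))
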