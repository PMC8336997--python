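"""Post-hoc feature selection by decoupling shrinkage and selection (DSS).

The pooled stacked model is typically dense (ridge is one of the base
learners, so every pooled slope can be nonzero). To obtain a sparse model
without refitting the ensemble, the fitted linear predictor
eta* = b0* + X b* is approximated by an adaptive-lasso regression of eta*
on X: per-coefficient penalty multipliers 1/|b*_j| make strong dense
effects cheap to keep and exclude features with b*_j = 0 outright
(infinite multiplier). Lambda is chosen by cross-validation or adjusted to
hit a requested number of non-zero coefficients; the cap is never exceeded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np

from .glm_core import (
    deviance,
    default_path_ratio,
    enet_path,
    lambda_max,
    lambda_path,
)
from .stacking import FoldAssignment, StackedModel, make_folds

__all__ = [
    "SparseApproximation",
    "dss_fit",
    "dss_path",
    "dss_select",
    "dss_cv_deviance",
]


@dataclass
class SparseApproximation:
    """Sparse coefficients (gamma0, gamma) approximating the pooled predictor."""

    gamma0: float
    gamma: np.ndarray
    nonzero: int
    lam: float

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.gamma0 + X @ self.gamma


def _adaptive_weights(model: StackedModel) -> np.ndarray:
    """1/|pooled slope|, renormalized to mean 1 over the finite entries.

    The renormalization keeps the lambda scale comparable with a plain
    lasso; it rescales the whole path without changing support ordering."""
    beta = model.pooled_slopes
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(beta)
    finite = np.isfinite(w)
    if finite.any():
        w = w / np.mean(w[finite])
        w[~finite] = np.inf
    return w


def _target(model: StackedModel, X: np.ndarray) -> np.ndarray:
    return model.linear_predictor(X)


def dss_fit(X, model: StackedModel, lam: float) -> SparseApproximation:
    """Adaptive-lasso approximation of the pooled linear predictor at one lam.

    Gaussian regression of eta* on X with unpenalized intercept and penalty
    multipliers 1/|pooled slope| (features with zero pooled slope are
    excluded)."""
    X = np.asarray(X, dtype=float)
    eta_star = _target(model, X)
    w = _adaptive_weights(model)
    if not np.isfinite(w).any():
        warnings.warn("all pooled slopes are zero; returning the intercept-only "
                      "approximation")
        return SparseApproximation(float(eta_star.mean()),
                                   np.zeros_like(model.pooled_slopes), 0, float(lam))
    _, B, b0, _ = enet_path(X, eta_star, "gaussian", 1.0, lams=[lam], weights=w)
    gamma = B[0]
    return SparseApproximation(float(b0[0]), gamma, int(np.count_nonzero(gamma)),
                               float(lam))


def _dss_lambda_path(X, eta_star, w, nlambda: int) -> np.ndarray:
    n, p = X.shape
    lmax = lambda_max(X, eta_star, "gaussian", 1.0, weights=w)
    # nudge above lambda-max so the path truly starts at the null model
    return lambda_path(lmax * 1.000001, nlambda=nlambda,
                       ratio=default_path_ratio(n, p))


def dss_path(X, model: StackedModel, nlambda: int = 100) -> List[SparseApproximation]:
    """Approximations over a decreasing lambda path on the adaptive problem.

    The support grows from empty (path start) towards the support of the
    pooled slopes, never exceeding min(n, p) active coefficients."""
    X = np.asarray(X, dtype=float)
    eta_star = _target(model, X)
    w = _adaptive_weights(model)
    if not np.isfinite(w).any():
        warnings.warn("all pooled slopes are zero; returning intercept-only path")
        c = float(eta_star.mean())
        z = np.zeros_like(model.pooled_slopes)
        return [SparseApproximation(c, z.copy(), 0, np.nan) for _ in range(nlambda)]
    lams = _dss_lambda_path(X, eta_star, w, nlambda)
    _, B, b0, _ = enet_path(X, eta_star, "gaussian", 1.0, lams=lams, weights=w)
    return [
        SparseApproximation(float(b0[il]), B[il],
                            int(np.count_nonzero(B[il])), float(lams[il]))
        for il in range(lams.size)
    ]


def dss_select(
    X,
    model: StackedModel,
    criterion: str = "cv",
    target: Optional[int] = None,
    folds: Optional[FoldAssignment] = None,
    nlambda: int = 100,
) -> SparseApproximation:
    """Pick one approximation from the path.

    criterion="cv": lambda minimizing the K-fold CV mean squared error of
    predicting eta* (the folds of the stacked fit unless overridden; ties
    -> larger lambda). criterion="nzero": the densest path element whose
    non-zero count stays at or below `target` (ties -> larger lambda), so
    the cap is never exceeded."""
    X = np.asarray(X, dtype=float)
    path = dss_path(X, model, nlambda=nlambda)
    if criterion == "nzero":
        if target is None or target < 0:
            raise ValueError("criterion='nzero' requires a non-negative target")
        nz = np.array([a.nonzero for a in path])
        ok = np.flatnonzero(nz <= target)
        best = int(ok[np.argmax(nz[ok])])  # densest under the cap; first on ties
        if nz.max() < target:
            warnings.warn(f"only {int(nz.max())} features available on the path; "
                          f"target {target} not reached")
        return path[best]
    if criterion != "cv":
        raise ValueError("criterion must be 'cv' or 'nzero'")
    eta_star = _target(model, X)
    w = _adaptive_weights(model)
    if not np.isfinite(w).any():
        return path[0]
    if folds is None:
        folds = model.base.folds
    lams = np.array([a.lam for a in path])
    pred = np.empty((X.shape[0], lams.size))
    for f in range(1, folds.K + 1):
        tr = folds.train_mask(f)
        te = folds.test_mask(f)
        _, B, b0, _ = enet_path(X[tr], eta_star[tr], "gaussian", 1.0, lams=lams,
                                weights=w)
        pred[te] = b0[None, :] + X[te] @ B.T
    mse = np.mean((eta_star[:, None] - pred) ** 2, axis=0)
    return path[int(np.argmin(mse))]


def dss_cv_deviance(
    X,
    y,
    model: StackedModel,
    approx: SparseApproximation,
    folds: Optional[FoldAssignment] = None,
) -> dict:
    """Fold-wise deviance of the sparsified model against the outcome.

    For each fold the adaptive-lasso approximation is refit (at approx.lam,
    on the training rows' pooled predictor) and scored on the held-out
    outcome; reported next to the dense model's in-sample deviance so the
    user can check how much predictivity sparsification costs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if folds is None:
        folds = model.base.folds
    eta_star = _target(model, X)
    w = _adaptive_weights(model)
    eta_sparse = np.empty(X.shape[0])
    if not np.isfinite(w).any():
        eta_sparse[:] = eta_star.mean()
    else:
        for f in range(1, folds.K + 1):
            tr = folds.train_mask(f)
            te = folds.test_mask(f)
            _, B, b0, _ = enet_path(X[tr], eta_star[tr], "gaussian", 1.0,
                                    lams=[approx.lam], weights=w)
            eta_sparse[te] = b0[0] + X[te] @ B[0]
    fam = model.family
    return {
        "sparse_cv_deviance": deviance(y, eta_sparse, fam),
        "dense_deviance": deviance(y, model.linear_predictor(X), fam),
        "nonzero": approx.nonzero,
    }
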