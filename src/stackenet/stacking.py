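"""Stacked elastic net.

Fits elastic-net base learners over a grid of mixing parameters alpha with
shared K-fold cross-validation, collects their cross-validated linear
predictors into an n x m matrix H, fits a [0,1]-box-constrained lasso meta
learner of the outcome on H (same folds), and pools everything into a single
intercept and coefficient vector:

    pooled_intercept = omega0 + sum_k omega_k * intercept_k
    pooled_slopes_j  = sum_k omega_k * slopes_jk

Because the meta learner combines *linear predictors* (link scale), the
ensemble collapses exactly to one coefficient vector per feature, so the
stacked model is as interpretable as a single penalized GLM. Selecting the
arg-min base learner instead of weighting them ("cross-validation selection"
rather than "super-learning") gives the tuned elastic net comparator, which
is the special case omega0 = 0, omega one-hot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import glm_core
from .glm_core import (
    Family,
    GlmFit,
    get_family,
    deviance,
    enet_path,
    lambda_max,
    lambda_path,
    default_path_ratio,
    _validate_outcome,
)

__all__ = [
    "FoldAssignment",
    "AlphaGrid",
    "BaseEnsembleFit",
    "MetaFit",
    "StackedModel",
    "make_folds",
    "fit_base_learners",
    "fit_meta_learner",
    "pool_coefficients",
    "predict",
    "select_tuned",
    "extract_base",
    "fit_stacked_elastic_net",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]

#: cross-validation fold-fit tolerance (see docs/methods.md); single fits
#: requested through fit_penalized_glm use the tighter glm_core default.
CV_TOL = 1e-7


@dataclass
class FoldAssignment:
    """Per-sample fold labels in {1..K}, deterministic given the seed."""

    fold_id: np.ndarray
    K: int
    seed: int

    def test_mask(self, k: int) -> np.ndarray:
        return self.fold_id == k

    def train_mask(self, k: int) -> np.ndarray:
        return self.fold_id != k


@dataclass
class AlphaGrid:
    """Elastic-net mixing parameters, ascending in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("alpha grid must be a non-empty 1-D sequence")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("alpha values must lie in [0, 1]")
        if np.any(np.diff(self.values) < 0):
            raise ValueError("alpha values must be sorted ascending")

    @classmethod
    def default(cls, m: int = 21) -> "AlphaGrid":
        """m equally spaced values covering ridge (0) through lasso (1)."""
        if m < 1:
            raise ValueError("m must be positive")
        return cls(np.array([0.5]) if m == 1 else np.linspace(0.0, 1.0, m))

    @property
    def m(self) -> int:
        return self.values.size

    def index_of(self, alpha: float) -> int:
        hits = np.flatnonzero(np.isclose(self.values, alpha, atol=1e-12))
        if hits.size == 0:
            raise ValueError(f"alpha={alpha} is not a grid member")
        return int(hits[0])


@dataclass
class BaseEnsembleFit:
    """Per-alpha tuned base learners plus their cross-validated linear predictors."""

    alpha_grid: AlphaGrid
    lambda_star: np.ndarray      # (m,) tuned lambda per alpha
    intercepts: np.ndarray       # (m,)
    slopes: np.ndarray           # (p, m)
    H_cv: np.ndarray             # (n, m) out-of-fold linear predictors at lambda_star
    cv_loss: np.ndarray          # (m,) CV deviance at lambda_star
    folds: FoldAssignment
    family: Family


@dataclass
class MetaFit:
    """Box-constrained lasso meta learner: intercept and weights in [0,1]."""

    omega0: float
    omega: np.ndarray
    lambda_star: float


@dataclass
class StackedModel:
    """Pooled stacked elastic net: one intercept and one slope per feature."""

    family: Family
    pooled_intercept: float
    pooled_slopes: np.ndarray
    base: BaseEnsembleFit
    meta: MetaFit

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = self.pooled_slopes.shape[0]
        if X.shape[1] != p:
            raise ValueError(f"X has {X.shape[1]} columns but the model has {p} slopes")
        return self.pooled_intercept + X @ self.pooled_slopes


def make_folds(
    n: int,
    K: int,
    y: Optional[np.ndarray] = None,
    family: Union[str, Family] = "gaussian",
    seed: int = 0,
) -> FoldAssignment:
    """Deterministic fold assignment; stratified on the classes for binomial."""
    if K < 2:
        raise ValueError("K must be at least 2")
    if n < K:
        raise ValueError("need at least K samples")
    fam = get_family(family)
    fold_id = np.empty(n, dtype=int)
    if fam.name == "binomial" and y is not None:
        splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
        split_args = (np.zeros(n), np.asarray(y))
    else:
        splitter = KFold(n_splits=K, shuffle=True, random_state=seed)
        split_args = (np.zeros(n),)
    for k, (_, test_idx) in enumerate(splitter.split(*split_args), start=1):
        fold_id[test_idx] = k
    return FoldAssignment(fold_id, K, seed)


def _cv_curve(y: np.ndarray, eta: np.ndarray, fam: Family) -> np.ndarray:
    """Mean deviance per lambda from an (n, nlambda) held-out eta matrix."""
    mu = fam.inverse_link(eta)
    return fam.unit_deviance(y[:, None], mu).mean(axis=0)


def fit_base_learners(
    X,
    y,
    family: Union[str, Family] = "gaussian",
    alpha_grid: Optional[AlphaGrid] = None,
    folds: Optional[FoldAssignment] = None,
    nlambda: int = 100,
    ratio: Optional[float] = None,
    tol: float = CV_TOL,
    scale_outcome: bool = True,
) -> BaseEnsembleFit:
    """Cross-validate each base learner over its lambda path with shared folds.

    For each alpha: the path is built on the full data; each fold fit runs
    over the whole path with warm starts; lambda* minimizes the pooled
    held-out deviance (ties -> larger lambda); the H column holds the
    held-out linear predictors at lambda*; the final coefficients are the
    full-data refit at lambda*."""
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_outcome(y, fam)
    n, p = X.shape
    if alpha_grid is None:
        alpha_grid = AlphaGrid.default()
    if folds is None:
        folds = make_folds(n, 10, y, fam, seed=0)
    if ratio is None:
        ratio = default_path_ratio(n, p)
    m = alpha_grid.m
    lambda_star = np.empty(m)
    intercepts = np.empty(m)
    slopes = np.empty((p, m))
    H_cv = np.empty((n, m))
    cv_loss = np.empty(m)
    for k, alpha in enumerate(alpha_grid.values):
        lmax = lambda_max(X, y, fam, alpha)
        lams = lambda_path(lmax, nlambda=nlambda, ratio=ratio)
        H_eta = np.empty((n, lams.size))
        for f in range(1, folds.K + 1):
            tr = folds.train_mask(f)
            te = folds.test_mask(f)
            _, B, b0, _ = enet_path(X[tr], y[tr], fam, alpha, lams=lams, tol=tol,
                                    scale_outcome=scale_outcome)
            H_eta[te] = b0[None, :] + X[te] @ B.T
        curve = _cv_curve(y, H_eta, fam)
        istar = int(np.argmin(curve))  # first minimum = largest lambda on ties
        _, Bf, b0f, _ = enet_path(X, y, fam, alpha, lams=lams, tol=tol,
                                  scale_outcome=scale_outcome)
        lambda_star[k] = lams[istar]
        intercepts[k] = b0f[istar]
        slopes[:, k] = Bf[istar]
        H_cv[:, k] = H_eta[:, istar]
        cv_loss[k] = curve[istar]
    return BaseEnsembleFit(alpha_grid, lambda_star, intercepts, slopes, H_cv,
                           cv_loss, folds, fam)


def fit_meta_learner(
    H_cv,
    y,
    family: Union[str, Family] = "gaussian",
    folds: Optional[FoldAssignment] = None,
    nlambda: int = 100,
    ratio: Optional[float] = None,
    tol: float = CV_TOL,
) -> MetaFit:
    """Lasso of y on the cross-validated linear predictors, weights in [0,1].

    Uses the same folds as the base learners; the intercept is unpenalized
    and unconstrained; lambda* minimizes the held-out deviance (ties ->
    larger lambda); the returned weights are the all-rows refit at lambda*."""
    fam = get_family(family)
    H = np.asarray(H_cv, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = H.shape
    if folds is None:
        folds = make_folds(n, 10, y, fam, seed=0)
    lower = np.zeros(m)
    upper = np.ones(m)
    if ratio is None:
        ratio = default_path_ratio(n, m)
    lmax = lambda_max(H, y, fam, 1.0, lower=lower, upper=upper)
    lams = lambda_path(lmax, nlambda=nlambda, ratio=ratio)
    eta = np.empty((n, lams.size))
    for f in range(1, folds.K + 1):
        tr = folds.train_mask(f)
        te = folds.test_mask(f)
        _, B, b0, _ = enet_path(H[tr], y[tr], fam, 1.0, lams=lams,
                                lower=lower, upper=upper, tol=tol)
        eta[te] = b0[None, :] + H[te] @ B.T
    curve = _cv_curve(y, eta, fam)
    istar = int(np.argmin(curve))
    _, Bf, b0f, _ = enet_path(H, y, fam, 1.0, lams=lams,
                              lower=lower, upper=upper, tol=tol)
    return MetaFit(float(b0f[istar]), Bf[istar], float(lams[istar]))


def pool_coefficients(
    base: BaseEnsembleFit, meta: MetaFit, family: Optional[Union[str, Family]] = None
) -> StackedModel:
    """Collapse the ensemble into pooled estimates (exact, no approximation)."""
    if meta.omega.shape[0] != base.alpha_grid.m:
        raise ValueError("meta dimension does not match the base ensemble")
    fam = get_family(family) if family is not None else base.family
    pooled_intercept = float(meta.omega0 + base.intercepts @ meta.omega)
    pooled_slopes = base.slopes @ meta.omega
    return StackedModel(fam, pooled_intercept, pooled_slopes, base, meta)


def predict(
    model: Union[StackedModel, GlmFit],
    X_new,
    scale: str = "link",
    family: Optional[Union[str, Family]] = None,
) -> np.ndarray:
    """Predictions on the link scale (eta) or the response scale (h^-1(eta)).

    A StackedModel carries its family; for a bare GlmFit pass the family
    explicitly when asking for response-scale predictions (default gaussian,
    where both scales coincide)."""
    if scale not in ("link", "response"):
        raise ValueError("scale must be 'link' or 'response'")
    eta = model.linear_predictor(np.asarray(X_new, dtype=float))
    if scale == "link":
        return eta
    if isinstance(model, StackedModel):
        fam = model.family
    else:
        fam = get_family(family) if family is not None else get_family("gaussian")
    return fam.inverse_link(eta)


def select_tuned(base: BaseEnsembleFit) -> Tuple[int, GlmFit]:
    """The tuned elastic net: the base learner with minimal CV deviance.

    Ties break toward the smaller alpha."""
    k = int(np.argmin(base.cv_loss))
    fit = GlmFit(
        intercept=float(base.intercepts[k]),
        slopes=base.slopes[:, k].copy(),
        lam=float(base.lambda_star[k]),
        converged=True,
        alpha=float(base.alpha_grid.values[k]),
    )
    return k, fit


def extract_base(base: BaseEnsembleFit, alpha: float) -> GlmFit:
    """The refitted single-alpha learner for a grid member (e.g. ridge at 0)."""
    k = base.alpha_grid.index_of(alpha)
    return GlmFit(
        intercept=float(base.intercepts[k]),
        slopes=base.slopes[:, k].copy(),
        lam=float(base.lambda_star[k]),
        converged=True,
        alpha=float(base.alpha_grid.values[k]),
    )


def fit_stacked_elastic_net(
    X,
    y,
    family: Union[str, Family] = "gaussian",
    m: int = 21,
    K: int = 10,
    seed: int = 0,
    nlambda: int = 100,
    ratio: Optional[float] = None,
    tol: float = CV_TOL,
) -> StackedModel:
    """Fit the full stacked elastic net: folds -> base learners -> meta -> pool."""
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = make_folds(X.shape[0], K, y, fam, seed=seed)
    grid = AlphaGrid.default(m)
    base = fit_base_learners(X, y, fam, grid, folds, nlambda=nlambda, ratio=ratio,
                             tol=tol)
    meta = fit_meta_learner(base.H_cv, y, fam, folds, nlambda=nlambda, tol=tol)
    return pool_coefficients(base, meta, fam)


# ---------------------------------------------------------------------------
# serialization

def _sparse_columns(slopes: np.ndarray):
    cols = []
    for k in range(slopes.shape[1]):
        idx = np.flatnonzero(slopes[:, k])
        cols.append({"index": idx.tolist(), "value": slopes[idx, k].tolist()})
    return cols


def model_to_dict(model: StackedModel) -> dict:
    base = model.base
    return {
        "format": "stackenet-model",
        "family": model.family.name,
        "alpha_grid": base.alpha_grid.values.tolist(),
        "lambda_star": base.lambda_star.tolist(),
        "base_intercepts": base.intercepts.tolist(),
        "base_slopes": _sparse_columns(base.slopes),
        "n_features": int(base.slopes.shape[0]),
        "cv_loss": base.cv_loss.tolist(),
        "meta": {
            "omega0": model.meta.omega0,
            "omega": model.meta.omega.tolist(),
            "lambda_star": model.meta.lambda_star,
        },
        "pooled_intercept": model.pooled_intercept,
        "pooled_slopes": model.pooled_slopes.tolist(),
        "folds": {"K": base.folds.K, "seed": base.folds.seed,
                  "fold_id": base.folds.fold_id.tolist()},
    }


def model_from_dict(doc: dict) -> StackedModel:
    if doc.get("format") != "stackenet-model":
        raise ValueError("not a stackenet model document")
    fam = get_family(doc["family"])
    p = int(doc["n_features"])
    grid = AlphaGrid(np.asarray(doc["alpha_grid"], dtype=float))
    slopes = np.zeros((p, grid.m))
    for k, col in enumerate(doc["base_slopes"]):
        slopes[np.asarray(col["index"], dtype=int), k] = col["value"]
    folds = FoldAssignment(np.asarray(doc["folds"]["fold_id"], dtype=int),
                           int(doc["folds"]["K"]), int(doc["folds"]["seed"]))
    base = BaseEnsembleFit(
        alpha_grid=grid,
        lambda_star=np.asarray(doc["lambda_star"], dtype=float),
        intercepts=np.asarray(doc["base_intercepts"], dtype=float),
        slopes=slopes,
        H_cv=np.empty((0, grid.m)),
        cv_loss=np.asarray(doc["cv_loss"], dtype=float),
        folds=folds,
        family=fam,
    )
    meta = MetaFit(float(doc["meta"]["omega0"]),
                   np.asarray(doc["meta"]["omega"], dtype=float),
                   float(doc["meta"]["lambda_star"]))
    return StackedModel(fam, float(doc["pooled_intercept"]),
                        np.asarray(doc["pooled_slopes"], dtype=float), base, meta)


def save_model(model: StackedModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> StackedModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
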