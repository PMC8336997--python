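"""Penalized generalized linear model core.

Families (gaussian/identity, binomial/logit, poisson/log), unit deviances,
the weighted elastic-net penalty with box constraints, lambda-path
construction and a coordinate-descent solver. Everything above (stacking,
post-hoc selection, benchmarks) is built on this module.

The solver minimizes

    -(1/n) loglik(y; b0, b) + lam * sum_j w_j ((1-alpha)/2 b_j^2 + alpha |b_j|)

subject to elementwise bounds on b, with an unpenalized intercept. Features
are standardized internally (mean 0, sd 1 with denominator n) and the
coefficients returned on the original scale, so lambda is comparable across
features regardless of their units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.special import expit, xlogy

from ._cd import cd_solve, enet_path_gaussian

__all__ = [
    "Family",
    "PenaltySpec",
    "GlmFit",
    "get_family",
    "elastic_net_penalty",
    "deviance",
    "lambda_max",
    "lambda_path",
    "default_path_ratio",
    "enet_path",
    "fit_penalized_glm",
    "stationarity_residual",
]

#: guards the lambda-max formula for pure ridge (alpha = 0 has no finite lambda-max)
ALPHA_FLOOR = 1e-3

_MU_EPS = 1e-10


@dataclass(frozen=True)
class Family:
    """Distribution / link / unit-deviance triple for a GLM (canonical links)."""

    name: str
    link: Callable[[np.ndarray], np.ndarray]
    inverse_link: Callable[[np.ndarray], np.ndarray]
    unit_deviance: Callable[[np.ndarray, np.ndarray], np.ndarray]
    # working weight for IRLS; equals the variance function at the canonical link
    variance: Callable[[np.ndarray], np.ndarray]

    def __repr__(self) -> str:  # pragma: no cover
        return f"Family({self.name!r})"


def _binomial_unit_dev(y, mu):
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    return -2.0 * (xlogy(y, mu) + xlogy(1.0 - y, 1.0 - mu))


def _poisson_unit_dev(y, mu):
    mu = np.maximum(mu, _MU_EPS)
    return 2.0 * (xlogy(y, y / mu) - (y - mu))


GAUSSIAN = Family(
    "gaussian",
    link=lambda mu: np.asarray(mu, dtype=float),
    inverse_link=lambda eta: np.asarray(eta, dtype=float),
    unit_deviance=lambda y, mu: (y - mu) ** 2,
    variance=lambda mu: np.ones_like(mu),
)
BINOMIAL = Family(
    "binomial",
    link=lambda mu: np.log(mu / (1.0 - mu)),
    inverse_link=expit,
    unit_deviance=_binomial_unit_dev,
    variance=lambda mu: mu * (1.0 - mu),
)
POISSON = Family(
    "poisson",
    link=np.log,
    inverse_link=np.exp,
    unit_deviance=_poisson_unit_dev,
    variance=lambda mu: mu,
)

_FAMILIES = {f.name: f for f in (GAUSSIAN, BINOMIAL, POISSON)}


def get_family(family: Union[str, Family]) -> Family:
    if isinstance(family, Family):
        return family
    try:
        return _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(_FAMILIES)}"
        ) from None


@dataclass
class PenaltySpec:
    """Elastic-net penalty: strength lam, mixing alpha, per-coefficient
    multipliers (inf excludes a coefficient) and box constraints."""

    lam: float
    alpha: float
    weights: Optional[np.ndarray] = None
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    def resolved(self, p: int):
        """Return (weights, lower, upper) as length-p arrays."""
        w = np.ones(p) if self.weights is None else np.asarray(self.weights, dtype=float)
        lo = np.full(p, -np.inf) if self.lower is None else np.broadcast_to(
            np.asarray(self.lower, dtype=float), (p,)
        ).copy()
        up = np.full(p, np.inf) if self.upper is None else np.broadcast_to(
            np.asarray(self.upper, dtype=float), (p,)
        ).copy()
        if w.shape != (p,):
            raise ValueError(f"penalty weights have length {w.shape}, expected {p}")
        if np.any(w < 0):
            raise ValueError("penalty weights must be non-negative")
        if np.any(lo > up):
            raise ValueError("lower bounds must not exceed upper bounds")
        return w, lo, up


@dataclass
class GlmFit:
    """A single penalized GLM fit on the original feature scale."""

    intercept: float
    slopes: np.ndarray
    lam: float
    converged: bool = True
    alpha: Optional[float] = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.slopes.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns but the fit has {self.slopes.shape[0]} slopes"
            )
        return self.intercept + X @ self.slopes


def elastic_net_penalty(beta, lam: float, alpha: float, weights=None) -> float:
    """Evaluate lam * sum_j w_j ((1-alpha)/2 beta_j^2 + alpha |beta_j|).

    Coefficients that are exactly zero contribute zero even under infinite
    weight (infinite weight means "excluded", so a zero coefficient is
    feasible there)."""
    beta = np.asarray(beta, dtype=float)
    if weights is None:
        weights = np.ones_like(beta)
    weights = np.asarray(weights, dtype=float)
    if beta.shape != weights.shape:
        raise ValueError("beta and weights must have the same length")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    terms = (1.0 - alpha) / 2.0 * beta**2 + alpha * np.abs(beta)
    contrib = np.where(beta == 0.0, 0.0, weights * terms)
    return float(lam * np.sum(contrib))


def deviance(y, eta, family: Union[str, Family]) -> float:
    """Mean unit deviance of the linear predictor eta against the outcome y.

    Gaussian: mean squared error. Binomial: mean of -2[y log mu + (1-y) log(1-mu)].
    Poisson: mean of 2[y log(y/mu) - (y - mu)]."""
    fam = get_family(family)
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if y.shape != eta.shape:
        raise ValueError("y and eta must have the same length")
    if np.any(np.isnan(y)) or np.any(np.isnan(eta)):
        raise ValueError("NaN values in deviance input")
    mu = fam.inverse_link(eta)
    return float(np.mean(fam.unit_deviance(y, mu)))


def _standardize(X: np.ndarray, standardize: bool):
    """Column means and scales (sd with denominator n; scale 1 if constant
    or if standardize is off)."""
    m = X.mean(axis=0)
    if standardize:
        s = np.sqrt(np.mean((X - m) ** 2, axis=0))
    else:
        s = np.ones(X.shape[1])
    const = s <= 1e-12
    s = np.where(const, 1.0, s)
    Xs = (X - m) / s
    return Xs, m, s, const


def lambda_max(
    X,
    y,
    family: Union[str, Family] = "gaussian",
    alpha: float = 1.0,
    weights=None,
    lower=None,
    upper=None,
    standardize: bool = True,
) -> float:
    """Smallest lam at which every penalized slope is exactly zero.

    Computed as max_j score_j / (max(alpha, 1e-3) * w_j) with
    score_j = |<x_j, y - mu0>| / n at the intercept-only fit mu0, on the
    standardized feature scale. With one-sided box constraints only the
    feasible sign of the score counts."""
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    spec = PenaltySpec(0.0, alpha, weights, lower, upper)
    w, lo, up = spec.resolved(p)
    Xs, _, _, const = _standardize(X, standardize)
    mu0 = np.full(n, y.mean())
    score = Xs.T @ (y - mu0) / n
    pos = np.where(up > 0, np.maximum(score, 0.0), 0.0)
    neg = np.where(lo < 0, np.maximum(-score, 0.0), 0.0)
    allowed = np.maximum(pos, neg)
    ok = np.isfinite(w) & (w > 0) & ~const
    if not np.any(ok):
        return 0.0
    lmax = np.max(allowed[ok] / w[ok]) / max(alpha, ALPHA_FLOOR)
    return float(lmax)


def lambda_path(lmax: float, nlambda: int = 100, ratio: float = 0.01) -> np.ndarray:
    """Exponentially decreasing sequence from lmax down to ratio * lmax."""
    if nlambda < 2:
        raise ValueError("nlambda must be at least 2")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if lmax <= 0:
        warnings.warn("lambda_max is zero (null signal); using a default tiny path")
        lmax = 1e-3
    return np.geomspace(lmax, ratio * lmax, nlambda)


def default_path_ratio(n: int, p: int) -> float:
    """0.01 in the high-dimensional regime (p >= n), 1e-4 otherwise."""
    return 0.01 if p >= n else 1e-4


def _irls_mu_w(fam: Family, eta: np.ndarray):
    if fam.name == "binomial":
        mu = np.clip(expit(eta), 1e-5, 1.0 - 1e-5)
        return mu, mu * (1.0 - mu)
    if fam.name == "poisson":
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        return mu, np.maximum(mu, 1e-8)
    raise ValueError(fam.name)  # pragma: no cover


def _irls_single(Xs, y, fam, pf, lo, up, alpha, lam, beta, b0, tol, maxit,
                 irls_tol=1e-8, irls_max=50):
    converged = False
    for _ in range(irls_max):
        eta = b0 + Xs @ beta
        mu, wv = _irls_mu_w(fam, eta)
        z = eta + (y - mu) / wv
        r = z - eta
        d = np.einsum("i,ij,ij->j", wv, Xs, Xs) / Xs.shape[0]
        beta_old = beta.copy()
        b0_old = b0
        b0, _, _ = cd_solve(Xs, r, wv, d, beta, b0, pf, lo, up, lam, alpha, tol, maxit)
        if max(np.max(np.abs(beta - beta_old)), abs(b0 - b0_old)) < irls_tol:
            converged = True
            break
    return b0, converged


def _ridge_svd_path(Xs, y, c: float, lams: np.ndarray):
    """Exact gaussian ridge path (uniform penalty weight c, no bounds)."""
    n = Xs.shape[0]
    yc = y - y.mean()
    U, dvec, Vt = np.linalg.svd(Xs, full_matrices=False)
    uy = dvec * (U.T @ yc)
    B = np.empty((lams.shape[0], Xs.shape[1]))
    for il, lam in enumerate(lams):
        B[il] = Vt.T @ (uy / (dvec**2 + n * lam * c))
    b0 = np.full(lams.shape[0], y.mean())
    return B, b0, np.ones(lams.shape[0], dtype=bool)


def enet_path(
    X,
    y,
    family: Union[str, Family] = "gaussian",
    alpha: float = 1.0,
    lams: Optional[Sequence[float]] = None,
    weights=None,
    lower=None,
    upper=None,
    nlambda: int = 100,
    ratio: Optional[float] = None,
    standardize: bool = True,
    tol: float = 1e-14,
    maxit: int = 100_000,
    warm: Optional[GlmFit] = None,
    scale_outcome: bool = False,
):
    """Fit the elastic net over a decreasing lambda path with warm starts.

    Returns (lams, B, b0, conv) where B is (nlambda, p) on the original
    feature scale and conv flags per-lambda convergence.

    With scale_outcome=True (gaussian only) the outcome is divided by its
    sample standard deviation before solving and the fit is rescaled back,
    so the ridge/lasso balance of the penalty is invariant to the outcome
    units — the convention of the reference R implementation stack. Supplied
    lambda values are interpreted on the original outcome scale.
    """
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has length {y.shape[0]} but X has {n} rows")
    if scale_outcome and fam.name == "gaussian":
        sd_y = float(np.sqrt(np.mean((y - y.mean()) ** 2)))
        if sd_y > 0:
            sub_lams = None if lams is None else np.asarray(lams, dtype=float) / sd_y
            sub_lower = None if lower is None else np.asarray(lower, dtype=float) / sd_y
            sub_upper = None if upper is None else np.asarray(upper, dtype=float) / sd_y
            sub_warm = None if warm is None else GlmFit(
                warm.intercept / sd_y, warm.slopes / sd_y, warm.lam, warm.converged)
            got_lams, B, b0, conv = enet_path(
                X, y / sd_y, fam, alpha, lams=sub_lams, weights=weights,
                lower=sub_lower, upper=sub_upper, nlambda=nlambda, ratio=ratio,
                standardize=standardize, tol=tol, maxit=maxit, warm=sub_warm,
            )
            return got_lams * sd_y, B * sd_y, b0 * sd_y, conv
    spec = PenaltySpec(0.0, alpha, weights, lower, upper)
    w, lo, up = spec.resolved(p)
    Xs, m, s, const = _standardize(X, standardize)
    pf = w.copy()
    pf[const] = np.inf  # zero-variance features are frozen at zero
    lo_s = lo * s
    up_s = up * s
    if lams is None:
        lmax = lambda_max(X, y, fam, alpha, weights=w, lower=lower, upper=upper,
                          standardize=standardize)
        if ratio is None:
            ratio = default_path_ratio(n, p)
        lams = lambda_path(lmax, nlambda=nlambda, ratio=ratio)
    lams = np.asarray(lams, dtype=float)

    if warm is not None:
        beta_init = warm.slopes * s
        b0_init = warm.intercept + float(m @ warm.slopes)
    else:
        beta_init = np.zeros(p)
        ybar = float(y.mean())
        if fam.name == "gaussian":
            b0_init = ybar
        elif fam.name == "binomial":
            b0_init = float(fam.link(np.clip(ybar, 1e-5, 1 - 1e-5)))
        else:
            b0_init = float(np.log(max(ybar, 1e-8)))

    uniform = np.all(np.isfinite(pf)) and np.ptp(pf) == 0 if p else False
    unbounded = not (np.any(np.isfinite(lo)) or np.any(np.isfinite(up)))
    if fam.name == "gaussian" and alpha == 0.0 and uniform and unbounded:
        Bs, b0s, conv = _ridge_svd_path(Xs, y, float(pf[0]), lams)
    elif fam.name == "gaussian":
        Xf = np.asfortranarray(Xs)
        d = np.mean(Xs**2, axis=0)
        Bs, b0s, conv = enet_path_gaussian(
            Xf, y, d, pf, lo_s, up_s, alpha, lams, tol, maxit, b0_init, beta_init
        )
    else:
        nlam = lams.shape[0]
        Bs = np.empty((nlam, p))
        b0s = np.empty(nlam)
        conv = np.zeros(nlam, dtype=bool)
        beta = beta_init.copy()
        b0 = b0_init
        Xf = np.asfortranarray(Xs)
        for il, lam in enumerate(lams):
            b0, ok = _irls_single(Xf, y, fam, pf, lo_s, up_s, alpha, lam, beta, b0,
                                  tol, maxit)
            Bs[il] = beta
            b0s[il] = b0
            conv[il] = ok
    B = Bs / s
    b0_orig = b0s - B @ m
    return lams, B, b0_orig, conv


def fit_penalized_glm(
    X,
    y,
    family: Union[str, Family],
    penalty: PenaltySpec,
    warm: Optional[GlmFit] = None,
    standardize: bool = True,
    tol: float = 1e-14,
    maxit: int = 100_000,
) -> GlmFit:
    """Fit a penalized GLM at a single regularization strength.

    The intercept is unpenalized and unconstrained; slopes are returned on
    the original feature scale and respect the penalty's box constraints."""
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _validate_outcome(y, fam)
    lams, B, b0, conv = enet_path(
        X, y, fam, penalty.alpha, lams=[penalty.lam], weights=penalty.weights,
        lower=penalty.lower, upper=penalty.upper, standardize=standardize,
        tol=tol, maxit=maxit, warm=warm,
    )
    if not conv[0]:
        warnings.warn("penalized GLM did not reach tolerance; returning best iterate")
    return GlmFit(float(b0[0]), B[0], float(penalty.lam), bool(conv[0]),
                  alpha=penalty.alpha)


def _validate_outcome(y: np.ndarray, fam: Family):
    if np.any(np.isnan(y)):
        raise ValueError("NaN in outcome")
    if fam.name == "binomial" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binomial outcome must be coded 0/1")
    if fam.name == "poisson":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson outcome must be non-negative integers")


def stationarity_residual(
    X, y, family, penalty: PenaltySpec, fit: GlmFit, standardize: bool = True
) -> float:
    """Coordinate-wise fixed-point residual of a fit on the standardized scale.

    Zero at an exact optimum: each coordinate is compared with the value a
    single exact coordinate minimization (given all others) would assign."""
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w, lo, up = penalty.resolved(p)
    Xs, m, s, const = _standardize(X, standardize)
    pf = w.copy()
    pf[const] = np.inf
    b = fit.slopes * s
    b0 = fit.intercept + float(m @ fit.slopes)
    eta = b0 + Xs @ b
    if fam.name == "gaussian":
        mu, wv = eta, np.ones(n)
    else:
        mu, wv = _irls_mu_w(fam, eta)
    # canonical links: gradient of the mean negative log-likelihood is -X'(y - mu)/n
    g = -Xs.T @ (y - mu) / n
    d = np.einsum("i,ij,ij->j", wv, Xs, Xs) / n
    la = penalty.lam * penalty.alpha
    lr = penalty.lam * (1.0 - penalty.alpha)
    resid = 0.0
    for j in range(p):
        if not np.isfinite(pf[j]) or d[j] <= 0:
            continue
        z = -g[j] + d[j] * b[j]
        t = la * pf[j]
        if z > t:
            bnew = (z - t) / (d[j] + lr * pf[j])
        elif z < -t:
            bnew = (z + t) / (d[j] + lr * pf[j])
        else:
            bnew = 0.0
        bnew = min(max(bnew, lo[j] * s[j]), up[j] * s[j])
        resid = max(resid, abs(bnew - b[j]))
    resid = max(resid, abs(np.sum(y - mu) / np.sum(wv)))
    return float(resid)
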