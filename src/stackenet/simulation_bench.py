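"""Synthetic-data generators and benchmark runners.

Two families of simulations:

* Prediction scenarios: three latent signals z1, z2, z3 ~ N(0,1) define the
  outcome y = z1 + z2 + z3; each feature is either pure noise or a mix
  sqrt(pi) * z_l + sqrt(1-pi) * eps_j of one signal and private noise, so
  every feature has unit variance. Scenario 1 is sparse (two strong
  features, pi = 0.9), scenario 2 dense (all features weak, pi = 0.1),
  scenario 3 intermediate (10% moderate features, pi = 0.5). Models train
  on a small subsample and are scored by mean squared error on the held-out
  remainder.

* Estimation scenarios: X ~ MVN(0, Sigma) with compound symmetry
  (unit diagonal, rho = 0.1 off-diagonal), q coefficients equal to one
  (sparse q=5, dense q=50, mixed q=20), gaussian noise with half the sample
  sd of the linear predictor. Coefficient error is measured separately on
  the truly-zero and truly-nonzero coordinates, and support recovery under
  a hard cap on the number of selected features is scored by precision
  TP / (TP + FP).

All replications are seeded (seed + replication index) and every method in
a replication sees the same data and folds, so comparisons are paired.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .glm_core import Family, deviance, enet_path, get_family
from .stacking import (
    AlphaGrid,
    StackedModel,
    extract_base,
    fit_base_learners,
    fit_meta_learner,
    fit_stacked_elastic_net,
    make_folds,
    pool_coefficients,
    predict,
    select_tuned,
)
from .posthoc_selection import dss_select

__all__ = [
    "PredictionScenario",
    "EstimationScenario",
    "BenchResult",
    "prediction_scenario",
    "estimation_scenario",
    "simulate_prediction",
    "simulate_estimation",
    "run_prediction_benchmark",
    "run_estimation_benchmark",
    "run_selection_benchmark",
    "wilcoxon_signed_rank",
    "repeated_nested_cv",
]

#: comparator alphas within the default 21-point grid
METHOD_ALPHA = {"ridge": 0.0, "ridge_like": 0.05, "lasso_like": 0.95, "lasso": 1.0}
#: the four methods entering the best-approach fraction
BEST_SET = ("ridge", "lasso", "tune", "stack")


@dataclass
class PredictionScenario:
    """Feature construction plan: per-feature signal index (0 = noise,
    1 or 2 = the tied latent signal) and mixing weight pi."""

    id: int
    n: int
    p: int
    signal_index: np.ndarray
    pi: np.ndarray


def prediction_scenario(sid: int, n: int = 10_000, p: int = 500) -> PredictionScenario:
    """Build scenario 1 (sparse), 2 (dense) or 3 (intermediate).

    For non-default p the scenario keeps its proportions: scenario 1 ties
    the first and last feature, scenario 2 splits all features half/half,
    scenario 3 ties the first and last 5%."""
    signal = np.zeros(p, dtype=int)
    pi = np.zeros(p)
    if sid == 1:
        signal[0], signal[-1] = 1, 2
        pi[0] = pi[-1] = 0.9
    elif sid == 2:
        half = p // 2
        signal[:half], signal[half:] = 1, 2
        pi[:] = 0.1
    elif sid == 3:
        block = max(1, round(0.05 * p))
        signal[:block], signal[-block:] = 1, 2
        pi[:block] = pi[-block:] = 0.5
    else:
        raise ValueError("scenario id must be 1, 2 or 3")
    return PredictionScenario(sid, n, p, signal, pi)


@dataclass
class EstimationScenario:
    """Correlated-gaussian design with q unit effects."""

    n: int = 100
    p: int = 500
    q: int = 5
    rho: float = 0.1
    noise_factor: float = 0.5

    def __post_init__(self):
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.q >= self.p:
            raise ValueError("q must be smaller than p")


_ESTIMATION_Q = {"sparse": 5, "dense": 50, "mixed": 20}


def estimation_scenario(name_or_q: Union[str, int], n: int = 100, p: int = 500,
                        rho: float = 0.1, noise_factor: float = 0.5) -> EstimationScenario:
    q = _ESTIMATION_Q.get(name_or_q, name_or_q) if isinstance(name_or_q, str) else name_or_q
    if isinstance(q, str):
        raise ValueError(f"unknown estimation scenario {name_or_q!r}")
    return EstimationScenario(n=n, p=p, q=int(q), rho=rho, noise_factor=noise_factor)


@dataclass
class BenchResult:
    """Per-replication metric rows plus recomputable summaries."""

    rows: pd.DataFrame
    summary: dict
    seed: int

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def simulate_prediction(scenario: PredictionScenario, seed: int):
    """Draw (X, y): y = z1 + z2 + z3; x_j = sqrt(pi) z_l + sqrt(1-pi) eps_j.

    The square-root mixing weights make every feature unit-variance:
    pi Var(z_l) + (1-pi) Var(eps_j) = 1."""
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((3, scenario.n))
    X = rng.standard_normal((scenario.n, scenario.p))
    y = z.sum(axis=0)
    for l in (1, 2):
        cols = np.flatnonzero(scenario.signal_index == l)
        if cols.size:
            pi = scenario.pi[cols]
            X[:, cols] = (np.sqrt(pi)[None, :] * z[l - 1][:, None]
                          + np.sqrt(1.0 - pi)[None, :] * X[:, cols])
    return X, y


def simulate_estimation(scenario: EstimationScenario, seed: int):
    """Draw (X, beta, y) with compound-symmetry features and unit effects.

    X = sqrt(rho) g + sqrt(1-rho) E with a shared standard normal g gives
    exactly Cov(x_j, x_k) = rho, Var(x_j) = 1. The residual sd is
    noise_factor times the sample sd of the linear predictor."""
    rng = np.random.default_rng(seed)
    n, p = scenario.n, scenario.p
    g = rng.standard_normal(n)
    X = np.sqrt(scenario.rho) * g[:, None] + np.sqrt(1.0 - scenario.rho) * \
        rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[: scenario.q] = 1.0
    lp = X @ beta
    sigma = scenario.noise_factor * np.std(lp, ddof=1)
    y = lp + rng.normal(scale=sigma, size=n)
    return X, beta, y


def _data_hash(*arrays: np.ndarray) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:12]


def _method_coefs(method: str, base, meta_model: Optional[StackedModel]):
    """(intercept, slopes) of a fitted comparator."""
    if method == "stack":
        return meta_model.pooled_intercept, meta_model.pooled_slopes
    if method == "tune":
        _, fit = select_tuned(base)
        return fit.intercept, fit.slopes
    fit = extract_base(base, METHOD_ALPHA[method])
    return fit.intercept, fit.slopes


def _fit_all(X, y, family, methods, m, K, seed, nlambda, tol):
    """One shared fit serving every requested method (paired design)."""
    fam = get_family(family)
    folds = make_folds(X.shape[0], K, y, fam, seed=seed)
    if "stack" in methods or "tune" in methods:
        grid = AlphaGrid.default(m)
    else:
        grid = AlphaGrid(np.array(sorted({METHOD_ALPHA[meth] for meth in methods})))
    base = fit_base_learners(X, y, fam, grid, folds, nlambda=nlambda, tol=tol)
    model = None
    if "stack" in methods:
        meta = fit_meta_learner(base.H_cv, y, fam, folds, nlambda=nlambda, tol=tol)
        model = pool_coefficients(base, meta, fam)
    return base, model, folds


def run_prediction_benchmark(
    scenario: PredictionScenario,
    reps: int = 100,
    n_train: int = 100,
    methods: Sequence[str] = ("ridge", "lasso", "ridge_like", "lasso_like",
                              "tune", "stack"),
    m: int = 21,
    K: int = 10,
    seed: int = 0,
    nlambda: int = 100,
    tol: float = 1e-7,
) -> BenchResult:
    """Out-of-sample MSE of each method over seeded replications.

    Each replication simulates fresh data, trains every method on the first
    n_train samples with shared 10-fold CV and scores the remainder. The
    summary reports per-method median MSE and the fraction of replications
    in which stacking attains strictly the lowest MSE among ridge, lasso,
    tuned and stacked."""
    methods = list(methods)
    records = []
    for rep in range(reps):
        rs = seed + rep
        X, y = simulate_prediction(scenario, rs)
        Xtr, ytr = X[:n_train], y[:n_train]
        Xte, yte = X[n_train:], y[n_train:]
        try:
            base, model, _ = _fit_all(Xtr, ytr, "gaussian", methods, m, K, rs,
                                      nlambda, tol)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"replication {rep} failed and is excluded: {exc}")
            continue
        dh = _data_hash(Xtr, ytr)
        for meth in methods:
            b0, b = _method_coefs(meth, base, model)
            mse = float(np.mean((yte - (b0 + Xte @ b)) ** 2))
            records.append({"rep": rep, "seed": rs, "method": meth,
                            "metric": "test_mse", "value": mse, "data_hash": dh})
    rows = pd.DataFrame.from_records(records)
    summary = {"median_mse": {}, "best_fraction": None, "wilcoxon_vs_stack": {}}
    if len(rows):
        wide = rows.pivot(index="rep", columns="method", values="value")
        summary["median_mse"] = wide.median().to_dict()
        contenders = [meth for meth in BEST_SET if meth in wide.columns]
        if "stack" in contenders and len(contenders) > 1:
            sub = wide[contenders]
            best = (sub.idxmin(axis=1) == "stack") & \
                (sub.drop(columns="stack").gt(sub["stack"], axis=0).all(axis=1))
            summary["best_fraction"] = float(best.mean())
        if "stack" in wide.columns:
            for meth in wide.columns:
                if meth != "stack" and len(wide) >= 5:
                    summary["wilcoxon_vs_stack"][meth] = wilcoxon_signed_rank(
                        wide[meth].to_numpy(), wide["stack"].to_numpy())
    return BenchResult(rows, summary, seed)


def _capped_support(X, y, alpha: float, cap: int, nlambda: int, tol: float):
    """Support of the largest-lambda path fit with at most `cap` nonzeros."""
    _, B, b0, _ = enet_path(X, y, "gaussian", alpha, nlambda=nlambda, tol=tol)
    nz = np.count_nonzero(B, axis=1)
    ok = np.flatnonzero(nz <= cap)
    best = int(ok[np.argmax(nz[ok])])
    return np.flatnonzero(B[best])


def run_estimation_benchmark(
    scenario: EstimationScenario,
    reps: int = 100,
    methods: Sequence[str] = ("tune", "stack"),
    m: int = 21,
    K: int = 10,
    seed: int = 0,
    nlambda: int = 100,
    cap: Optional[int] = None,
    tol: float = 1e-7,
) -> BenchResult:
    """Coefficient estimation accuracy (and optionally selection precision).

    Per replication and method, MAE and MSE of the estimated against the
    true coefficients are computed separately over the truly-zero and the
    truly-nonzero coordinates. The summary reports the median over
    replications of the per-replication percentage decrease from tune to
    stack (and, as an alternative reading, the decrease of the medians).
    With `cap` set, support recovery under the feature cap is scored for
    the stacked model with post-hoc selection, the lasso and the
    lasso-like elastic net."""
    methods = list(methods)
    records = []
    sel_records = []
    for rep in range(reps):
        rs = seed + rep
        X, beta_true, y = simulate_estimation(scenario, rs)
        nonzero = beta_true != 0
        try:
            base, model, folds = _fit_all(X, y, "gaussian", methods, m, K, rs,
                                          nlambda, tol)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"replication {rep} failed and is excluded: {exc}")
            continue
        dh = _data_hash(X, y)
        for meth in methods:
            _, b = _method_coefs(meth, base, model)
            err = b - beta_true
            for coords, label in ((nonzero, "nonzero"), (~nonzero, "zero")):
                records.append({"rep": rep, "seed": rs, "method": meth,
                                "metric": f"mae_{label}",
                                "value": float(np.mean(np.abs(err[coords]))),
                                "data_hash": dh})
                records.append({"rep": rep, "seed": rs, "method": meth,
                                "metric": f"mse_{label}",
                                "value": float(np.mean(err[coords] ** 2)),
                                "data_hash": dh})
        if cap is not None:
            supports = {
                "stack_dss": np.flatnonzero(
                    dss_select(X, model, "nzero", target=cap,
                               nlambda=nlambda).gamma),
                "lasso": _capped_support(X, y, 1.0, cap, nlambda, tol),
                "lasso_like": _capped_support(X, y, 0.95, cap, nlambda, tol),
            }
            for meth, sel in supports.items():
                tp = int(np.sum(nonzero[sel]))
                fp = int(sel.size - tp)
                precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
                if tp + fp == 0:
                    warnings.warn(f"replication {rep}: {meth} selected nothing; "
                                  "precision recorded as 0")
                sel_records.extend([
                    {"rep": rep, "seed": rs, "method": meth, "metric": met,
                     "value": float(val), "data_hash": dh}
                    for met, val in (("tp", tp), ("fp", fp),
                                     ("precision", precision))
                ])
    rows = pd.DataFrame.from_records(records + sel_records)
    summary = {"seed": seed, "reps": reps}
    est = pd.DataFrame.from_records(records)
    if len(est):
        med = est.groupby(["method", "metric"])["value"].median()
        summary["median"] = {f"{meth}.{met}": float(v)
                             for (meth, met), v in med.items()}
        if {"tune", "stack"} <= set(methods):
            for met in ("mae_nonzero", "mse_nonzero", "mae_zero", "mse_zero"):
                t = est.query("method=='tune' and metric==@met").set_index("rep")["value"]
                s = est.query("method=='stack' and metric==@met").set_index("rep")["value"]
                dec = 100.0 * (t - s) / t
                summary[f"median_decrease_{met}"] = float(dec.median())
                summary[f"decrease_of_medians_{met}"] = float(
                    100.0 * (t.median() - s.median()) / t.median())
                if len(t) >= 5:
                    summary[f"wilcoxon_{met}"] = wilcoxon_signed_rank(
                        t.to_numpy(), s.to_numpy())
    if sel_records:
        sel = pd.DataFrame.from_records(sel_records)
        means = sel.groupby(["method", "metric"])["value"].mean()
        summary["selection_mean"] = {f"{meth}.{met}": float(v)
                                     for (meth, met), v in means.items()}
    return BenchResult(rows, summary, seed)


def run_selection_benchmark(
    scenario: EstimationScenario,
    reps: int = 100,
    cap: int = 10,
    seed: int = 0,
    m: int = 21,
    K: int = 10,
    nlambda: int = 100,
) -> BenchResult:
    """Support recovery under a hard cap on the number of selected features."""
    if cap < 1:
        raise ValueError("cap must be at least 1")
    return run_estimation_benchmark(scenario, reps=reps, methods=("tune", "stack"),
                                    m=m, K=K, seed=seed, nlambda=nlambda, cap=cap)


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired losses.

    Zero differences are dropped; the exact distribution is used up to 25
    informative pairs, the tie-corrected normal approximation beyond. Any
    multiplicity (Bonferroni) adjustment is the caller's responsibility."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and the same length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, alternative="two-sided", method=method,
                             correction=False)
    except ValueError:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx",
                             correction=False)
    return float(res.pvalue)


def repeated_nested_cv(
    X,
    y,
    family: Union[str, Family] = "binomial",
    methods: Sequence[str] = ("ridge", "lasso", "tune", "stack"),
    repetitions: int = 10,
    outer: int = 10,
    inner: int = 10,
    seed: int = 0,
    m: int = 21,
    nlambda: int = 100,
    tol: float = 1e-7,
) -> BenchResult:
    """Repeated nested cross-validation of the comparators on one dataset.

    Outer folds estimate the generalization deviance; inner folds do all
    tuning. All methods share fold splits within a repetition, so the
    comparison is paired. The method name "intercept" scores the null
    model."""
    fam = get_family(family)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    methods = list(methods)
    fitted_methods = [meth for meth in methods if meth != "intercept"]
    records = []
    for rr in range(repetitions):
        rep_seed = seed + rr
        ofolds = make_folds(n, outer, y, fam, seed=rep_seed)
        eta = {meth: np.empty(n) for meth in methods}
        for f in range(1, outer + 1):
            tr = ofolds.train_mask(f)
            te = ofolds.test_mask(f)
            if fitted_methods:
                base, model, _ = _fit_all(X[tr], y[tr], fam, fitted_methods, m,
                                          inner, rep_seed, nlambda, tol)
                for meth in fitted_methods:
                    b0, b = _method_coefs(meth, base, model)
                    eta[meth][te] = b0 + X[te] @ b
            if "intercept" in methods:
                mu0 = np.clip(y[tr].mean(), 1e-10, None)
                if fam.name == "binomial":
                    mu0 = np.clip(mu0, 1e-10, 1 - 1e-10)
                eta["intercept"][te] = float(fam.link(np.asarray(mu0)))
        for meth in methods:
            records.append({"repetition": rr, "seed": rep_seed, "method": meth,
                            "metric": "cv_deviance",
                            "value": deviance(y, eta[meth], fam)})
    rows = pd.DataFrame.from_records(records)
    wide = rows.pivot(index="repetition", columns="method", values="value")
    summary = {"median_cv_deviance": wide.median().to_dict()}
    return BenchResult(rows, summary, seed)
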