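"""Tests for fold handling, base/meta learners, pooling and serialization."""

import numpy as np
import pytest
from scipy.optimize import minimize

from stackenet import glm_core as gc
from stackenet import stacking as st


def _gaussian_data(seed=0, n=60, p=12, strength=1.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:3] = strength * np.array([1.5, -1.0, 0.7])
    y = X @ beta + rng.normal(size=n) * 0.6
    return X, y


# ---------------------------------------------------------------------------
# folds


def test_folds_leave_one_out_limit():
    f = st.make_folds(10, 10, seed=1)
    assert sorted(f.fold_id) == list(range(1, 11))


def test_folds_deterministic_and_balanced():
    a = st.make_folds(100, 10, seed=5)
    b = st.make_folds(100, 10, seed=5)
    assert np.array_equal(a.fold_id, b.fold_id)
    sizes = np.bincount(a.fold_id)[1:]
    assert sizes.max() - sizes.min() <= 1


def test_folds_stratified_for_binomial():
    y = np.r_[np.ones(20), np.zeros(80)]
    f = st.make_folds(100, 10, y, "binomial", seed=2)
    for k in range(1, 11):
        assert y[f.test_mask(k)].sum() == 2.0


def test_folds_rare_class_warns():
    y = np.r_[np.ones(3), np.zeros(47)]
    with pytest.warns(UserWarning):
        f = st.make_folds(50, 10, y, "binomial", seed=0)
    assert np.unique(f.fold_id).size == 10


# ---------------------------------------------------------------------------
# base learners


def test_single_alpha_grid_equals_standalone_cv_lasso():
    """m=1 stacked base fit reproduces a hand-rolled CV lasso (glm_core only)."""
    X, y = _gaussian_data(3)
    folds = st.make_folds(60, 5, seed=9)
    base = st.fit_base_learners(X, y, "gaussian", st.AlphaGrid(np.array([1.0])),
                                folds, nlambda=40)
    # independent CV over the same path using only glm_core calls
    lmax = gc.lambda_max(X, y, "gaussian", 1.0)
    lams = gc.lambda_path(lmax, 40, gc.default_path_ratio(60, 12))
    H = np.empty((60, 40))
    for k in range(1, 6):
        tr, te = folds.train_mask(k), folds.test_mask(k)
        _, B, b0, _ = gc.enet_path(X[tr], y[tr], "gaussian", 1.0, lams=lams,
                                   tol=st.CV_TOL, scale_outcome=True)
        H[te] = b0[None, :] + X[te] @ B.T
    curve = np.mean((y[:, None] - H) ** 2, axis=0)
    istar = int(np.argmin(curve))
    assert base.lambda_star[0] == pytest.approx(lams[istar])
    assert base.cv_loss[0] == pytest.approx(curve[istar])
    _, Bf, b0f, _ = gc.enet_path(X, y, "gaussian", 1.0, lams=lams, tol=st.CV_TOL,
                                 scale_outcome=True)
    assert np.allclose(base.slopes[:, 0], Bf[istar], atol=1e-10)
    assert np.allclose(base.H_cv[:, 0], H[:, istar], atol=1e-10)


def test_h_cv_entry_has_no_leakage(small_stacked_model):
    """A stored out-of-fold linear predictor is reproduced by refitting
    without that sample's fold."""
    X, y, model = small_stacked_model
    base = model.base
    folds = base.folds
    i, k = 17, 2  # arbitrary sample and base learner
    alpha = base.alpha_grid.values[k]
    lmax = gc.lambda_max(X, y, "gaussian", alpha)
    lams = gc.lambda_path(lmax, 100, gc.default_path_ratio(*X.shape))
    tr = folds.train_mask(folds.fold_id[i])
    _, B, b0, _ = gc.enet_path(X[tr], y[tr], "gaussian", alpha, lams=lams,
                               tol=st.CV_TOL, scale_outcome=True)
    il = int(np.argmin(np.abs(lams - base.lambda_star[k])))
    eta_i = b0[il] + X[i] @ B[il]
    assert eta_i == pytest.approx(base.H_cv[i, k], abs=1e-8)


def test_null_signal_shrinks_to_path_start():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(50, 10))
    y = rng.normal(size=50)  # independent of X
    folds = st.make_folds(50, 5, seed=0)
    base = st.fit_base_learners(X, y, "gaussian", st.AlphaGrid(np.array([1.0])),
                                folds, nlambda=30)
    assert np.count_nonzero(base.slopes[:, 0]) <= 2
    # the held-out predictor column stays nearly constant relative to y
    assert np.ptp(base.H_cv[:, 0]) < np.std(y)


# ---------------------------------------------------------------------------
# meta learner


def test_meta_perfect_predictor_gets_unit_weight():
    rng = np.random.default_rng(4)
    H = rng.normal(size=(80, 3))
    y = H[:, 1].copy()
    folds = st.make_folds(80, 5, seed=1)
    meta = st.fit_meta_learner(H, y, "gaussian", folds)
    assert meta.omega[1] > 0.99
    assert np.all(meta.omega[[0, 2]] < 0.01)
    assert abs(meta.omega0) < 0.01


def test_meta_path_start_is_intercept_only():
    rng = np.random.default_rng(5)
    H = rng.normal(size=(60, 4))
    y = 0.5 * H[:, 0] + rng.normal(size=60)
    lmax = gc.lambda_max(H, y, "gaussian", 1.0, lower=np.zeros(4), upper=np.ones(4))
    _, B, b0, _ = gc.enet_path(H, y, "gaussian", 1.0, lams=[lmax * 1.0001],
                               lower=np.zeros(4), upper=np.ones(4))
    assert np.count_nonzero(B[0]) == 0
    assert b0[0] == pytest.approx(y.mean())


def test_meta_weights_feasible_on_entire_path():
    rng = np.random.default_rng(6)
    H = rng.normal(size=(70, 5)) + rng.normal(size=(70, 1))
    y = H @ np.array([0.5, 0.4, 0.0, 0.3, 0.2]) + rng.normal(size=70)
    lmax = gc.lambda_max(H, y, "gaussian", 1.0, lower=np.zeros(5), upper=np.ones(5))
    lams = gc.lambda_path(lmax, 60, 1e-4)
    _, B, _, _ = gc.enet_path(H, y, "gaussian", 1.0, lams=lams,
                              lower=np.zeros(5), upper=np.ones(5))
    assert np.all(B >= 0.0)
    assert np.all(B <= 1.0)


def test_meta_matches_box_constrained_qp():
    """Fixed-lambda meta fit equals an independent box-QP solution.

    With weights constrained to [0, 1] the lasso term is linear, so the
    objective is smooth over the feasible box and L-BFGS-B solves the same
    problem exactly."""
    rng = np.random.default_rng(8)
    n, m = 50, 3
    H = rng.normal(size=(n, m))
    y = H @ np.array([0.8, 0.3, 0.0]) + 0.3 * rng.normal(size=n)
    lam = 0.05
    _, B, b0, _ = gc.enet_path(H, y, "gaussian", 1.0, lams=[lam],
                               lower=np.zeros(m), upper=np.ones(m),
                               standardize=False, tol=1e-16)

    def obj(th):
        w0, w = th[0], th[1:]
        return 0.5 * np.mean((y - w0 - H @ w) ** 2) + lam * np.sum(w)

    res = minimize(obj, np.zeros(m + 1), method="L-BFGS-B",
                   bounds=[(None, None)] + [(0.0, 1.0)] * m,
                   options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 20000})
    assert b0[0] == pytest.approx(res.x[0], abs=1e-5)
    assert np.allclose(B[0], res.x[1:], atol=1e-5)


def test_meta_constant_column_gets_zero_weight():
    rng = np.random.default_rng(9)
    H = rng.normal(size=(40, 3))
    H[:, 2] = 1.7
    y = H[:, 0] + 0.2 * rng.normal(size=40)
    meta = st.fit_meta_learner(H, y, "gaussian", st.make_folds(40, 5, seed=0))
    assert meta.omega[2] == 0.0


# ---------------------------------------------------------------------------
# pooling, prediction, tuning


def test_pooling_identity_exact(small_stacked_model):
    X, _, model = small_stacked_model
    rng = np.random.default_rng(0)
    Xnew = rng.normal(size=(25, X.shape[1]))
    lhs = st.predict(model, Xnew, scale="link")
    etas = model.base.intercepts[None, :] + Xnew @ model.base.slopes
    rhs = model.meta.omega0 + etas @ model.meta.omega
    assert np.allclose(lhs, rhs, rtol=1e-12, atol=1e-12)


def test_one_hot_meta_reproduces_single_alpha(small_stacked_model):
    X, _, model = small_stacked_model
    base = model.base
    for k in range(base.alpha_grid.m):
        omega = np.zeros(base.alpha_grid.m)
        omega[k] = 1.0
        pooled = st.pool_coefficients(base, st.MetaFit(0.0, omega, 0.0))
        single = st.extract_base(base, base.alpha_grid.values[k])
        assert pooled.pooled_intercept == single.intercept
        assert np.array_equal(pooled.pooled_slopes, base.slopes[:, k])


def test_zero_weights_give_intercept_only(small_stacked_model):
    _, _, model = small_stacked_model
    base = model.base
    pooled = st.pool_coefficients(base, st.MetaFit(1.3, np.zeros(base.alpha_grid.m), 0.0))
    assert pooled.pooled_intercept == 1.3
    assert np.count_nonzero(pooled.pooled_slopes) == 0


def test_predict_scales_and_errors(small_stacked_model):
    X, _, model = small_stacked_model
    p = X.shape[1]
    Z = np.zeros((4, p))
    assert np.allclose(st.predict(model, Z, "response"),
                       model.pooled_intercept)
    with pytest.raises(ValueError):
        st.predict(model, np.zeros((4, p + 2)))
    with pytest.raises(ValueError):
        st.predict(model, Z, scale="probability")
    # logit^-1(0) = 0.5 for a null binomial fit
    fit = gc.GlmFit(0.0, np.zeros(p), 0.0)
    assert np.allclose(st.predict(fit, Z, "response", family="binomial"), 0.5)


def test_select_tuned_argmin_and_tiebreak(small_stacked_model):
    _, _, model = small_stacked_model
    base = model.base
    k, fit = st.select_tuned(base)
    assert k == int(np.argmin(base.cv_loss))
    assert fit.alpha == base.alpha_grid.values[k]
    # forced tie breaks toward the smaller alpha
    tied = st.BaseEnsembleFit(base.alpha_grid, base.lambda_star, base.intercepts,
                              base.slopes, base.H_cv,
                              np.ones(base.alpha_grid.m), base.folds, base.family)
    assert st.select_tuned(tied)[0] == 0


def test_fit_is_deterministic():
    X, y = _gaussian_data(21, n=50, p=8)
    a = st.fit_stacked_elastic_net(X, y, m=4, K=5, seed=3)
    b = st.fit_stacked_elastic_net(X, y, m=4, K=5, seed=3)
    assert a.pooled_intercept == b.pooled_intercept
    assert np.array_equal(a.pooled_slopes, b.pooled_slopes)
    assert np.array_equal(a.meta.omega, b.meta.omega)
    assert np.array_equal(a.base.H_cv, b.base.H_cv)


def test_strong_signal_beats_intercept_out_of_sample():
    rng = np.random.default_rng(33)
    X = rng.normal(size=(120, 10))
    beta = np.array([2.0, -1.5, 1.0, 0, 0, 0, 0, 0, 0, 0])
    y = X @ beta + 0.5 * rng.normal(size=120)
    model = st.fit_stacked_elastic_net(X[:60], y[:60], m=5, K=5, seed=1)
    mse = np.mean((y[60:] - st.predict(model, X[60:])) ** 2)
    assert mse <= np.mean((y[60:] - y[:60].mean()) ** 2)


def test_serialization_roundtrip(tmp_path, small_stacked_model):
    _, _, model = small_stacked_model
    path = tmp_path / "model.json"
    st.save_model(model, path)
    loaded = st.load_model(path)
    assert loaded.family.name == model.family.name
    assert loaded.pooled_intercept == model.pooled_intercept
    assert np.array_equal(loaded.pooled_slopes, model.pooled_slopes)
    assert np.array_equal(loaded.base.slopes, model.base.slopes)
    assert np.array_equal(loaded.meta.omega, model.meta.omega)
    assert loaded.base.folds.seed == model.base.folds.seed
    rng = np.random.default_rng(1)
    Xn = rng.normal(size=(5, model.pooled_slopes.size))
    assert np.array_equal(st.predict(loaded, Xn), st.predict(model, Xn))
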