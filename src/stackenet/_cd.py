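"""Numba coordinate-descent kernels for the penalized weighted least squares core.

All kernels operate on a (possibly standardized) feature matrix and solve

    min_{b0, b}  (1/(2n)) sum_i w_i (y_i - b0 - x_i.b)^2
                 + lam * sum_j pf_j ( (1-alpha)/2 b_j^2 + alpha |b_j| )
    subject to   lo_j <= b_j <= up_j

with an unpenalized, unconstrained intercept. pf_j = +inf excludes coordinate j.
The GLM families reach this core through iteratively reweighted least squares
(see glm_core). The gaussian path kernel uses sequential strong rules with a
full optimality check, glmnet-style. Feature matrices should be passed in
Fortran (column-major) order so column scans are contiguous.
"""

import numpy as np
from numba import njit

# convergence metric is max_j d_j * (delta b_j)^2, glmnet-style


@njit(cache=True, fastmath=True)
def _sweep_w(X, r, w, d, beta, pf, lo, up, la, lr, idx):
    """One weighted coordinate sweep over idx; updates beta and r in place.

    Returns the max weighted squared coefficient change."""
    n = X.shape[0]
    dmax = 0.0
    for t in range(idx.shape[0]):
        j = idx[t]
        pfj = pf[j]
        if not np.isfinite(pfj):
            continue
        dj = d[j]
        if dj <= 0.0:
            continue
        bj = beta[j]
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * r[i]
        z = s / n + dj * bj
        thr = la * pfj
        if z > thr:
            bnew = (z - thr) / (dj + lr * pfj)
        elif z < -thr:
            bnew = (z + thr) / (dj + lr * pfj)
        else:
            bnew = 0.0
        if bnew < lo[j]:
            bnew = lo[j]
        elif bnew > up[j]:
            bnew = up[j]
        diff = bnew - bj
        if diff != 0.0:
            for i in range(n):
                r[i] -= diff * X[i, j]
            beta[j] = bnew
            chg = dj * diff * diff
            if chg > dmax:
                dmax = chg
    return dmax


@njit(cache=True, fastmath=True)
def _sweep_unw(X, r, d, beta, pf, lo, up, la, lr, idx):
    """Unweighted coordinate sweep (gaussian fast path)."""
    n = X.shape[0]
    dmax = 0.0
    for t in range(idx.shape[0]):
        j = idx[t]
        pfj = pf[j]
        if not np.isfinite(pfj):
            continue
        dj = d[j]
        if dj <= 0.0:
            continue
        bj = beta[j]
        s = 0.0
        for i in range(n):
            s += X[i, j] * r[i]
        z = s / n + dj * bj
        thr = la * pfj
        if z > thr:
            bnew = (z - thr) / (dj + lr * pfj)
        elif z < -thr:
            bnew = (z + thr) / (dj + lr * pfj)
        else:
            bnew = 0.0
        if bnew < lo[j]:
            bnew = lo[j]
        elif bnew > up[j]:
            bnew = up[j]
        diff = bnew - bj
        if diff != 0.0:
            for i in range(n):
                r[i] -= diff * X[i, j]
            beta[j] = bnew
            chg = dj * diff * diff
            if chg > dmax:
                dmax = chg
    return dmax


@njit(cache=True, fastmath=True)
def _intercept_step_w(r, w, wsum):
    s = 0.0
    for i in range(r.shape[0]):
        s += w[i] * r[i]
    delta = s / wsum
    for i in range(r.shape[0]):
        r[i] -= delta
    return delta


@njit(cache=True, fastmath=True)
def _intercept_step(r):
    s = 0.0
    n = r.shape[0]
    for i in range(n):
        s += r[i]
    delta = s / n
    for i in range(n):
        r[i] -= delta
    return delta


@njit(cache=True, fastmath=True)
def cd_solve(X, r, w, d, beta, b0, pf, lo, up, lam, alpha, tol, maxit):
    """Solve the box-constrained elastic net at a single lam (weighted data).

    r must hold z - b0 - X beta on entry and does on exit. Returns
    (b0, n_sweeps, converged)."""
    n, p = X.shape
    wsum = 0.0
    for i in range(n):
        wsum += w[i]
    la = lam * alpha
    lr = lam * (1.0 - alpha)
    allidx = np.arange(p)
    it = 0
    converged = False
    while it < maxit:
        delta0 = _intercept_step_w(r, w, wsum)
        b0 += delta0
        dmax = (wsum / n) * delta0 * delta0
        dfull = _sweep_w(X, r, w, d, beta, pf, lo, up, la, lr, allidx)
        if dfull > dmax:
            dmax = dfull
        it += 1
        if dmax < tol:
            converged = True
            break
        active = np.flatnonzero(beta)
        while it < maxit:
            delta0 = _intercept_step_w(r, w, wsum)
            b0 += delta0
            dmax = (wsum / n) * delta0 * delta0
            dact = _sweep_w(X, r, w, d, beta, pf, lo, up, la, lr, active)
            if dact > dmax:
                dmax = dact
            it += 1
            if dmax < tol:
                break
    return b0, it, converged


@njit(cache=True, fastmath=True)
def enet_path_gaussian(X, y, d, pf, lo, up, alpha, lams, tol, maxit, b0_init, beta_init):
    """Gaussian lambda path with warm starts and sequential strong rules.

    Each lambda is solved on the strong set (plus everything already active),
    then every excluded coordinate is checked for optimality; violators are
    added and the solve repeats. Returns (B [nlam x p], b0 [nlam], conv)."""
    n, p = X.shape
    nlam = lams.shape[0]
    beta = beta_init.copy()
    b0 = b0_init
    r = y - b0 - X @ beta
    g = (r @ X) / n
    B = np.empty((nlam, p))
    b0s = np.empty(nlam)
    conv = np.zeros(nlam, dtype=np.bool_)
    member = np.zeros(p, dtype=np.bool_)
    for il in range(nlam):
        lam = lams[il]
        lam_prev = lams[il - 1] if il > 0 else lam
        la = lam * alpha
        lr = lam * (1.0 - alpha)
        strong = alpha * (2.0 * lam - lam_prev)
        for j in range(p):
            member[j] = np.isfinite(pf[j]) and (
                beta[j] != 0.0 or abs(g[j]) >= strong * pf[j]
            )
        idx = np.flatnonzero(member)
        dmax = np.inf
        it = 0
        while True:
            while it < maxit:
                delta0 = _intercept_step(r)
                b0 += delta0
                dmax = delta0 * delta0
                dsw = _sweep_unw(X, r, d, beta, pf, lo, up, la, lr, idx)
                if dsw > dmax:
                    dmax = dsw
                it += 1
                if dmax < tol:
                    break
                active = np.flatnonzero(beta)
                while it < maxit:
                    delta0 = _intercept_step(r)
                    b0 += delta0
                    dmax = delta0 * delta0
                    dact = _sweep_unw(X, r, d, beta, pf, lo, up, la, lr, active)
                    if dact > dmax:
                        dmax = dact
                    it += 1
                    if dmax < tol:
                        break
            # optimality check on the excluded coordinates
            g = (r @ X) / n
            nviol = 0
            for j in range(p):
                if member[j] or not np.isfinite(pf[j]) or d[j] <= 0.0:
                    continue
                z = g[j]
                thr = la * pf[j]
                if z > thr:
                    bnew = (z - thr) / (d[j] + lr * pf[j])
                elif z < -thr:
                    bnew = (z + thr) / (d[j] + lr * pf[j])
                else:
                    bnew = 0.0
                if bnew < lo[j]:
                    bnew = lo[j]
                elif bnew > up[j]:
                    bnew = up[j]
                if bnew != 0.0:
                    member[j] = True
                    nviol += 1
            if nviol == 0 or it >= maxit:
                break
            idx = np.flatnonzero(member)
        B[il] = beta
        b0s[il] = b0
        conv[il] = dmax < tol
    return B, b0s, conv
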