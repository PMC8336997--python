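"""Independent reference implementations used as test oracles.

These share no solver code with the package: the elastic net reference is
plain (accelerated) proximal gradient descent, vectorized numpy only.
"""

import numpy as np


def fista_elastic_net(X, y, lam, alpha, n_iter=60_000, rtol=1e-13):
    """Accelerated proximal gradient on the standardized elastic-net objective.

    Mirrors the package's standardization convention (column mean 0, sd with
    denominator n; unpenalized intercept) and back-transforms identically,
    but is otherwise an independent solver. Returns (intercept, slopes) on
    the original feature scale."""
    n, p = X.shape
    m = X.mean(axis=0)
    s = np.sqrt(np.mean((X - m) ** 2, axis=0))
    s = np.where(s <= 1e-12, 1.0, s)
    Xs = (X - m) / s
    yc = y - y.mean()
    L = np.linalg.eigvalsh(Xs.T @ Xs / n).max() + lam * (1 - alpha)
    b = np.zeros(p)
    zv = b.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = -Xs.T @ (yc - Xs @ zv) / n + lam * (1 - alpha) * zv
        w = zv - grad / L
        thr = lam * alpha / L
        b_new = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        zv = b_new + (t - 1) / t_new * (b_new - b)
        if np.max(np.abs(b_new - b)) < rtol * (1 + np.max(np.abs(b_new))):
            b = b_new
            break
        b, t = b_new, t_new
    slopes = b / s
    return float(y.mean() - m @ slopes), slopes
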