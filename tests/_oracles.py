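"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's fitting code paths: the logistic
oracle maximizes the exact binomial log-likelihood over a dense slope grid,
profiling the intercept with a damped 1-D Newton iteration (the profile
log-likelihood in the intercept is strictly concave, so the iteration is
globally convergent).
"""

import numpy as np


def aggregate(d, y):
    levels = np.unique(d)
    n = np.array([np.sum(d == lv) for lv in levels], dtype=float)
    k = np.array([np.sum(y[d == lv]) for lv in levels], dtype=float)
    return levels, n, k


def profile_grid_logistic(d, y, b1_grid=None):
    """Grid-search ML logistic fit: slope grid with profiled intercept.

    Returns ``(beta0, beta1, pse)`` at the grid maximum. Slope resolution
    0.005 over [-3, 3]; the intercept is profiled to machine precision.
    """
    if b1_grid is None:
        b1_grid = np.arange(-3.0, 3.0 + 1e-12, 0.005)
    levels, n, k = aggregate(np.asarray(d, float), np.asarray(y, int))

    b1 = np.asarray(b1_grid)
    b0 = np.zeros_like(b1)
    # damped Newton on dl/db0 = sum(k - n*p), concave in b0
    for _ in range(100):
        eta = b0[:, None] + b1[:, None] * levels[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = (k[None, :] - n[None, :] * p).sum(axis=1)
        hess = -(n[None, :] * p * (1 - p)).sum(axis=1)
        step = np.clip(grad / -hess, -2.0, 2.0)
        b0 = b0 + step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = b0[:, None] + b1[:, None] * levels[None, :]
    # stable binomial log-likelihood
    ll = (k[None, :] * eta - n[None, :] * np.logaddexp(0.0, eta)).sum(axis=1)
    i = int(np.argmax(ll))
    beta0, beta1 = float(b0[i]), float(b1[i])
    pse = -beta0 / beta1 if beta1 != 0 else np.nan
    return beta0, beta1, pse


def type7_quartiles(values):
    """Brute-force type-7 quartiles: linear interpolation of order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    out = []
    for q in (0.25, 0.75):
        h = (len(x) - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, len(x) - 1)
        out.append(x[lo] + (h - lo) * (x[hi] - x[lo]))
    return tuple(out)
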