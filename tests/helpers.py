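"""Independent oracles and small utilities shared across tests.

The brute-force likelihood maximizer here deliberately avoids the package's
Newton-Raphson path: it evaluates the cumulative-logit / Bernoulli
log-likelihood directly and maximizes it with a coarse grid start plus
derivative-free Nelder-Mead polish.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit


def po_negloglik(theta, X, y01, K):
    """Negative PO log-likelihood; theta = (alpha_1..alpha_{K-1}, beta)."""
    q = K - 1
    alpha, beta = theta[:q], theta[q:]
    if np.any(np.diff(alpha) <= 0):
        return np.inf
    eta = X @ beta
    F = expit(alpha[None, :] + eta[:, None])
    cum = np.column_stack([np.zeros(len(y01)), F, np.ones(len(y01))])
    pi = cum[np.arange(len(y01)), y01 + 1] - cum[np.arange(len(y01)), y01]
    if np.any(pi <= 0):
        return np.inf
    return -float(np.log(pi).sum())


def brute_force_po(X, y, n_grid=21, grid_half_width=3.0):
    """Grid + Nelder-Mead maximization of the proportional-odds likelihood.

    Returns (alpha_hat, beta_hat, loglik).  Intended for tiny instances
    (p <= 4); independent of the package's Newton solver.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    classes, y01 = np.unique(y, return_inverse=True)
    K = len(classes)
    q = K - 1
    p = X.shape[1]
    counts = np.bincount(y01, minlength=K)
    alpha0 = logit(np.clip(np.cumsum(counts)[:-1] / len(y01), 1e-9, 1 - 1e-9))

    # coarse grid over each beta coordinate (others at 0), pick the best start
    best = (np.inf, np.concatenate([alpha0, np.zeros(p)]))
    for j in range(p):
        for b in np.linspace(-grid_half_width, grid_half_width, n_grid):
            beta = np.zeros(p)
            beta[j] = b
            th = np.concatenate([alpha0, beta])
            v = po_negloglik(th, X, y01, K)
            if v < best[0]:
                best = (v, th)

    th = best[1]
    for _ in range(3):  # repeated Nelder-Mead restarts to polish tightly
        res = minimize(
            po_negloglik, th, args=(X, y01, K), method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 40000, "maxfev": 40000},
        )
        th = res.x
    return th[:q], th[q:], -po_negloglik(th, X, y01, K)


def grouped_to_rows(x_levels, counts):
    """Expand a (levels x categories) count table into per-row (X, y)."""
    xs, ys = [], []
    for xi, row in zip(x_levels, counts):
        for k, c in enumerate(row):
            xs.extend([xi] * c)
            ys.extend([k + 1] * c)
    return np.asarray(xs, dtype=float)[:, None], np.asarray(ys)


def numeric_hessian(f, theta, eps=1e-5):
    """Central finite-difference Hessian of a scalar function."""
    theta = np.asarray(theta, dtype=float)
    m = len(theta)
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m)
            ej = np.zeros(m)
            ei[i] = eps
            ej[j] = eps
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * eps * eps)
    return H
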