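"""Block-coordinate-descent kernel for the graphical lasso.

Friedman-style solver: the working covariance W is updated one column at a
time by solving the lasso subproblem

    min_beta  1/2 beta' W11 beta - s' beta + rho ||beta||_1,

with ``s`` the corresponding column of the input covariance, then
``w12 = W11 beta``.  With the penalty restricted to off-diagonal precision
entries the diagonal of W stays fixed at the input diagonal; with a penalized
diagonal it is fixed at ``diag(M) + rho``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _lasso_cd(v, s, beta, rho, tol, max_sweep):
    p = s.shape[0]
    for _ in range(max_sweep):
        dmax = 0.0
        for q in range(p):
            g = s[q]
            for k in range(p):
                if k != q:
                    g -= v[q, k] * beta[k]
            if g > rho:
                b = (g - rho) / v[q, q]
            elif g < -rho:
                b = (g + rho) / v[q, q]
            else:
                b = 0.0
            d = abs(b - beta[q])
            if d > dmax:
                dmax = d
            beta[q] = b
        if dmax < tol:
            break


@njit(cache=True)
def glasso_sweeps(m, rho, w, b, tol, inner_tol, max_iter, max_sweep):
    """Run up to ``max_iter`` outer sweeps in place; return (iters, converged).

    ``w`` is the working covariance (diagonal already set by the caller) and
    ``b`` holds the per-column lasso coefficients for warm starts.
    """
    j_dim = m.shape[0]
    v = np.empty((j_dim - 1, j_dim - 1))
    s = np.empty(j_dim - 1)
    beta = np.empty(j_dim - 1)
    iters = 0
    converged = False
    for iters in range(1, max_iter + 1):
        dmax = 0.0
        for j in range(j_dim):
            a = 0
            for r in range(j_dim):
                if r == j:
                    continue
                c = 0
                for col in range(j_dim):
                    if col == j:
                        continue
                    v[a, c] = w[r, col]
                    c += 1
                s[a] = m[r, j]
                beta[a] = b[r, j]
                a += 1
            _lasso_cd(v, s, beta, rho, inner_tol, max_sweep)
            a = 0
            for r in range(j_dim):
                if r == j:
                    continue
                new = 0.0
                for c in range(j_dim - 1):
                    new += v[a, c] * beta[c]
                d = abs(new - w[r, j])
                if d > dmax:
                    dmax = d
                w[r, j] = new
                w[j, r] = new
                b[r, j] = beta[a]
                a += 1
        if dmax < tol:
            converged = True
            break
    return iters, converged


def recover_precision(w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Precision matrix from the working covariance and lasso coefficients."""
    j_dim = w.shape[0]
    theta = np.zeros_like(w)
    for j in range(j_dim):
        others = np.arange(j_dim) != j
        beta = b[others, j]
        denom = w[j, j] - w[others, j] @ beta
        theta[j, j] = 1.0 / denom
        theta[others, j] = -beta * theta[j, j]
    return 0.5 * (theta + theta.T)
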