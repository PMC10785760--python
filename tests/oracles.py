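"""Independent brute-force oracles the implementation is checked against."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def bh_stepup(p: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Literal Benjamini–Hochberg: q_i = min_{j: p_j >= p_i} m*p_(j)/j,
    reject the first k ordered p-values with p_(k) <= k*alpha/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    k = 0
    for rank in range(m):
        if p[order[rank]] <= (rank + 1) * alpha / m:
            k = rank + 1
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return q, reject


def hypergeom_tail(overlap: int, pathway_size: int, n_draw: int, n_pop: int) -> float:
    """P(X >= overlap) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(overlap, min(pathway_size, n_draw) + 1):
        total += (
            math.comb(pathway_size, x)
            * math.comb(n_pop - pathway_size, n_draw - x)
            / math.comb(n_pop, n_draw)
        )
    return min(total, 1.0)


def permutation_spearman_p(x: np.ndarray, y: np.ndarray, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for Spearman rho with a pseudo-count."""
    rng = np.random.default_rng(seed)
    obs = stats.spearmanr(x, y).statistic
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        if abs(stats.spearmanr(x, perm).statistic) >= abs(obs) - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Beta and SEs from the explicit normal equations."""
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    return beta, se


def pc1_eigendecomposition(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """PC1 via explicit covariance eigendecomposition (sign: largest |loading| > 0)."""
    cov = z.T @ z / (z.shape[0] - 1)
    w, v = np.linalg.eigh(cov)
    load = v[:, -1]
    if load[np.argmax(np.abs(load))] < 0:
        load = -load
    return z @ load, load, float(w[-1] / w.sum())
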