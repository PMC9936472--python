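"""Independent reference implementations used to cross-check the package.

These are deliberately written from first principles (explicit IRLS,
enumeration, brute force) and share no code with the implementation under
test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def irls_binomial_logit(X: np.ndarray, succ: np.ndarray, fail: np.ndarray,
                        tol: float = 1e-12, max_iter: int = 200):
    """Binomial GLM (logit link) fitted by hand-rolled IRLS.

    Returns (beta_vector, unscaled_se_vector, pearson_dispersion, df_resid).
    """
    n = succ + fail
    y = succ / n
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = n * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    w = n * mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    resid = (succ - n * mu) / np.sqrt(n * mu * (1 - mu))
    df_resid = X.shape[0] - X.shape[1]
    dispersion = float(resid @ resid / df_resid) if df_resid > 0 else 1.0
    return beta, se, dispersion, df_resid


def transition_design(n_reps: int):
    """Design matrix intercept + replicate dummies (drop first) + timepoint
    dummy, rows ordered (rep1 tp_a, rep1 tp_b, rep2 tp_a, ...)."""
    rows = []
    for rep in range(n_reps):
        for tp in (0, 1):
            row = [1.0]
            row += [1.0 if rep == r else 0.0 for r in range(1, n_reps)]
            row.append(float(tp))
            rows.append(row)
    return np.asarray(rows)


def sign_changes_bruteforce(signs) -> int:
    """Count sign changes in a sequence, skipping zeros, by direct scan."""
    filtered = [s for s in signs if s != 0]
    count = 0
    for i in range(1, len(filtered)):
        if filtered[i] != filtered[i - 1]:
            count += 1
    return count


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct enumeration."""
    total = math.comb(N, n)
    p = 0.0
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            p += math.comb(K, i) * math.comb(N - K, n - i) / total
    return p


def ranksum_exact_bruteforce(x, y) -> tuple[float, float]:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for idx in order[i:j + 1]:
            ranks[idx] = avg
        i = j + 1
    mu = n1 * len(y) / 2.0
    u_obs = sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    total = extreme = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def bh_stepup_reference(pvals):
    """Benjamini-Hochberg step-up adjusted p-values, straightforward loop."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(pvals[i] * m / rank_from_top, prev)
        adj[i] = val
        prev = val
    return adj
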