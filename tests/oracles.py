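"""Independent brute-force oracles used only by the test suite.

Each oracle is written directly from the mathematical definition it checks
(explicit dense covariance matrices, exhaustive enumeration, direct series
summation) and deliberately does not share code with the package internals.
"""

from __future__ import annotations

import math
import numpy as np

_LOG2PI = np.log(2.0 * np.pi)


def dense_longitudinal_V(mouse_idx, day, K, components):
    """Observation covariance assembled entry by entry from the model definition."""
    s1, s2, s3, s4, s5, s6, resid = components
    N = len(mouse_idx)
    V = np.zeros((N, N))
    for a in range(N):
        for b in range(N):
            i, j = mouse_idx[a], mouse_idx[b]
            g = K[i, j]
            ident = 1.0 if i == j else 0.0
            v = (
                (s1 * g + s2 * ident)
                + day[a] * day[b] * (s3 * g + s4 * ident)
                + (day[a] + day[b]) * (s5 * g + s6 * ident)
            )
            if a == b:
                v += resid
            V[a, b] = v
    return V


def dense_reml_loglik(y, X, mouse_idx, day, K, components):
    """Restricted log-likelihood from the dense covariance."""
    V = dense_longitudinal_V(mouse_idx, day, K, components)
    N, p = X.shape
    sign, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XVX = X.T @ Vi @ X
    XVy = X.T @ Vi @ y
    beta = np.linalg.solve(XVX, XVy)
    quad = y @ Vi @ y - XVy @ beta
    _, logdetXVX = np.linalg.slogdet(XVX)
    return -0.5 * (logdetV + logdetXVX + quad + (N - p) * _LOG2PI)


def dense_gls_snp_test(y, X, g_obs, mouse_idx, day, K, components):
    """Wald Z for one SNP by explicit GLS with the dense covariance.

    Observations with missing genotype (NaN in g_obs) are excluded.
    Returns (gamma_hat, se, z).
    """
    keep = ~np.isnan(g_obs)
    V = dense_longitudinal_V(mouse_idx, day, K, components)[np.ix_(keep, keep)]
    Xs = np.column_stack([X[keep], g_obs[keep]])
    Vi = np.linalg.inv(V)
    A = Xs.T @ Vi @ Xs
    cov = np.linalg.pinv(A)
    beta = cov @ (Xs.T @ Vi @ y[keep])
    se = math.sqrt(cov[-1, -1])
    return beta[-1], se, beta[-1] / se


def fisher_exact_enumeration(a, b, c, d):
    """Two-sided Fisher exact p by full enumeration of tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_hyper(x):
        # P(X = x) for X ~ Hypergeometric(n, r1, c1)
        return (
            math.lgamma(r1 + 1) - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
            + math.lgamma(r2 + 1) - math.lgamma(c1 - x + 1) - math.lgamma(r2 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: math.exp(log_hyper(x)) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def poisson_tail_sum(k, lam, terms=10_000):
    """P(X >= k) by direct mass summation (complement of the lower sum)."""
    if k <= 0:
        return 1.0
    log_lam = math.log(lam) if lam > 0 else -math.inf
    total = 0.0
    for x in range(0, k):
        total += math.exp(-lam + x * log_lam - math.lgamma(x + 1)) if lam > 0 else (1.0 if x == 0 else 0.0)
    return 1.0 - total


def pip_enumeration(R, z, prior_var, prior):
    """Gene posterior inclusion by an independently-coded subset sum.

    Iterates subsets in bitmask order (different from the package's
    size-ordered itertools enumeration) and accumulates per-gene posterior
    mass with a log-sum-exp reduction.
    """
    G = len(z)
    R = np.asarray(R, float)
    z = np.asarray(z, float)
    logs = np.full((G, 2 ** G), -np.inf)  # per-gene member mass
    all_logs = np.empty(2 ** G)
    for mask in range(2 ** G):
        members = [g for g in range(G) if mask >> g & 1]
        cov = R + 1e-8 * np.eye(G)
        for g in members:
            cov = cov + prior_var * np.outer(R[:, g], R[:, g])
        sign, ld = np.linalg.slogdet(cov)
        ll = -0.5 * (ld + z @ np.linalg.solve(cov, z))
        lp = len(members) * math.log(prior) + (G - len(members)) * math.log(1 - prior)
        all_logs[mask] = ll + lp
        for g in members:
            logs[g, mask] = ll + lp
    denom = _logsumexp(all_logs)
    return np.array([math.exp(_logsumexp(logs[g]) - denom) for g in range(G)])


def _logsumexp(v):
    m = np.max(v)
    if m == -np.inf:
        return -np.inf
    return m + math.log(np.sum(np.exp(v - m)))


def blom_direct(values):
    """Blom scores computed directly from sorted positions (no rankdata)."""
    from scipy.stats import norm

    values = np.asarray(values, float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # mean rank for ties
    for v in np.unique(values):
        sel = values == v
        ranks[sel] = ranks[sel].mean()
    return norm.ppf((ranks - 0.375) / (n + 0.25))
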