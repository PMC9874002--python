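"""Independent brute-force oracles used to check the package's numerics.

Everything here is written as plainly as possible (explicit loops, direct
formulas), deliberately avoiding the vectorized code paths in the package.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess


def bh_naive(p):
    """Benjamini-Hochberg step-up by direct min-over-k evaluation."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for pos, i in enumerate(order, start=1):
        candidates = []
        for k in range(pos, m + 1):
            pk = p[order[k - 1]]
            candidates.append(min(pk * m / k, 1.0))
        q[i] = min(candidates)
    return np.array(q)


def pearson_naive(x, y):
    """Product-moment r, two-sided p, and Fisher-z 95% CI by direct formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    mx, my = x.mean(), y.mean()
    r = sum((a - mx) * (b - my) for a, b in zip(x, y)) / np.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    if abs(r) >= 1:
        return r, 0.0, (r, r)
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    p = 2 * stats.t.sf(abs(t), n - 2)
    z = 0.5 * np.log((1 + r) / (1 - r))
    h = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (np.tanh(z - h), np.tanh(z + h))
    return r, p, ci


def tmm_naive(counts, lib, ref, j, trim_M=0.30, trim_A=0.05):
    """log2 TMM factor of sample j vs reference, by explicit double trimming."""
    M, A, w = [], [], []
    for g in range(counts.shape[0]):
        o, r = counts[g, j], counts[g, ref]
        if o > 0 and r > 0:
            po, pr = o / lib[j], r / lib[ref]
            M.append(np.log2(po / pr))
            A.append(0.5 * (np.log2(po) + np.log2(pr)))
            w.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
    M, A, w = np.array(M), np.array(A), np.array(w)
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 0.0
    n = M.size

    def ranks(v):
        # average rank: (#smaller) + (#equal + 1)/2
        out = np.empty(n)
        for idx in range(n):
            less = sum(1 for u in v if u < v[idx])
            equal = sum(1 for u in v if u == v[idx])
            out[idx] = less + (equal + 1) / 2.0
        return out

    rM, rA = ranks(M), ranks(A)
    loL = np.floor(n * trim_M) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * trim_A) + 1
    hiS = n + 1 - loS
    num = den = 0.0
    for g in range(n):
        if loL <= rM[g] <= hiL and loS <= rA[g] <= hiS:
            num += M[g] / w[g]
            den += 1.0 / w[g]
    return num / den if den > 0 else 0.0


def tmm_factors_naive(counts, trim_M=0.30, trim_A=0.05):
    """Full TMM factor vector, anchored to geometric mean 1."""
    counts = np.asarray(counts, float)
    lib = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j] / lib[j] * 1e6, 0.75)
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.array(
        [0.0 if j == ref else tmm_naive(counts, lib, ref, j, trim_M, trim_A)
         for j in range(counts.shape[1])]
    )
    f = 2.0 ** logf
    return f / np.exp(np.mean(np.log(f)))


def moderated_t_naive(y, w, case_mask, s2_prior=None, df_prior=None):
    """Per-gene weighted LS fit + closed-form posterior variance, gene by gene.

    When the prior is not supplied it is estimated by the same log-variance
    moment matching, but with the trigamma inversion done by scipy's brentq
    root finder instead of Newton iteration.
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    n = y.shape[1]
    X = np.column_stack([np.ones(n), case_mask.astype(float)])
    effects, s2s, vs = [], [], []
    for g in range(y.shape[0]):
        Wg = np.diag(w[g])
        beta = np.linalg.solve(X.T @ Wg @ X, X.T @ Wg @ y[g])
        resid = y[g] - X @ beta
        s2s.append(float(resid @ Wg @ resid) / (n - 2))
        effects.append(beta[1])
        vs.append(np.linalg.inv(X.T @ Wg @ X)[1, 1])
    effects, s2s, vs = map(np.array, (effects, s2s, vs))
    df = n - 2

    if s2_prior is None:
        z = np.log(s2s[s2s > 0])
        e = z - special.digamma(df / 2) + np.log(df / 2)
        evar = np.var(e, ddof=1) - special.polygamma(1, df / 2)
        if evar > 0:
            from scipy.optimize import brentq

            half_d0 = brentq(lambda a: special.polygamma(1, a) - evar, 1e-6, 1e8)
            df_prior = 2 * half_d0
            s2_prior = np.exp(
                np.mean(e) + special.digamma(half_d0) - np.log(half_d0)
            )
        else:
            df_prior, s2_prior = np.inf, np.exp(np.mean(e))

    if np.isinf(df_prior):
        s2_post = np.full_like(s2s, s2_prior)
        df_tot = np.inf
    else:
        s2_post = (df_prior * s2_prior + df * s2s) / (df_prior + df)
        df_tot = df_prior + df
    t = effects / np.sqrt(s2_post * vs)
    p = 2 * stats.t.sf(np.abs(t), df_tot)
    return t, p, s2_post


def voom_naive(counts, eff_lib, case_mask, span=0.5):
    """Step-by-step mean-variance-trend precision weights."""
    counts = np.asarray(counts, float)
    eff_lib = np.asarray(eff_lib, float)
    y = np.log2((counts + 0.5) / (eff_lib + 1) * 1e6)
    fitted = np.empty_like(y)
    for g in range(y.shape[0]):
        fitted[g, case_mask] = y[g, case_mask].mean()
        fitted[g, ~case_mask] = y[g, ~case_mask].mean()
    sigma = np.array(
        [np.sqrt(((y[g] - fitted[g]) ** 2).sum() / (y.shape[1] - 2))
         for g in range(y.shape[0])]
    )
    sx = y.mean(axis=1) + np.mean(np.log2(eff_lib + 1)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    w = np.empty_like(y)
    for g in range(y.shape[0]):
        for j in range(y.shape[1]):
            logcount = np.log2(1e-6 * 2 ** fitted[g, j] * (eff_lib[j] + 1))
            pred = np.interp(logcount, trend[:, 0], trend[:, 1])
            w[g, j] = max(pred, 1e-6) ** -4
    return y, w


def kcdf_naive(x):
    """Gaussian-kernel CDF scores by explicit double loop, h = SD/4."""
    x = np.asarray(x, float)
    n = x.shape[1]
    z = np.zeros_like(x)
    for g in range(x.shape[0]):
        h = max(np.std(x[g], ddof=1) / 4.0, 1e-8)
        for j in range(n):
            z[g, j] = np.mean([stats.norm.cdf((x[g, j] - x[g, k]) / h)
                               for k in range(n)])
    return z


def es_naive(rank_scores, order, members, tau=1.0):
    """Enrichment score by an explicit cumulative random walk."""
    p = len(rank_scores)
    inside = [g in members for g in order]
    m = sum(inside)
    denom = sum(abs(rank_scores[g]) ** tau for g, i in zip(order, inside) if i)
    cum, walk = 0.0, []
    for g, i in zip(order, inside):
        if i:
            # zero total weight: uniform inside steps
            cum += abs(rank_scores[g]) ** tau / denom if denom > 0 else 1.0 / m
        else:
            cum -= 1.0 / (p - m)
        walk.append(cum)
    d_pos = max(max(walk), 0.0)
    d_neg = min(min(walk), 0.0)
    return d_pos + d_neg
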