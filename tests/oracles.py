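"""Independent brute-force reference implementations used only by tests.

Every function here is written from the defining formula with explicit
loops / normal equations, deliberately sharing no code with the package,
so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def wls_origin_oracle(bx, by, se_out):
    """Weighted least squares through the origin + weighted residual SS."""
    num = den = 0.0
    for x, y, s in zip(bx, by, se_out):
        w = 1.0 / s**2
        num += w * x * y
        den += w * x * x
    slope = num / den
    q = 0.0
    for x, y, s in zip(bx, by, se_out):
        q += (y - slope * x) ** 2 / s**2
    return slope, math.sqrt(1.0 / den), q


def wls_intercept_oracle(bx, by, se_out):
    """Free-intercept WLS via explicitly assembled normal equations."""
    sw = swx = swx2 = swy = swxy = 0.0
    for x, y, s in zip(bx, by, se_out):
        w = 1.0 / s**2
        sw += w
        swx += w * x
        swx2 += w * x * x
        swy += w * y
        swxy += w * x * y
    det = sw * swx2 - swx * swx
    intercept = (swx2 * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    q = 0.0
    for x, y, s in zip(bx, by, se_out):
        q += (y - intercept - slope * x) ** 2 / s**2
    # unscaled covariance diag of (intercept, slope)
    cov00 = swx2 / det
    cov11 = sw / det
    return intercept, slope, q, math.sqrt(cov00), math.sqrt(cov11)


def weighted_median_oracle(ratios, weights):
    """Interpolated weighted median, re-derived step by step."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    ps = []
    for r, w in pairs:
        ps.append((cum + w / 2.0) / total)
        cum += w
    # find the bracketing pair around probability 0.5 and interpolate
    if ps[0] >= 0.5:
        return pairs[0][0]
    if ps[-1] <= 0.5:
        return pairs[-1][0]
    for k in range(len(ps) - 1):
        if ps[k] <= 0.5 <= ps[k + 1]:
            frac = (0.5 - ps[k]) / (ps[k + 1] - ps[k])
            return pairs[k][0] + frac * (pairs[k + 1][0] - pairs[k][0])
    raise AssertionError("unreachable")


def greedy_clump_oracle(snp_ids, pvals, r2_lookup, threshold):
    """Greedy clumping re-implemented with explicit set bookkeeping.

    ``r2_lookup``: callable (snp_a, snp_b) -> r2. Ties on p-value break by
    lexicographically smaller snp_id.
    """
    remaining = list(snp_ids)
    pmap = dict(zip(snp_ids, pvals))
    kept = []
    while remaining:
        best = min(remaining, key=lambda s: (pmap[s], s))
        kept.append(best)
        remaining = [
            s for s in remaining if s != best and r2_lookup(best, s) <= threshold
        ]
    return kept


def fixed_meta_oracle(thetas, ses):
    """Inverse-variance pooling from the defining sums."""
    ws = [1.0 / s**2 for s in ses]
    pooled = sum(w * t for w, t in zip(ws, thetas)) / sum(ws)
    se = math.sqrt(1.0 / sum(ws))
    q = sum(w * (t - pooled) ** 2 for w, t in zip(ws, thetas))
    return pooled, se, q


def dl_meta_oracle(thetas, ses):
    """DerSimonian-Laird pooling from the textbook formula."""
    k = len(thetas)
    ws = [1.0 / s**2 for s in ses]
    fixed = sum(w * t for w, t in zip(ws, thetas)) / sum(ws)
    q = sum(w * (t - fixed) ** 2 for w, t in zip(ws, thetas))
    c = sum(ws) - sum(w**2 for w in ws) / sum(ws)
    tau2 = max(0.0, (q - (k - 1)) / c)
    wstar = [1.0 / (s**2 + tau2) for s in ses]
    pooled = sum(w * t for w, t in zip(wstar, thetas)) / sum(wstar)
    se = math.sqrt(1.0 / sum(wstar))
    return pooled, se, tau2


def ols_oracle(y, x_columns):
    """OLS coefficients and SEs via (X'X)^-1 X'y with an intercept."""
    n = len(y)
    x = np.column_stack([np.ones(n)] + [np.asarray(c, float) for c in x_columns])
    y = np.asarray(y, float)
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    p = x.shape[1]
    sigma2 = float(resid @ resid) / (n - p)
    cov = sigma2 * np.linalg.inv(xtx)
    return beta, np.sqrt(np.diag(cov))


def simple_concordance_oracle(x, y):
    """Slope/intercept/R^2 from covariance and correlation definitions."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    slope = cov / np.var(x)
    intercept = y.mean() - slope * x.mean()
    r = cov / (np.std(x) * np.std(y))
    return slope, intercept, r * r
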