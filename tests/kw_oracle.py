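"""Independent brute-force Kruskal-Wallis oracle used only by tests.

Midranks, the rank-sum formula and the tie-correction divisor are computed
from first principles; the chi-square upper tail is an incomplete-gamma
series/continued-fraction evaluation (no reuse of the statistics stack the
implementation itself calls).
"""

import math

import numpy as np


def midranks(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=float)
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # average of 1-based positions i+1..j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kw_statistic(groups):
    """Tie-corrected Kruskal-Wallis H by the rank-sum formula."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    N = pooled.size
    ranks = midranks(pooled)
    H = 0.0
    start = 0
    for n_i in sizes:
        rbar = ranks[start : start + n_i].mean()
        H += n_i * (rbar - (N + 1) / 2.0) ** 2
        start += n_i
    H *= 12.0 / (N * (N + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    if correction == 0.0:
        return 0.0
    return H / correction


def _gamma_series_p(a, x, eps=1e-15, itmax=10000):
    """Lower regularized incomplete gamma P(a, x) by series expansion."""
    if x <= 0:
        return 0.0
    ap = a
    summ = 1.0 / a
    delta = summ
    for _ in range(itmax):
        ap += 1.0
        delta *= x / ap
        summ += delta
        if abs(delta) < abs(summ) * eps:
            break
    return summ * math.exp(-x + a * math.log(x) - math.lgamma(a))


def _gamma_cf_q(a, x, eps=1e-15, itmax=10000):
    """Upper regularized incomplete gamma Q(a, x) by continued fraction."""
    tiny = 1e-300
    b = x + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, itmax + 1):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            break
    return h * math.exp(-x + a * math.log(x) - math.lgamma(a))


def chi2_sf(x, df):
    """Upper-tail chi-square probability from the incomplete gamma."""
    if x <= 0:
        return 1.0
    a, half = df / 2.0, x / 2.0
    if half < a + 1.0:
        return 1.0 - _gamma_series_p(a, half)
    return _gamma_cf_q(a, half)


def kw_oracle(groups):
    """(H, p) with the degenerate all-identical rule."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H = kw_statistic(groups)
    return H, chi2_sf(H, len(groups) - 1)


def kw_permutation_p(groups, n_perm=10000, seed=0):
    """Monte-Carlo permutation p-value for the observed H."""
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    h_obs = kw_statistic(groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts, start = [], 0
        for n_i in sizes:
            parts.append(perm[start : start + n_i])
            start += n_i
        if kw_statistic(parts) >= h_obs - 1e-12:
            count += 1
    return count / n_perm
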