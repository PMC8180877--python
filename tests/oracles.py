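"""Independent brute-force oracles, deliberately naive.

Everything here recomputes statistics by direct definition (pair counting,
explicit ranks, full enumeration, plain loops) so the package's vectorized
or library-backed implementations can be checked against code that shares
nothing with them.
"""

import itertools
import math

import numpy as np


def rankdata_average(x):
    """Average ranks by explicit sorting (no scipy)."""
    x = list(x)
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def tau_b_brute(x, y):
    """Kendall tau-b by direct concordant/discordant/tied pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - _tie_term(x)) * (n0 - _tie_term(y)))
    return (conc - disc) / denom


def _tie_term(v):
    from collections import Counter
    return sum(t * (t - 1) / 2 for t in Counter(v).values())


def kruskal_h_brute(groups):
    """Tie-corrected Kruskal-Wallis H from explicit ranks."""
    pooled = [v for g in groups for v in g]
    n_tot = len(pooled)
    ranks = rankdata_average(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i:i + len(g)]
        i += len(g)
        h += sum(r) ** 2 / len(g)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    from collections import Counter
    ties = sum(t**3 - t for t in Counter(pooled).values())
    correction = 1.0 - ties / (n_tot**3 - n_tot)
    return h / correction


def mann_whitney_u_brute(a, b):
    """U of the first sample by counting pairwise wins (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def bh_brute(pvals):
    """Step-up BH by the textbook recipe."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def log_posterior_brute(params, data, priors):
    """From-scratch joint log-density of the hierarchical cumulative-logit
    model: plain Python loops, scipy distribution objects only."""
    from scipy.stats import norm, dirichlet, multivariate_normal, logistic
    from scipy.special import beta as beta_fn

    lp = 0.0
    for o in ("artist", "audience"):
        for b in np.atleast_1d(params.beta[o]):
            lp += norm.logpdf(b, 0, priors.beta_sd)
    for m, cut in params.cut.items():
        cut = np.asarray(cut, dtype=float)
        k = cut.size + 1
        cdf = [0.0] + [logistic.cdf(c - priors.cut_anchor) for c in cut] + [1.0]
        p = np.diff(cdf)
        lp += dirichlet.logpdf(p / p.sum(), [priors.cut_alpha] * k)
        for c in cut:
            lp += logistic.logpdf(c - priors.cut_anchor)
    for s in params.sigma_u:
        lp += norm.logpdf(s, 0, priors.sigma_sd) + math.log(2.0)
    rho = params.L[1, 0] / math.hypot(params.L[1, 0], params.L[1, 1])
    eta = priors.lkj_eta
    lp += (eta - 1) * math.log(1 - rho**2) \
        - ((2 * eta - 1) * math.log(2) + math.log(beta_fn(eta, eta)))
    s1, s2 = params.sigma_u
    cov = [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
    for row in params.u:
        lp += multivariate_normal.logpdf(row, [0, 0], cov)
    if params.w is not None:
        lp += norm.logpdf(params.sigma_w, 0, priors.sigma_sd) + math.log(2.0)
        for wc in params.w:
            lp += norm.logpdf(wc, 0, params.sigma_w)

    for i, o in enumerate(("artist", "audience")):
        X = data.X[o]
        beta = np.atleast_1d(params.beta[o])
        for m, yvec in data.y[o].items():
            cut = np.asarray(params.cut[m], dtype=float)
            for r in range(len(yvec)):
                yy = yvec[r]
                if yy < 1:
                    continue
                e = float(np.dot(X[r], beta))
                if params.w is not None and data.concert_idx is not None:
                    e += params.w[data.concert_idx[r]]
                shift = params.u[data.participant_idx[r], i]
                hi = cut[yy - 1] + shift if yy - 1 < len(cut) else math.inf
                lo = cut[yy - 2] + shift if yy >= 2 else -math.inf
                prob = logistic.cdf(hi - e) - logistic.cdf(lo - e)
                lp += math.log(prob)
    return lp
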