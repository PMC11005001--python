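"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written with different numerical machinery than the
package (explicit loops, bracketing root-finders, first-principles
combinatorics) so that agreement is evidence of correctness rather than
shared code paths.
"""

import numpy as np
from scipy import optimize, special, stats


def oracle_moderated_t(X, n1, n2):
    """Two-group moderated t via the moment-matching formulas, feature by
    feature, with trigamma inverted by bracketing root-finding."""
    g = X.shape[0]
    m1 = X[:, :n1].mean(axis=1)
    m2 = X[:, n1:].mean(axis=1)
    df = n1 + n2 - 2
    s2 = np.empty(g)
    for i in range(g):
        rss = ((X[i, :n1] - m1[i]) ** 2).sum() + ((X[i, n1:] - m2[i]) ** 2).sum()
        s2[i] = rss / df
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar > 0:
        half_d0 = optimize.brentq(
            lambda x: special.polygamma(1, x) - evar, 1e-8, 1e8
        )
        d0 = 2 * half_d0
        s0 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = min(d0 + df, g * df)
    else:
        d0 = np.inf
        s0 = s2.mean()  # pooled variance
        s2_post = np.full(g, s0)
        df_total = g * df  # capped at the pooled residual df
    fc = m2 - m1
    t = fc / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df=df_total)
    return fc, t, p, d0, s0


def bh_oracle(p):
    """Benjamini–Hochberg step-up computed directly from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return np.minimum(adj, 1.0)


def qn_oracle_complete(X):
    """Complete-data quantile normalization: mean of order statistics
    written back by rank."""
    order = np.argsort(X, axis=0)
    ref = np.mean(np.sort(X, axis=0), axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        out[order[:, j], j] = ref
    return out


def enrichment_oracle(ranked, term, background):
    """Min-over-prefixes hypergeometric tail from first-principles
    combinatorics."""
    from math import comb

    N = len(background)
    T = term & background
    K = len(T)
    best = 1.0
    for n in range(1, len(ranked) + 1):
        k = len(set(ranked[:n]) & T)
        tail = sum(
            comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)
        ) / comb(N, n)
        best = min(best, tail)
    return best


def median_oracle(pairs):
    """Per-gene median via sorting, no library median call."""
    by_gene = {}
    for gene, v in pairs:
        by_gene.setdefault(gene, []).append(v)
    out = {}
    for gene, vals in by_gene.items():
        vals = sorted(vals)
        n = len(vals)
        out[gene] = (
            vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
        )
    return out
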