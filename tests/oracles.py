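"""Independent brute-force oracles used by the test suite.

Each function recomputes a pipeline quantity from first principles by a
route deliberately different from the implementation: direct enumeration,
naive loops, or closed forms.  They are slow and simple on purpose.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up by literal definition:
    q_(i) = min_{j >= i} min(1, p_(j) * m / j), back in input order."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(1.0, p[order[j]] * m / (j + 1)) for j in range(i, m)
        )
    out = np.empty(m)
    out[order] = q_sorted
    return out


def pooled_t(control, treatment) -> tuple[float, float, int]:
    """Classical pooled two-sample t statistic, its two-sided p, and df."""
    from scipy import stats

    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    nc, nt = len(c), len(t)
    df = nc + nt - 2
    sp2 = (np.sum((c - c.mean()) ** 2) + np.sum((t - t.mean()) ** 2)) / df
    stat = (t.mean() - c.mean()) / math.sqrt(sp2 * (1 / nc + 1 / nt))
    p = 2 * stats.t.sf(abs(stat), df)
    return stat, p, df


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    denom = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    ) / denom


def ward_merge_heights(points: np.ndarray) -> np.ndarray:
    """Minimum-variance agglomeration by direct recomputation.

    Clusters are kept as explicit point sets; at every step the pair
    minimizing the Ward merge cost

        d2(A, B) = 2 |A| |B| / (|A| + |B|) * ||mean(A) - mean(B)||^2

    is merged and sqrt(d2) recorded.  Equivalent to the ward.D2
    convention but computed from raw points, not by recurrence.
    """
    clusters = [np.atleast_2d(p) for p in np.asarray(points, dtype=float)]
    heights = []
    while len(clusters) > 1:
        best = None
        for (i, a), (j, b) in combinations(enumerate(clusters), 2):
            na, nb = len(a), len(b)
            d2 = 2 * na * nb / (na + nb) * np.sum((a.mean(axis=0) - b.mean(axis=0)) ** 2)
            if best is None or d2 < best[0]:
                best = (d2, i, j)
        d2, i, j = best
        heights.append(math.sqrt(d2))
        merged = np.vstack([clusters[i], clusters[j]])
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return np.asarray(heights)


def motif_matrix(foreground, background, pseudocount=0.0) -> np.ndarray:
    """Scaled enrichment information content by naive counting."""
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    L = len(foreground[0])
    out = np.zeros((L, 20))
    for pos in range(L):
        fg = [w[pos] for w in foreground if w[pos] != "-"]
        bg = [w[pos] for w in background if w[pos] != "-"]
        nf, nb = len(fg), len(bg)
        for r, res in enumerate(aa):
            f = (fg.count(res) + pseudocount) / (nf + 20 * pseudocount)
            b = (bg.count(res) + pseudocount) / (nb + 20 * pseudocount)
            if f == 0:
                continue
            if b == 0:
                b = 1.0 / (nb + 20)
            val = f * math.log2(f / b)
            out[pos, r] = min(max(val, 0.0), math.log2(20)) / math.log2(20)
    return out


def sample_variances(rng, n, d, d0, s0_sq) -> np.ndarray:
    """Residual variances from the hierarchical model: sigma^2 is scaled
    inverse-chi-square (d0, s0_sq), s2 | sigma^2 ~ sigma^2 * chi2_d / d."""
    sigma2 = s0_sq * d0 / rng.chisquare(d0, size=n)
    return sigma2 * rng.chisquare(d, size=n) / d
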