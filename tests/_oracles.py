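"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately naive (enumeration, full sorts, O(n^3) scans)
and shares no code with the package paths it checks.
"""

from itertools import combinations, product

import numpy as np


def signed_rank_p_enumeration(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    absd = np.abs(d)
    order = np.argsort(absd)
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    w_obs = ranks[d > 0].sum()
    m = n * (n + 1) / 2
    w_hi, w_lo = max(w_obs, m - w_obs), min(w_obs, m - w_obs)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w >= w_hi or w <= w_lo:
            count += 1
    return min(count / 2.0**n, 1.0)


def bh_stepup(p) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(p[i] * m / rank_from_top, prev)
        adj[i] = val
        prev = val
    return adj


def complete_linkage_heights(points) -> list[float]:
    """Merge heights of naive complete-linkage agglomeration (O(n^3))."""
    clusters = [[i] for i in range(len(points))]
    points = np.asarray(points, dtype=float)
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(
                    np.linalg.norm(points[i] - points[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def sam_exhaustive_q(X, n_tumour, s0) -> np.ndarray:
    """Permutation-FDR q values for a two-group design by full enumeration.

    ``X`` is probes x samples with the first ``n_tumour`` columns labelled
    tumour. Mirrors the published procedure: for each observed |d|
    threshold, expected false positives are averaged over every balanced
    label assignment; q is the running minimum of expected/observed from
    the smallest threshold up.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]

    def d_stat(t_idx):
        t_idx = np.asarray(t_idx)
        mask = np.zeros(n, dtype=bool)
        mask[t_idx] = True
        T, N = X[:, mask], X[:, ~mask]
        n1, n2 = T.shape[1], N.shape[1]
        num = T.mean(axis=1) - N.mean(axis=1)
        ss = T.var(axis=1, ddof=1) * (n1 - 1) + N.var(axis=1, ddof=1) * (n2 - 1)
        s = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
        return num / (s + s0)

    d_obs = np.abs(d_stat(np.arange(n_tumour)))
    all_d = [np.abs(d_stat(c)) for c in combinations(range(n), n_tumour)]
    q = np.empty(d_obs.size)
    for i, thr in enumerate(d_obs):
        expected = np.mean([(dp >= thr).sum() for dp in all_d])
        observed = (d_obs >= thr).sum()
        q[i] = min(expected / observed, 1.0)
    # monotonise: a larger |d| can never have a larger q
    order = np.argsort(-d_obs, kind="stable")
    q_sorted = np.minimum.accumulate(q[order][::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q_sorted
    return out


def fisher_two_sided_enumeration(a, b, c, d) -> float:
    """Two-sided Fisher p by scanning every table with the observed margins."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    ntot = r1 + r2
    denom = comb(ntot, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x) * comb(r2, c1 - x) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
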