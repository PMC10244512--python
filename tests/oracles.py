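"""Brute-force reference implementations used only to cross-check results.

These deliberately share no code with the package: rank-sum p-values by
full enumeration, BH by the quadratic step-up definition, Spearman by
hand-computed midranks + Pearson, and interval overlap by a nested scan.
"""

from itertools import combinations

import numpy as np


def exact_rank_sum_p(x, y):
    """Two-sided permutation p for the rank-sum statistic, by enumeration."""
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    # midranks by hand
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    mu = n1 * ranks.sum() / n
    obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for comb in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(comb)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def naive_bh(p):
    """Quadratic Benjamini-Hochberg step-up: q_i = min_{p_j >= p_i} p_j m / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    rank_of = np.empty(m, int)
    rank_of[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        candidates = [
            p[j] * m / rank_of[j] for j in range(m) if p[j] >= p[i] - 1e-15
        ]
        q[i] = min(1.0, min(candidates))
    return q


def midrank_spearman(x, y):
    """Spearman rho as the Pearson correlation of hand-computed midranks."""

    def midranks(v):
        v = np.asarray(v, float)
        out = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            out[i] = less + (equal + 1) / 2.0
        return out

    rx, ry = midranks(x), midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_force_overlaps(probe_positions, intervals, flank=0):
    """Set of probe indices whose (flanked) 1-bp interval hits any interval."""
    hits = set()
    for i, (chrom, pos) in enumerate(probe_positions):
        lo, hi = pos - flank, pos + 1 + flank
        for ichrom, start, end in intervals:
            if chrom == ichrom and lo < end and start < hi:
                hits.add(i)
                break
    return hits


def brute_force_cis_pairs(probes, genes, window):
    """All-vs-all distance scan for the cis-window enumeration."""
    out = set()
    for p in probes:
        for g in genes:
            tss = g.start if g.strand == "+" else g.end - 1
            if g.chrom == p.chrom and abs(tss - p.pos) <= window:
                out.add((p.probe_id, g.gene_id))
    return out
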