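"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive (per-base loops, exhaustive
enumeration) and shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def naive_classify(reads, genes, promoter_bp):
    """Per-read feature assignment by explicit interval checks.

    ``reads``: list of (chrom, start, end); ``genes``: list of
    (gene_id, chrom, strand, start, end). Returns (promoter, cds,
    intergenic, genic) counts.
    """
    promoters = []
    bodies = []
    for _, chrom, strand, gs, ge in genes:
        if strand == "+":
            tss = gs
            promoters.append((chrom, max(0, tss - promoter_bp), tss))
        else:
            tss = ge - 1
            promoters.append((chrom, tss + 1, tss + 1 + promoter_bp))
        bodies.append((chrom, gs, ge))

    def hits(read, feats):
        rc, rs, re = read
        return any(rc == c and rs < e and s < re for c, s, e in feats)

    n_prom = n_cds = n_inter = 0
    for read in reads:
        p = hits(read, promoters)
        b = hits(read, bodies)
        n_prom += p
        n_cds += b
        n_inter += not (p or b)
    return n_prom, n_cds, n_inter, len(reads) - n_inter


def naive_tss_profile(reads, genes, window, bin_bp):
    """Base-by-base metagene profile, averaged over genes."""
    n_bins = 2 * window // bin_bp
    acc = np.zeros(n_bins)
    for _, chrom, strand, gs, ge in genes:
        tss = gs if strand == "+" else ge - 1
        depth = np.zeros(2 * window)
        for off_idx in range(2 * window):
            offset = off_idx - window
            pos = tss + offset if strand == "+" else tss - offset
            for rc, rs, re in reads:
                if rc == chrom and rs <= pos < re:
                    depth[off_idx] += 1
        acc += depth.reshape(n_bins, bin_bp).mean(axis=1)
    return acc / len(genes)


def naive_gene_scores(reads, genes, promoter_bp, window):
    """Per-gene overlap counts by explicit checks."""
    out = {}
    for gid, chrom, strand, gs, ge in genes:
        if strand == "+":
            tss = gs
            prom = (max(0, tss - promoter_bp), tss)
            win = (max(0, tss - window), tss + window)
        else:
            tss = ge - 1
            prom = (tss + 1, tss + 1 + promoter_bp)
            win = (max(0, tss - window + 1), tss + window + 1)

        def count(lo, hi):
            return sum(1 for rc, rs, re in reads if rc == chrom and rs < hi and lo < re)

        out[gid] = (count(*prom), count(gs, ge), count(*win))
    return out


def exhaustive_min_inertia(points: np.ndarray, k: int) -> float:
    """Minimum within-cluster sum of squares over all assignments of
    n points to at most k clusters (n small)."""
    n = len(points)
    best = math.inf
    for assign in product(range(k), repeat=n):
        inertia = 0.0
        for c in range(k):
            members = points[[i for i in range(n) if assign[i] == c]]
            if len(members):
                inertia += float(((members - members.mean(axis=0)) ** 2).sum())
        best = min(best, inertia)
    return best


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by explicit summation of the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def mirror_instance(reads, genes, length):
    """Reflect all coordinates through a genome of given length and flip
    strands; TSS-relative geometry must be invariant under this map."""
    m_reads = [(c, length - e, length - s) for c, s, e in reads]
    m_genes = [
        (gid, c, "-" if strand == "+" else "+", length - ge, length - gs)
        for gid, c, strand, gs, ge in genes
    ]
    return m_reads, m_genes
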