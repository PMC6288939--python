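"""Independent brute-force oracles used by the test suite.

These deliberately use naive per-base / enumeration algorithms, kept
separate from the package implementations they check.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np


def perbase_flatten(exons):
    """Per-base gene-membership scan: the reference answer for region flattening.

    ``exons`` is a sequence of ExonRecord-like objects.  Returns
    ``(retained, clusters)`` where ``retained`` is a set of
    ``(gene_id, chrom, start, end, kind, n_source_exons)`` tuples and
    ``clusters`` is a set of frozensets of ``(gene_id, start, end)`` member
    intervals (one frozenset per ambiguous cluster, per chromosome the
    members' chrom is implied by construction on single-chrom fixtures).
    """
    base_genes: dict[tuple[str, int], set[str]] = defaultdict(set)
    gene_bases: dict[tuple[str, str], set[int]] = defaultdict(set)
    for e in exons:
        for b in range(e.start, e.end + 1):
            base_genes[(e.chrom, b)].add(e.gene_id)
            gene_bases[(e.gene_id, e.chrom)].add(b)

    merged = []  # (gene, chrom, start, end, n_source)
    for (gene, chrom), bases in gene_bases.items():
        gene_exons = [e for e in exons if e.gene_id == gene and e.chrom == chrom]

        def spanned(b, _exons=gene_exons):
            # adjacent-but-not-overlapping exons stay separate: a run only
            # continues across b -> b+1 if one exon covers both bases
            return any(x.start <= b and x.end >= b + 1 for x in _exons)

        ordered = sorted(bases)
        runs = []
        run_start = prev = ordered[0]
        for b in ordered[1:]:
            if b == prev + 1 and spanned(prev):
                prev = b
            else:
                runs.append((run_start, prev))
                run_start = prev = b
        runs.append((run_start, prev))
        for start, end in runs:
            sources = {
                (x.start, x.end)
                for x in exons
                if x.gene_id == gene
                and x.chrom == chrom
                and x.start <= end
                and x.end >= start
            }
            merged.append((gene, chrom, start, end, len(sources)))

    ambiguous = [
        m
        for m in merged
        if any(len(base_genes[(m[1], b)]) > 1 for b in range(m[2], m[3] + 1))
    ]
    retained = {
        (g, c, s, e, "single" if n == 1 else "overlap", n)
        for (g, c, s, e, n) in merged
        if (g, c, s, e, n) not in ambiguous
    }

    # cluster ambiguous intervals that share bases (transitively)
    clusters = []
    remaining = list(ambiguous)
    while remaining:
        seed = remaining.pop()
        cluster = [seed]
        cluster_bases = set(range(seed[2], seed[3] + 1))
        changed = True
        while changed:
            changed = False
            for m in list(remaining):
                if m[1] == seed[1] and cluster_bases & set(range(m[2], m[3] + 1)):
                    cluster.append(m)
                    cluster_bases |= set(range(m[2], m[3] + 1))
                    remaining.remove(m)
                    changed = True
        clusters.append(frozenset((g, s, e) for (g, c, s, e, n) in cluster))
    return retained, set(clusters)


def bh_reject_oracle(p_values: np.ndarray, alpha: float) -> set[int]:
    """BH rejection set by the step-up definition: largest k with p_(k) <= k*alpha/m."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    return set(order[:k_max].tolist())


def hypergeom_enum(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability by direct enumeration."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


def welch_by_hand(a, b):
    """Scalar Welch test worked from the textbook formulas."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    d = a.mean() - b.mean()
    se2 = va / na + vb / nb
    t = d / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return d, t, df, p
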