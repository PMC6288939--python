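"""Hypergeometric over-representation of gene sets in a DE gene list.

Gene-set "enrichment" here is the classical over-representation test: for
each annotated set, the overlap between the differentially expressed genes
and the set is compared with the hypergeometric expectation.  The
background (universe) is restricted to genes that were both tested and
carry at least one annotation of the tested type, and BH correction is
applied across the sets of one annotation type for one comparison, with
significance at FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .model import adjust_fdr


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"gene set {self.set_id!r} is empty")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (set id, description, then gene ids)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT needs >= 3 tab-separated fields"
                )
            genes = frozenset(g for g in cols[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set has no genes")
            sets.append(GeneSet(cols[0], cols[1] or cols[0], genes))
    return sets


def hypergeom_upper_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) for X ~ Hypergeom(N, K, n).

    ``k`` successes among ``n`` draws, from an urn of ``N`` with ``K``
    marked.  Computed via the survival function (log-space internally).
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent margins: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_enrichment(
    de_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of each gene set in the DE list.

    The universe should already be restricted to tested genes; it is further
    intersected with the union of annotated genes so that only genes with
    the relevant annotation form the background.  Sets with no member in the
    universe are omitted.  Returns one row per kept set with k, K, n, N, the
    upper-tail p, BH-adjusted p, and a significance flag at ``fdr``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    annotated = set().union(*(s.gene_ids for s in gene_sets)) if gene_sets else set()
    background = universe & annotated
    if not background:
        raise ValueError("no universe gene carries any annotation")
    de = set(de_genes) & background
    N, n = len(background), len(de)

    rows = []
    for s in gene_sets:
        members = s.gene_ids & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & de)
        rows.append(
            {
                "set_id": s.set_id,
                "name": s.name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_upper_p(k, K, n, N),
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_id", "name", "k", "K", "n", "N", "p"]
    )
    if len(out):
        out["p_adj"] = adjust_fdr(out["p"].to_numpy())
        out["significant"] = out["p_adj"] < fdr
        out = out.sort_values(["p", "set_id"], kind="stable").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
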