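"""Flatten a GFF3 exon annotation into unique exonic regions per gene.

Counting reads at the exon level is ambiguous wherever annotated exons
overlap.  Overlapping exons *of the same gene* are merged into a single
"overlap region" (a maximal interval); exons or merged intervals that
share bases with a *different* gene cannot be attributed unambiguously
and are excluded from analysis.  The retained intervals — single exons
plus same-gene overlap regions — are the unit of quantification and
testing for the whole pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention); the BED
writer converts to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd


class GFFParseError(ValueError):
    """Raised for a malformed GFF3 line; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"GFF3 parse error at line {line_number}: {message}")


class GeneAttributionError(ValueError):
    """Raised when an exon feature has no resolvable gene."""


@dataclass(frozen=True)
class ExonRecord:
    exon_id: str
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"exon {self.exon_id}: start {self.start} > end {self.end}"
            )
        if not self.gene_id:
            raise ValueError(f"exon {self.exon_id}: empty gene_id")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExonicRegion:
    """A unique genomic interval attributed to exactly one gene."""

    region_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    kind: str  # "single" | "overlap"
    n_source_exons: int
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AmbiguousRegion:
    """A cluster of merged intervals shared between >= 2 genes, excluded."""

    chrom: str
    start: int
    end: int
    gene_ids: frozenset[str]
    # the per-gene merged intervals making up the cluster
    members: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError("AmbiguousRegion requires >= 2 genes")


def _prescan_gff(path: str | Path) -> None:
    """Cheap line-level validation so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                return
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(lineno, f"expected 9 columns, found {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise GFFParseError(
                    lineno, f"non-integer coordinates {cols[3]!r}/{cols[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise GFFParseError(lineno, f"bad interval [{start}, {end}]")


def _resolve_gene(db: gffutils.FeatureDB, feature: gffutils.Feature) -> str:
    """Gene attribution: a gene_id attribute, else the top of the Parent chain."""
    if "gene_id" in feature.attributes:
        return feature.attributes["gene_id"][0]
    current = feature
    seen: set[str] = set()
    while "Parent" in current.attributes:
        parent_id = current.attributes["Parent"][0]
        if parent_id in seen:
            raise GeneAttributionError(
                f"cyclic Parent chain at feature {feature.id!r}"
            )
        seen.add(parent_id)
        try:
            current = db[parent_id]
        except gffutils.FeatureNotFoundError:
            # parent referenced but not defined: treat its id as the gene
            return parent_id
        if current.featuretype == "gene":
            return current.id
    if current is not feature:
        return current.id
    raise GeneAttributionError(
        f"exon feature {feature.id!r} ({feature.seqid}:{feature.start}-{feature.end}) "
        "has neither a gene_id attribute nor a Parent chain"
    )


def read_gff(path: str | Path, feature: str = "exon") -> list[ExonRecord]:
    """Read exon features from a GFF3 file into :class:`ExonRecord` objects.

    Parameters
    ----------
    path
        GFF3 file (1-based inclusive coordinates).
    feature
        Feature type to keep (default ``"exon"``).
    """
    _prescan_gff(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    records = []
    for i, feat in enumerate(db.features_of_type(feature, order_by=("seqid", "start"))):
        gene_id = _resolve_gene(db, feat)
        exon_id = feat.id or f"{feature}_{i + 1}"
        records.append(
            ExonRecord(
                exon_id=exon_id,
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    return records


def _merge_gene_exons(
    exons: Sequence[ExonRecord],
) -> list[tuple[int, int, int, str]]:
    """Merge overlapping (>= 1 shared bp) exons of one gene on one chromosome.

    Adjacent-but-not-overlapping exons (end + 1 == next start) stay separate.
    Exact duplicate intervals (the same exon listed once per transcript) count
    as one source exon.  Returns (start, end, n_source_exons, strand) tuples.
    """
    by_coord: dict[tuple[int, int], str] = {}
    for e in sorted(exons, key=lambda x: (x.start, x.end)):
        by_coord.setdefault((e.start, e.end), e.strand)
    intervals = [(s, t, strand) for (s, t), strand in sorted(by_coord.items())]
    merged: list[tuple[int, int, int, str]] = []
    for start, end, strand in intervals:
        if merged and start <= merged[-1][1]:  # >= 1 bp shared
            pstart, pend, n, pstrand = merged[-1]
            merged[-1] = (
                pstart,
                max(pend, end),
                n + 1,
                pstrand if pstrand == strand else ".",
            )
        else:
            merged.append((start, end, 1, strand))
    return merged


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def build_exonic_regions(
    exons: Iterable[ExonRecord],
    trim_ambiguous: bool = False,
) -> tuple[list[ExonicRegion], list[AmbiguousRegion]]:
    """Flatten exons into unique per-gene regions, excluding cross-gene overlap.

    Per gene, overlapping exons are merged into maximal intervals
    (``kind="single"`` from one exon, ``"overlap"`` from several).  A merged
    interval sharing >= 1 bp with another gene's interval is ambiguous: by
    default the whole interval of every gene involved is dropped, and each
    connected cluster of such intervals is reported as one
    :class:`AmbiguousRegion`.  With ``trim_ambiguous=True`` only the shared
    bases are removed and the unambiguous remainders are retained.

    Returns ``(retained, dropped)``.
    """
    exons = list(exons)
    if not exons:
        return [], []

    # warn on genes split across chromosomes; processing is per-chromosome
    chroms_by_gene: dict[str, set[str]] = {}
    for e in exons:
        chroms_by_gene.setdefault(e.gene_id, set()).add(e.chrom)
    for gene_id, chroms in chroms_by_gene.items():
        if len(chroms) > 1:
            warnings.warn(
                f"gene {gene_id} has exons on multiple chromosomes "
                f"({sorted(chroms)}); merged per chromosome",
                stacklevel=2,
            )

    by_chrom: dict[str, dict[str, list[ExonRecord]]] = {}
    for e in exons:
        by_chrom.setdefault(e.chrom, {}).setdefault(e.gene_id, []).append(e)

    retained: list[ExonicRegion] = []
    dropped: list[AmbiguousRegion] = []

    for chrom in sorted(by_chrom):
        genes = by_chrom[chrom]
        # (start, end, n_source, strand, gene_id) merged intervals on this chrom
        merged: list[tuple[int, int, int, str, str]] = []
        for gene_id in sorted(genes):
            for start, end, n, strand in _merge_gene_exons(genes[gene_id]):
                merged.append((start, end, n, strand, gene_id))
        merged.sort(key=lambda t: (t[0], t[1], t[4]))

        # sweep for cross-gene overlap; union-find clusters overlapping intervals
        uf = _UnionFind(len(merged))
        ambiguous_flags = [False] * len(merged)
        active: list[int] = []  # indices with end >= current start
        for i, (start, end, _, _, gene) in enumerate(merged):
            active = [j for j in active if merged[j][1] >= start]
            for j in active:
                if merged[j][4] != gene:
                    ambiguous_flags[i] = ambiguous_flags[j] = True
                    uf.union(i, j)
            active.append(i)

        if trim_ambiguous:
            shared = _shared_base_intervals(merged)
            for start, end, n, strand, gene in merged:
                for tstart, tend in _subtract(start, end, shared):
                    retained.append(
                        ExonicRegion(
                            region_id=f"{gene}:{tstart}-{tend}",
                            gene_id=gene,
                            chrom=chrom,
                            start=tstart,
                            end=tend,
                            kind="single" if n == 1 else "overlap",
                            n_source_exons=n,
                            strand=strand,
                        )
                    )
            for sstart, send in shared:
                genes_here = frozenset(
                    g for (a, b, _, _, g) in merged if a <= send and b >= sstart
                )
                if len(genes_here) >= 2:
                    dropped.append(
                        AmbiguousRegion(chrom, sstart, send, genes_here, ())
                    )
            continue

        clusters: dict[int, list[int]] = {}
        for i in range(len(merged)):
            if ambiguous_flags[i]:
                clusters.setdefault(uf.find(i), []).append(i)
            else:
                start, end, n, strand, gene = merged[i]
                retained.append(
                    ExonicRegion(
                        region_id=f"{gene}:{start}-{end}",
                        gene_id=gene,
                        chrom=chrom,
                        start=start,
                        end=end,
                        kind="single" if n == 1 else "overlap",
                        n_source_exons=n,
                        strand=strand,
                    )
                )
        for members_idx in clusters.values():
            members = tuple(
                (merged[i][4], merged[i][0], merged[i][1]) for i in sorted(members_idx)
            )
            dropped.append(
                AmbiguousRegion(
                    chrom=chrom,
                    start=min(m[1] for m in members),
                    end=max(m[2] for m in members),
                    gene_ids=frozenset(m[0] for m in members),
                    members=members,
                )
            )

    retained.sort(key=lambda r: (r.chrom, r.start, r.end, r.gene_id))
    dropped.sort(key=lambda r: (r.chrom, r.start, r.end))
    return retained, dropped


def _shared_base_intervals(
    merged: Sequence[tuple[int, int, int, str, str]],
) -> list[tuple[int, int]]:
    """Maximal intervals of bases covered by >= 2 distinct genes."""
    events: list[tuple[int, int, str]] = []
    for start, end, _, _, gene in merged:
        events.append((start, 1, gene))
        events.append((end + 1, -1, gene))
    events.sort()
    cover: dict[str, int] = {}
    out: list[tuple[int, int]] = []
    open_start: int | None = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            _, delta, gene = events[i]
            cover[gene] = cover.get(gene, 0) + delta
            if cover[gene] == 0:
                del cover[gene]
            i += 1
        multi = len(cover) >= 2
        if multi and open_start is None:
            open_start = pos
        elif not multi and open_start is not None:
            out.append((open_start, pos - 1))
            open_start = None
    return out


def _subtract(
    start: int, end: int, holes: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Interval minus a sorted disjoint list of intervals."""
    pieces = []
    cur = start
    for hstart, hend in holes:
        if hend < cur or hstart > end:
            continue
        if hstart > cur:
            pieces.append((cur, hstart - 1))
        cur = max(cur, hend + 1)
        if cur > end:
            break
    if cur <= end:
        pieces.append((cur, end))
    return pieces


def regions_to_frame(regions: Sequence[ExonicRegion]) -> pd.DataFrame:
    """Region table: region_id, gene_id, coordinates, kind, n_source_exons, length."""
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "gene_id": [r.gene_id for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "strand": [r.strand for r in regions],
            "kind": [r.kind for r in regions],
            "n_source_exons": [r.n_source_exons for r in regions],
            "length": [r.length for r in regions],
        }
    )


def write_regions_tsv(regions: Sequence[ExonicRegion], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[ExonicRegion], path: str | Path) -> None:
    """Write retained regions as BED6 (0-based, half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t0\t{r.strand}\n"
            )


def summarize_regions(
    retained: Sequence[ExonicRegion], dropped: Sequence[AmbiguousRegion]
) -> dict[str, int]:
    """Census of the flattening: single/overlap counts before and after exclusion.

    "Before" counts every merged interval (including those later excluded as
    ambiguous); "after" counts retained intervals only.
    """
    n_single_after = sum(1 for r in retained if r.kind == "single")
    n_overlap_after = len(retained) - n_single_after
    n_ambiguous_intervals = sum(len(d.members) for d in dropped)
    return {
        "n_single_retained": n_single_after,
        "n_overlap_retained": n_overlap_after,
        "n_retained": len(retained),
        "n_ambiguous_clusters": len(dropped),
        "n_ambiguous_intervals": n_ambiguous_intervals,
        "n_merged_total": len(retained) + n_ambiguous_intervals,
        "n_genes_retained": len({r.gene_id for r in retained}),
    }
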