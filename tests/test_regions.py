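"""Annotation flattening: GFF parsing, interval merging, ambiguity exclusion."""

import numpy as np
import pytest
from oracles import perbase_flatten

from exonde.regions import (
    AmbiguousRegion,
    ExonRecord,
    GeneAttributionError,
    GFFParseError,
    build_exonic_regions,
    read_gff,
    summarize_regions,
    write_regions_bed,
)

GFF_HEADER = "##gff-version 3\n"


def _exon(gene, start, end, chrom="chr1", eid=None):
    return ExonRecord(eid or f"{gene}:{start}", gene, chrom, start, end)


def _write(tmp_path, text, name="test.gff3"):
    path = tmp_path / name
    path.write_text(GFF_HEADER + text)
    return path


class TestReadGff:
    def test_plain_exons_with_gene_id_attribute(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;gene_id=G1\n"
            "chr1\tsrc\texon\t300\t400\t.\t+\t.\tID=e2;gene_id=G1\n"
            "chr1\tsrc\texon\t500\t600\t.\t+\t.\tID=e3;gene_id=G1\n",
        )
        records = read_gff(gff)
        assert len(records) == 3
        assert {r.gene_id for r in records} == {"G1"}
        assert records[0].start == 100 and records[0].end == 200  # 1-based preserved

    def test_feature_filter_excludes_cds(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\tCDS\t100\t200\t.\t+\t0\tID=c1;gene_id=G1\n"
            "chr1\tsrc\tCDS\t300\t400\t.\t+\t0\tID=c2;gene_id=G1\n",
        )
        assert read_gff(gff, feature="exon") == []

    def test_parent_chain_resolves_to_gene(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=G2\n"
            "chr1\tsrc\tmRNA\t1\t1000\t.\t+\t.\tID=mRNA1;Parent=G2\n"
            "chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;Parent=mRNA1\n",
        )
        records = read_gff(gff)
        assert len(records) == 1
        assert records[0].gene_id == "G2"

    def test_dangling_parent_id_used_as_gene(self, tmp_path):
        # Parent points to an undefined ID: the topmost reference is the gene
        gff = _write(tmp_path, "chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;Parent=G9\n")
        assert read_gff(gff)[0].gene_id == "G9"

    def test_malformed_line_names_line_number(self, tmp_path):
        gff = _write(
            tmp_path,
            "chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;gene_id=G1\n"
            "chr1\tsrc\texon\tnotanumber\t400\t.\t+\t.\tID=e2;gene_id=G1\n",
        )
        with pytest.raises(GFFParseError, match="line 3"):
            read_gff(gff)

    def test_exon_without_gene_attribution_is_an_error(self, tmp_path):
        gff = _write(tmp_path, "chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=orphan\n")
        with pytest.raises(GeneAttributionError, match="orphan"):
            read_gff(gff)


class TestBuildExonicRegions:
    def test_same_gene_overlap_merges(self):
        retained, dropped = build_exonic_regions(
            [_exon("G1", 100, 200), _exon("G1", 150, 250)]
        )
        assert dropped == []
        (region,) = retained
        assert (region.start, region.end) == (100, 250)
        assert region.kind == "overlap" and region.n_source_exons == 2
        assert region.region_id == "G1:100-250"
        assert region.length == 151

    def test_adjacent_exons_stay_separate(self):
        retained, _ = build_exonic_regions([_exon("G1", 100, 200), _exon("G1", 201, 300)])
        assert [(r.start, r.end, r.kind) for r in retained] == [
            (100, 200, "single"),
            (201, 300, "single"),
        ]

    def test_cross_gene_overlap_drops_both(self):
        retained, dropped = build_exonic_regions(
            [_exon("G1", 300, 400), _exon("G2", 350, 450)]
        )
        assert retained == []
        (amb,) = dropped
        assert amb.gene_ids == frozenset({"G1", "G2"})
        assert (amb.start, amb.end) == (300, 450)
        assert set(amb.members) == {("G1", 300, 400), ("G2", 350, 450)}

    def test_mixed_retained_and_dropped(self):
        retained, dropped = build_exonic_regions(
            [
                _exon("G1", 100, 200),
                _exon("G1", 150, 250),
                _exon("G1", 300, 400),
                _exon("G2", 350, 450),
            ]
        )
        assert [(r.gene_id, r.start, r.end, r.kind) for r in retained] == [
            ("G1", 100, 250, "overlap")
        ]
        (amb,) = dropped
        assert set(amb.members) == {("G1", 300, 400), ("G2", 350, 450)}

    def test_empty_input(self):
        assert build_exonic_regions([]) == ([], [])

    def test_duplicate_exon_interval_counts_once(self):
        # one exon listed per transcript: identical coordinates are one source
        retained, _ = build_exonic_regions([_exon("G1", 100, 200), _exon("G1", 100, 200)])
        (region,) = retained
        assert region.kind == "single" and region.n_source_exons == 1

    def test_multi_chromosome_gene_warns(self):
        with pytest.warns(UserWarning, match="multiple chromosomes"):
            build_exonic_regions(
                [_exon("G1", 100, 200, chrom="chr1"), _exon("G1", 100, 200, chrom="chr2")]
            )

    def test_trim_ambiguous_keeps_unshared_bases(self):
        retained, dropped = build_exonic_regions(
            [_exon("G1", 300, 400), _exon("G2", 350, 450)], trim_ambiguous=True
        )
        assert {(r.gene_id, r.start, r.end) for r in retained} == {
            ("G1", 300, 349),
            ("G2", 401, 450),
        }
        (amb,) = dropped
        assert (amb.start, amb.end) == (350, 400)


class TestOracleProperties:
    def _compare(self, exons):
        retained, dropped = build_exonic_regions(exons)
        oracle_retained, oracle_clusters = perbase_flatten(exons)
        got_retained = {
            (r.gene_id, r.chrom, r.start, r.end, r.kind, r.n_source_exons)
            for r in retained
        }
        got_clusters = {frozenset(d.members) for d in dropped}
        assert got_retained == oracle_retained
        assert got_clusters == oracle_clusters

    def test_matches_perbase_scan_on_random_annotations(self):
        from conftest import SEED, random_annotation

        rng = np.random.default_rng(SEED)
        for _ in range(60):
            self._compare(random_annotation(rng))

    def test_idempotence_on_retained_regions(self):
        from conftest import SEED, random_annotation

        rng = np.random.default_rng(SEED + 1)
        for _ in range(20):
            retained, _ = build_exonic_regions(random_annotation(rng))
            as_exons = [
                ExonRecord(r.region_id, r.gene_id, r.chrom, r.start, r.end)
                for r in retained
            ]
            again, dropped = build_exonic_regions(as_exons)
            assert dropped == []
            assert [(r.gene_id, r.start, r.end) for r in again] == [
                (r.gene_id, r.start, r.end) for r in sorted(
                    retained, key=lambda x: (x.chrom, x.start, x.end, x.gene_id)
                )
            ]

    def test_base_conservation(self):
        from conftest import SEED, random_annotation

        rng = np.random.default_rng(SEED + 2)
        for _ in range(20):
            exons = random_annotation(rng)
            retained, dropped = build_exonic_regions(exons)
            merged_total = sum(r.length for r in retained) + sum(
                e - s + 1 for d in dropped for (_, s, e) in d.members
            )
            oracle_retained, oracle_clusters = perbase_flatten(exons)
            oracle_total = sum(e - s + 1 for (_, _, s, e, _, _) in oracle_retained) + sum(
                e - s + 1 for cluster in oracle_clusters for (_, s, e) in cluster
            )
            assert merged_total == oracle_total


def test_bed_writer_converts_to_zero_based_half_open(tmp_path):
    retained, _ = build_exonic_regions([_exon("G1", 100, 200)])
    bed = tmp_path / "out.bed"
    write_regions_bed(retained, bed)
    chrom, start, end, name, score, strand = bed.read_text().strip().split("\t")
    assert (chrom, start, end, name) == ("chr1", "99", "200", "G1:100-200")
    assert int(end) - int(start) == retained[0].length


def test_summary_counts_before_and_after_exclusion():
    retained, dropped = build_exonic_regions(
        [
            _exon("G1", 100, 200),
            _exon("G1", 150, 250),
            _exon("G1", 300, 400),
            _exon("G2", 350, 450),
        ]
    )
    census = summarize_regions(retained, dropped)
    assert census["n_retained"] == 1
    assert census["n_overlap_retained"] == 1
    assert census["n_ambiguous_intervals"] == 2
    assert census["n_merged_total"] == 3


def test_ambiguous_region_requires_two_genes():
    with pytest.raises(ValueError):
        AmbiguousRegion("chr1", 1, 10, frozenset({"G1"}))
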