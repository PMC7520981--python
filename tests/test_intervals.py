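"""Interval engine: format I/O, overlap fractions, merging, nearest-gene
and feature assignment, each checked against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opente.genes import GeneModel, Transcript
from opente.intervals import (
    GenomicInterval,
    assign_feature,
    merge_intervals,
    nearest_gene,
    overlap_fractional,
    read_bed,
    total_bp,
    write_bed,
)


def random_intervals(rng, n, domain=100_000, max_len=2_000, chroms=("chr1", "chr2")):
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, domain - length))
        out.append(GenomicInterval(chrom, start, start + length, ".", f"iv{i}"))
    return out


def brute_force_pairs(queries, subjects, fq, fs):
    pairs = set()
    for q in queries:
        for s in subjects:
            ov = q.overlap_bp(s)
            if ov >= 1 and ov / len(q) >= fq and ov / len(s) >= fs:
                pairs.add((q.id, s.id))
    return pairs


class TestGenomicInterval:
    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)

    def test_rejects_negative_start(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10)

    def test_rejects_empty_chrom(self):
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)


class TestBedIO:
    def test_reads_bed3_with_default_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 0, 100, ".")

    def test_empty_interval_reports_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\nchr1\t100\t100\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)

    def test_too_few_columns_is_an_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\n")
        with pytest.raises(ValueError):
            read_bed(p)

    def test_roundtrip_500_random_intervals(self, tmp_path):
        rng = np.random.default_rng(11)
        ivs = random_intervals(rng, 500)
        # strands vary too
        ivs = [
            GenomicInterval(i.chrom, i.start, i.end, "+-."[k % 3], i.id)
            for k, i in enumerate(ivs)
        ]
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        back = read_bed(p)
        assert [(i.chrom, i.start, i.end, i.strand, i.id) for i in ivs] == [
            (i.chrom, i.start, i.end, i.strand, i.id) for i in back
        ]


class TestOverlapFractional:
    def test_joint_fractions_satisfied(self):
        q = [GenomicInterval("chr1", 100, 1100, ".", "q")]
        s = [GenomicInterval("chr1", 500, 1100, ".", "s")]
        (pair,) = overlap_fractional(q, s, 0.5, 0.2)
        assert pair.overlap_bp == 600
        assert pair.frac_query == pytest.approx(0.6)
        assert pair.frac_subject == pytest.approx(1.0)

    def test_query_fraction_too_small(self):
        q = [GenomicInterval("chr1", 0, 1000, ".", "q")]
        s = [GenomicInterval("chr1", 900, 10900, ".", "s")]
        assert overlap_fractional(q, s, 0.5, 0.2) == []

    def test_negative_fraction_is_error(self):
        with pytest.raises(ValueError):
            overlap_fractional([], [], -0.1, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        q = random_intervals(rng, 400)
        s = [
            GenomicInterval(i.chrom, i.start, i.end, ".", f"s{k}")
            for k, i in enumerate(random_intervals(rng, 400))
        ]
        fq, fs = rng.uniform(0, 0.8, size=2)
        got = {(p.query_id, p.subject_id) for p in overlap_fractional(q, s, fq, fs)}
        assert got == brute_force_pairs(q, s, fq, fs)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        q = random_intervals(rng, 100)
        s = [
            GenomicInterval(i.chrom, i.start, i.end, ".", f"s{k}")
            for k, i in enumerate(random_intervals(rng, 100))
        ]
        fwd = {(p.query_id, p.subject_id) for p in overlap_fractional(q, s, 0.4, 0.1)}
        rev = {(p.subject_id, p.query_id) for p in overlap_fractional(s, q, 0.1, 0.4)}
        assert fwd == rev

    def test_thresholded_output_is_subset_of_unthresholded(self):
        rng = np.random.default_rng(4)
        q = random_intervals(rng, 200)
        s = [
            GenomicInterval(i.chrom, i.start, i.end, ".", f"s{k}")
            for k, i in enumerate(random_intervals(rng, 200))
        ]
        loose = {(p.query_id, p.subject_id) for p in overlap_fractional(q, s, 0, 0)}
        tight = {(p.query_id, p.subject_id) for p in overlap_fractional(q, s, 0.5, 0.3)}
        assert tight <= loose


class TestMergeIntervals:
    def test_bookended_intervals_merge(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)]
        (m,) = merge_intervals(ivs)
        assert (m.start, m.end) == (0, 20)

    def test_disjoint_intervals_unchanged(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)]
        assert [(m.start, m.end) for m in merge_intervals(ivs)] == [(0, 10), (20, 30)]

    def test_covered_bp_matches_mask_oracle(self):
        rng = np.random.default_rng(5)
        ivs = random_intervals(rng, 300, domain=50_000, chroms=("chr1",))
        mask = np.zeros(50_000, dtype=bool)
        for iv in ivs:
            mask[iv.start:iv.end] = True
        assert total_bp(ivs) == int(mask.sum())

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=30))
    def test_idempotent(self, raw):
        ivs = [GenomicInterval("chr1", s, s + l) for s, l in raw]
        once = merge_intervals(ivs)
        twice = merge_intervals(once)
        assert [(m.start, m.end) for m in once] == [(m.start, m.end) for m in twice]


class TestNearestGene:
    def test_overlap_gives_distance_zero(self):
        te = GenomicInterval("chr1", 1000, 1200)
        genes = [GenomicInterval("chr1", 1100, 5000, "+", "gA")]
        assert nearest_gene(te, genes, 20_000) == "gA"

    def test_beyond_max_distance_is_none(self):
        te = GenomicInterval("chr1", 0, 100)
        genes = [GenomicInterval("chr1", 25_000, 30_000, "+", "gA")]
        assert nearest_gene(te, genes, 20_000) is None

    def test_matches_exhaustive_scan_with_leftmost_tiebreak(self):
        rng = np.random.default_rng(6)
        genes = [
            GenomicInterval(i.chrom, i.start, i.end, "+", f"g{k}")
            for k, i in enumerate(random_intervals(rng, 150))
        ]
        for te in random_intervals(rng, 150):
            def gap(g):
                if g.chrom != te.chrom:
                    return None
                if te.end <= g.start:
                    return g.start - te.end
                if g.end <= te.start:
                    return te.start - g.end
                return 0
            cands = [(gap(g), g.chrom, g.start, g.id) for g in genes if gap(g) is not None]
            cands = [c for c in cands if c[0] < 20_000]
            expected = min(cands)[3] if cands else None
            assert nearest_gene(te, genes, 20_000) == expected


def toy_gene(gene_id, chrom, strand, exon_coords, gene_type="protein_coding"):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_coords)
    return GeneModel(gene_id, gene_type, strand, (Transcript(f"{gene_id}.t0", exons, strand),))


class TestAssignFeature:
    @pytest.fixture()
    def model(self):
        # three genes, plus/minus strands, two with introns
        return [
            toy_gene("gA", "chr1", "+", [(1000, 1200), (1800, 2000)]),
            toy_gene("gB", "chr1", "-", [(5000, 5300), (6000, 6200)]),
            toy_gene("gC", "chr2", "+", [(100, 400)]),
        ]

    def test_first_exon_interval_gets_both_labels(self, model):
        (lab,) = assign_feature([GenomicInterval("chr1", 1050, 1100)], model)
        assert lab == frozenset({"first_exon", "exon"})

    def test_minus_strand_first_exon_is_3prime_most_block(self, model):
        (lab,) = assign_feature([GenomicInterval("chr1", 6050, 6100)], model)
        assert "first_exon" in lab
        (lab2,) = assign_feature([GenomicInterval("chr1", 5100, 5200)], model)
        assert lab2 == frozenset({"exon"})

    def test_between_genes_is_intergenic(self, model):
        (lab,) = assign_feature([GenomicInterval("chr1", 3000, 3200)], model)
        assert lab == frozenset({"intergenic"})

    def test_matches_per_bp_oracle_on_random_intervals(self, model):
        rng = np.random.default_rng(7)
        ivs = random_intervals(rng, 120, domain=8_000, max_len=600)
        labels = assign_feature(ivs, model)

        # per-bp oracle
        def bp_sets(chrom):
            exon = set()
            first = set()
            body = {}
            for g in model:
                for tx in g.transcripts:
                    if tx.exons[0].chrom != chrom:
                        continue
                    for e in tx.exons:
                        exon.update(range(e.start, e.end))
                    fe = (
                        max(tx.exons, key=lambda e: e.end)
                        if g.strand == "-"
                        else min(tx.exons, key=lambda e: e.start)
                    )
                    first.update(range(fe.start, fe.end))
                span = g.span
                if span.chrom == chrom:
                    body.setdefault(g.gene_id, set()).update(range(span.start, span.end))
            return exon, first, body

        cache = {c: bp_sets(c) for c in ("chr1", "chr2")}
        for iv, lab in zip(ivs, labels):
            exon, first, body = cache[iv.chrom]
            bps = set(range(iv.start, iv.end))
            expected = set()
            if bps & first:
                expected.update({"first_exon", "exon"})
            if bps & exon:
                expected.add("exon")
            gene_bp = set().union(*body.values()) if body else set()
            for g in self_introns(cache, iv.chrom):
                if bps & g:
                    expected.add("intron")
            if not (bps & gene_bp):
                expected.add("intergenic")
            assert lab == frozenset(expected), iv


def self_introns(cache, chrom):
    """Per-gene intron bp sets: gene body minus that gene's exon bp."""
    exon, _first, body = cache[chrom]
    return [bp - exon for bp in body.values()]
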