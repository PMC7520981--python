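"""Subfamily LER, feature enrichment, tissue sharing, and the
permutation overlap test."""

import math

import numpy as np
import pytest

from opente.enrichment import (
    enriched_subfamilies,
    feature_enrichment,
    open_regions_with_te_bp,
    permutation_overlap_test,
    subfamily_ler,
    tissue_sharing,
)
from opente.intervals import ChromSizes, GenomicInterval
from opente.te_annotation import TECatalog, TEInstance


def make_catalog(spec):
    """spec: {subfamily: n_copies}; copies are 1-kb TEs laid end to end."""
    instances = []
    pos = 0
    for sf in sorted(spec):
        for i in range(spec[sf]):
            iv = GenomicInterval("chr1", pos, pos + 1000, "+", f"{sf}_{i}")
            instances.append(TEInstance(iv, sf, "fam", "LTR"))
            pos += 2000
    return TECatalog(instances)


class TestSubfamilyLER:
    def test_worked_example(self):
        # copies=100, open/genome=0.01 -> expected 1; observed 8 -> LER 3
        cat = make_catalog({"X": 100})
        accessible = [f"X_{i}" for i in range(8)]
        (r,) = subfamily_ler(accessible, cat, open_te_bp=10_000, genome_bp=1_000_000)
        assert r.ler == pytest.approx(3.0)

    def test_observed_equals_expected_gives_zero(self):
        cat = make_catalog({"X": 100})
        (r,) = subfamily_ler([f"X_{i}" for i in range(1)], cat, 10_000, 1_000_000)
        assert r.ler == pytest.approx(0.0)

    def test_zero_observed_is_minus_infinity(self):
        cat = make_catalog({"X": 50})
        (r,) = subfamily_ler([], cat, 10_000, 1_000_000)
        assert r.ler == -math.inf and not r.enriched

    def test_invalid_open_bp_is_error(self):
        cat = make_catalog({"X": 5})
        with pytest.raises(ValueError):
            subfamily_ler([], cat, 0, 1_000_000)

    def test_matches_independent_count_reimplementation(self):
        rng = np.random.default_rng(2)
        cat = make_catalog({"A": 40, "B": 25, "C": 60})
        accessible = [te.te_id for te in cat if rng.random() < 0.3]
        records = {r.subfamily: r for r in subfamily_ler(accessible, cat, 50_000, 2_000_000)}
        for sf in ("A", "B", "C"):
            obs = sum(1 for t in accessible if t.startswith(sf + "_"))
            copies = len([t for t in cat if t.subfamily == sf])
            expected = copies * 50_000 / 2_000_000
            want = math.log2(obs / expected) if obs else -math.inf
            assert records[sf].observed == obs
            assert records[sf].ler == pytest.approx(want)

    def test_doubling_observed_adds_one_in_log_space(self):
        cat = make_catalog({"A": 400})
        acc1 = [f"A_{i}" for i in range(40)]
        acc2 = [f"A_{i}" for i in range(80)]
        (r1,) = subfamily_ler(acc1, cat, 50_000, 10_000_000)
        (r2,) = subfamily_ler(acc2, cat, 50_000, 10_000_000)
        assert r2.ler == pytest.approx(r1.ler + 1.0)


class TestEnrichedFilter:
    def rec(self, copies, ler):
        from opente.enrichment import LERRecord
        return LERRecord("X", "LTR", 1, copies, ler, False)

    def test_copies_boundary_is_strict(self):
        assert enriched_subfamilies([self.rec(10, 5.0)]) == []
        assert len(enriched_subfamilies([self.rec(11, 5.0)])) == 1

    def test_ler_boundary_is_strict(self):
        assert enriched_subfamilies([self.rec(200, 3.0)]) == []
        assert len(enriched_subfamilies([self.rec(200, 3.01)])) == 1


class TestFeatureEnrichment:
    def test_ratio_and_undefined_feature(self):
        from opente.genes import GeneModel, Transcript
        exon = GenomicInterval("chr1", 1000, 2000, "+")
        gene = GeneModel("g", "protein_coding", "+", (Transcript("g.t", (exon,), "+"),))
        all_tes = [GenomicInterval("chr1", 1500, 1600, ".", f"a{i}") for i in range(50)]
        all_tes += [GenomicInterval("chr1", 5000 + i * 200, 5100 + i * 200, ".", f"b{i}")
                    for i in range(10)]
        accessible = all_tes[:5]  # 5 of 50 first-exon TEs
        ratios = feature_enrichment(accessible, all_tes, [gene])
        assert ratios["first_exon"] == pytest.approx(5 / 50)
        assert ratios["intergenic"] == pytest.approx(0.0)
        assert ratios["intron"] is None  # no intron in a single-exon model

    def test_planted_first_exon_preference_on_dataset(self, dataset, catalog, gene_models):
        _, truth = dataset
        union = [catalog.by_id[t].interval for t in truth["open_union"]]
        ratios = feature_enrichment(union, catalog.intervals(), gene_models)
        assert ratios["first_exon"] > ratios["intergenic"]


class TestTissueSharing:
    def test_categories(self):
        sharing = {
            s.te_id: s
            for s in tissue_sharing(
                {"liver": {"a", "b"}, "lung": {"b"}, "intestine": {"b", "c"}},
                n_total_tissues=3,
            )
        }
        assert sharing["a"].category == "tissue_specific"
        assert sharing["b"].category == "constitutive"
        assert sharing["c"].category == "tissue_specific"

    def test_histogram_matches_matrix_oracle(self):
        rng = np.random.default_rng(3)
        tissues = ["t1", "t2", "t3", "t4", "t5"]
        matrix = rng.random((60, 5)) < 0.4
        sets = {
            t: {f"te{i}" for i in range(60) if matrix[i, j]}
            for j, t in enumerate(tissues)
        }
        sharing = tissue_sharing(sets, n_total_tissues=5)
        got = {}
        for s in sharing:
            got[s.n_tissues] = got.get(s.n_tissues, 0) + 1
        sums = matrix.sum(axis=1)
        want = {int(k): int((sums == k).sum()) for k in np.unique(sums) if k > 0}
        assert got == want
        assert len(sharing) == int((sums > 0).sum())


class TestPermutationTest:
    @pytest.fixture()
    def sizes(self):
        s = ChromSizes()
        s["chr1"] = 1_000_000
        return s

    def test_query_equals_reference_gives_minimal_p(self, sizes):
        q = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 500, ".", f"q{i}")
             for i in range(20)]
        res = permutation_overlap_test(q, q, sizes, n_perm=100, seed=0)
        assert res.observed_stat == 20
        assert res.p_enrichment <= 2 / 101

    def test_empty_reference(self, sizes):
        q = [GenomicInterval("chr1", 0, 500, ".", "q0")]
        res = permutation_overlap_test(q, [], sizes, n_perm=100, seed=0)
        assert res.observed_stat == 0
        assert res.p_enrichment == 1.0

    def test_reproducible_under_fixed_seed(self, sizes):
        rng = np.random.default_rng(4)
        q = [GenomicInterval("chr1", int(s), int(s) + 400, ".", f"q{i}")
             for i, s in enumerate(rng.integers(0, 900_000, 50))]
        r = [GenomicInterval("chr1", int(s), int(s) + 800, ".", f"r{i}")
             for i, s in enumerate(rng.integers(0, 900_000, 50))]
        a = permutation_overlap_test(q, r, sizes, n_perm=50, seed=9)
        b = permutation_overlap_test(q, r, sizes, n_perm=50, seed=9)
        assert a.null_stats == b.null_stats and a.p_enrichment == b.p_enrichment

    def test_interval_longer_than_chromosome_is_error(self, sizes):
        q = [GenomicInterval("chr1", 0, 2_000_000, ".", "q0")]
        with pytest.raises(ValueError):
            permutation_overlap_test(q, [], sizes, n_perm=10, seed=0)

    def test_p_never_zero_and_in_unit_interval(self, sizes):
        q = [GenomicInterval("chr1", i * 1000, i * 1000 + 500, ".", f"q{i}")
             for i in range(30)]
        res = permutation_overlap_test(q, q, sizes, n_perm=100, seed=1)
        assert 0 < res.p_enrichment <= 1
        assert 0 < res.p_two_sided <= 1


class TestOpenRegionsWithTE:
    def test_counts_only_peaks_containing_accessible_tes(self):
        peaks = [
            GenomicInterval("chr1", 0, 1000),
            GenomicInterval("chr1", 5000, 6000),
            GenomicInterval("chr1", 10_000, 10_500),
        ]
        tes = [GenomicInterval("chr1", 100, 300, ".", "te1")]
        assert open_regions_with_te_bp(peaks, tes) == 1000
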