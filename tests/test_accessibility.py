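"""IPKM normalization and the two-method accessible-TE caller."""

import numpy as np
import pytest

from opente.accessibility import (
    AccessibilityCall,
    InsertionTrack,
    K27Peak,
    annotate_h3k27ac,
    call_accessible,
    classify_mesc,
    compute_ipkm,
    ipkm_cutoff,
)
from opente.intervals import GenomicInterval
from opente.te_annotation import TECatalog, TEInstance


def track_from_positions(library_id, positions, chrom="chr1"):
    counts = {}
    for p in positions:
        counts[p] = counts.get(p, 0) + 1
    return InsertionTrack(library_id, {chrom: counts})


def te(te_id, chrom, start, end, subfamily="SF1"):
    return TEInstance(
        GenomicInterval(chrom, start, end, "+", te_id), subfamily, "fam", "LTR"
    )


class TestComputeIPKM:
    def test_formula_on_worked_example(self):
        # 2,000-bp region, 40 insertions, library total 2,000,000 -> 10.0
        positions = list(range(1000, 1040))
        counts = {p: 1 for p in positions}
        counts[5_000_000] = 2_000_000 - 40  # bulk of the library elsewhere
        trk = InsertionTrack("lib", {"chr1": counts})
        (v,) = compute_ipkm([GenomicInterval("chr1", 0, 2000, ".", "r")], trk)
        assert v.ipkm == pytest.approx(10.0)

    def test_zero_insertions_give_zero(self):
        trk = track_from_positions("lib", [10_000])
        (v,) = compute_ipkm([GenomicInterval("chr1", 0, 2000, ".", "r")], trk)
        assert v.ipkm == 0.0

    def test_depth_rescaling_leaves_ipkm_unchanged(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 100_000, size=500)
        t1 = InsertionTrack("a", {"chr1": {int(p): 1 for p in pos}})
        t2 = InsertionTrack("b", {"chr1": {int(p): 2 for p in pos}})
        regions = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 3_000, ".", f"r{i}")
                   for i in range(10)]
        v1 = [v.ipkm for v in compute_ipkm(regions, t1)]
        v2 = [v.ipkm for v in compute_ipkm(regions, t2)]
        assert v1 == pytest.approx(v2)

    def test_zero_library_total_is_error(self):
        trk = InsertionTrack("lib", {})
        with pytest.raises(ValueError):
            compute_ipkm([GenomicInterval("chr1", 0, 100, ".", "r")], trk)

    def test_insertion_counted_by_point_position(self):
        trk = track_from_positions("lib", [99, 100, 199, 200])
        (v,) = compute_ipkm([GenomicInterval("chr1", 100, 200, ".", "r")], trk)
        # positions 100 and 199 inside; 99 and 200 outside
        assert v.ipkm == pytest.approx(2 / 0.1 / (4 / 1e6))


class TestIpkmCutoff:
    def test_constant_list(self):
        assert ipkm_cutoff([5, 5, 5, 5], 0.25) == 5.0

    def test_linear_interpolation_between_order_statistics(self):
        # sorted [1,2,3,4,5]: q=0.25 sits at index 1 exactly -> 2.0
        assert ipkm_cutoff([5, 3, 1, 4, 2], 0.25) == pytest.approx(2.0)

    def test_cutoff_within_min_max(self):
        rng = np.random.default_rng(1)
        vals = list(rng.uniform(0, 100, size=37))
        c = ipkm_cutoff(vals, 0.25)
        assert min(vals) <= c <= max(vals)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            ipkm_cutoff([], 0.25)


class TestCaller:
    @pytest.fixture()
    def scenario(self):
        """Three TEs: one fully inside a peak, one at 30% overlap with
        dense insertions, one at 30% overlap with background insertions."""
        cat = TECatalog(
            [
                te("teA", "chr1", 1000, 2000),
                te("teB", "chr1", 10_000, 11_000),
                te("teC", "chr1", 20_000, 21_000),
            ]
        )
        peaks = [
            GenomicInterval("chr1", 900, 2100),      # covers teA
            GenomicInterval("chr1", 9_700, 10_300),  # 30% of teB
            GenomicInterval("chr1", 19_700, 20_300), # 30% of teC
            GenomicInterval("chr1", 30_000, 30_500),
            GenomicInterval("chr1", 40_000, 40_500),
        ]
        positions = []
        positions += list(range(1000, 2000, 20))       # teA dense
        positions += list(range(10_000, 11_000, 20))   # teB dense
        positions += [20_500]                          # teC nearly empty
        positions += list(range(30_000, 30_500, 50))   # modest noise peaks
        positions += list(range(40_000, 40_500, 50))
        trk = track_from_positions("t_s_rep1", positions)
        return cat, {("t", "s"): peaks}, {("t", "s"): [trk]}

    def test_full_overlap_called_by_method1(self, scenario):
        cat, peaks, tracks = scenario
        calls = {c.te_id: c for c in call_accessible(cat, peaks, tracks)}
        assert calls["teA"].called
        assert calls["teA"].method in ("overlap", "both")

    def test_partial_overlap_with_dense_insertions_rescued_by_ipkm(self, scenario):
        cat, peaks, tracks = scenario
        calls = {c.te_id: c for c in call_accessible(cat, peaks, tracks)}
        assert calls["teB"].called
        assert calls["teB"].method == "ipkm"

    def test_partial_overlap_without_signal_stays_closed(self, scenario):
        cat, peaks, tracks = scenario
        calls = {c.te_id: c for c in call_accessible(cat, peaks, tracks)}
        assert not calls["teC"].called
        assert calls["teC"].method == "none"

    def test_called_flag_consistent_with_method(self, scenario):
        cat, peaks, tracks = scenario
        for c in call_accessible(cat, peaks, tracks):
            assert c.called == (c.method != "none")

    def test_method2_disabled_loses_the_rescue(self, scenario):
        cat, peaks, tracks = scenario
        calls = {c.te_id: c for c in call_accessible(cat, peaks, tracks, use_method2=False)}
        assert calls["teA"].called
        assert not calls["teB"].called

    def test_missing_track_for_library_is_error(self, scenario):
        cat, peaks, _ = scenario
        with pytest.raises(ValueError, match="track"):
            call_accessible(cat, peaks, {})

    def test_depth_rescaling_leaves_calls_unchanged(self, scenario):
        cat, peaks, tracks = scenario
        trk = tracks[("t", "s")][0]
        doubled = InsertionTrack(
            "t_s_rep1",
            {"chr1": {int(p): 2 for p in trk._pos["chr1"]}},
        )
        base = [(c.te_id, c.called, c.method) for c in call_accessible(cat, peaks, tracks)]
        scaled = [
            (c.te_id, c.called, c.method)
            for c in call_accessible(cat, peaks, {("t", "s"): [doubled]})
        ]
        assert base == scaled


class TestAnnotations:
    def test_h3k27ac_cpm_filter_and_union(self):
        cat = TECatalog([te("teA", "chr1", 1000, 2000), te("teB", "chr1", 5000, 6000)])
        calls = [
            AccessibilityCall("teA", "t", "s", True, "overlap"),
            AccessibilityCall("teB", "t", "s", True, "overlap"),
        ]
        k27 = [
            K27Peak(GenomicInterval("chr1", 900, 1100), 600, 2_000_000),   # CPM 300
            K27Peak(GenomicInterval("chr1", 5000, 5100), 4, 2_000_000),    # CPM 2, dropped
        ]
        annotate_h3k27ac(calls, k27, cat)
        assert calls[0].h3k27ac and not calls[1].h3k27ac

    def test_h3k27ac_union_from_five_peak_fixture(self):
        # 5 peaks, 2 below CPM threshold; union covers teA and teC only
        cat = TECatalog(
            [te("teA", "chr1", 100, 400), te("teB", "chr1", 1000, 1300),
             te("teC", "chr1", 2000, 2300)]
        )
        calls = [AccessibilityCall(t, "t", "s", True, "overlap") for t in ("teA", "teB", "teC")]
        total = 1_000_000
        k27 = [
            K27Peak(GenomicInterval("chr1", 90, 200), 10, total),    # CPM 10
            K27Peak(GenomicInterval("chr1", 150, 350), 50, total),   # CPM 50
            K27Peak(GenomicInterval("chr1", 1000, 1200), 2, total),  # CPM 2
            K27Peak(GenomicInterval("chr1", 1250, 1350), 3, total),  # CPM 3 (not > 3)
            K27Peak(GenomicInterval("chr1", 2100, 2200), 8, total),  # CPM 8
        ]
        annotate_h3k27ac(calls, k27, cat)
        assert [c.h3k27ac for c in calls] == [True, False, True]

    def test_mesc_overlap_flag(self):
        cat = TECatalog([te("teA", "chr1", 1000, 2000), te("teB", "chr2", 1000, 2000)])
        calls = [
            AccessibilityCall("teA", "t", "s", True, "overlap"),
            AccessibilityCall("teB", "t", "s", True, "overlap"),
        ]
        classify_mesc(calls, [GenomicInterval("chr1", 1500, 1600)], cat)
        assert calls[0].open_in_mesc and not calls[1].open_in_mesc


class TestCallerOnSyntheticData:
    def test_every_ipkm_call_exceeds_a_library_cutoff(self, calls, catalog, peaks_and_tracks):
        from opente.intervals import merge_intervals
        peaks, tracks = peaks_and_tracks
        checked = 0
        for c in calls:
            if c.method != "ipkm":
                continue
            merged = merge_intervals(peaks[(c.tissue, c.stage)])
            for i, p in enumerate(merged):
                merged[i] = GenomicInterval(p.chrom, p.start, p.end, ".", f"p{i}")
            ok = False
            for trk in tracks[(c.tissue, c.stage)]:
                cutoff = ipkm_cutoff(compute_ipkm(merged, trk))
                if c.ipkm.get(trk.library_id, 0) > cutoff:
                    ok = True
            assert ok, c
            checked += 1
            if checked >= 25:  # spot-check is enough
                break
        assert checked > 0

    def test_union_recall_at_least_each_method(self, dataset, calls, catalog, peaks_and_tracks):
        _, truth = dataset
        peaks, tracks = peaks_and_tracks
        truth_triples = {
            (t, tis, st)
            for tis, d in truth["open"].items()
            for st, ids in d.items()
            for t in ids
        }
        union_called = {(c.te_id, c.tissue, c.stage) for c in calls if c.called}
        m1 = call_accessible(catalog, peaks, tracks, use_method2=False)
        m1_called = {(c.te_id, c.tissue, c.stage) for c in m1 if c.called}
        recall = len(union_called & truth_triples) / len(truth_triples)
        recall_m1 = len(m1_called & truth_triples) / len(truth_triples)
        assert recall >= recall_m1
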