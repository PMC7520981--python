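"""The two-method accessible-TE caller with IPKM normalization.

Method 1 calls a TE accessible when it overlaps an open-chromatin peak
with at least 50% of the TE and at least 20% of the peak covered by the
same intersection.  Method 2 rescues TEs that touch a peak but fail the
fractions: their Tn5 insertion density (IPKM — insertions per kilobase
per million library insertions) must exceed the 25%-quantile IPKM of the
peaks in at least one replicate library.  The accessible set is the
union of both methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, merge_intervals, overlap_fractional
from .te_annotation import TECatalog


class InsertionTrack:
    """Sparse per-base Tn5 insertion counts for one library.

    An insertion at position p lies in region [start, end) iff
    start <= p < end; insertions are points, not fragment spans.
    """

    def __init__(self, library_id: str, counts_by_chrom: dict[str, dict[int, int]]):
        self.library_id = library_id
        self._pos: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}
        total = 0
        for chrom, counts in counts_by_chrom.items():
            if not counts:
                continue
            pos = np.array(sorted(counts), dtype=np.int64)
            c = np.array([counts[p] for p in pos], dtype=np.int64)
            if (c < 0).any():
                raise ValueError("insertion counts must be >= 0")
            self._pos[chrom] = pos
            self._cum[chrom] = np.concatenate(([0], np.cumsum(c)))
            total += int(c.sum())
        self.library_total = total

    def count(self, region: GenomicInterval) -> int:
        """Insertions whose position lies in the region."""
        pos = self._pos.get(region.chrom)
        if pos is None:
            return 0
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        cum = self._cum[region.chrom]
        return int(cum[hi] - cum[lo])

    @classmethod
    def from_file(cls, path, library_id: str) -> "InsertionTrack":
        """Read a (chrom, pos, count) tab file."""
        counts: dict[str, dict[int, int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected chrom, pos, count")
                chrom, pos, n = fields[0], int(fields[1]), int(fields[2])
                counts.setdefault(chrom, {})[pos] = counts.get(chrom, {}).get(pos, 0) + n
        return cls(library_id, counts)


@dataclass(frozen=True)
class IPKMValue:
    region_id: str
    ipkm: float


@dataclass
class AccessibilityCall:
    te_id: str
    tissue: str
    stage: str
    called: bool
    method: str  # overlap | ipkm | both | none
    ipkm: dict = field(default_factory=dict)  # library_id -> IPKM
    h3k27ac: bool = False
    open_in_mesc: bool = False

    @property
    def max_ipkm(self) -> float:
        return max(self.ipkm.values()) if self.ipkm else 0.0


def compute_ipkm(regions, track: InsertionTrack) -> list[IPKMValue]:
    """IPKM = insertions / (length/1000) / (library_total/1e6).

    Scale-invariant: doubling every count (and hence the library total)
    leaves every value unchanged.
    """
    if track.library_total == 0:
        raise ValueError(f"library {track.library_id} has zero total insertions")
    millions = track.library_total / 1e6
    out = []
    for r in regions:
        kb = len(r) / 1000.0
        out.append(IPKMValue(r.id, track.count(r) / kb / millions))
    return out


def ipkm_cutoff(peak_ipkms, quantile: float = 0.25) -> float:
    """q-th quantile of peak IPKMs, linear interpolation between order
    statistics (numpy default)."""
    values = [v.ipkm if isinstance(v, IPKMValue) else float(v) for v in peak_ipkms]
    if not values:
        raise ValueError("cannot take a quantile of an empty IPKM list")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(values, quantile))


def call_accessible(
    tes: TECatalog,
    peaks_by_library: dict,
    tracks_by_library: dict,
    min_frac_te: float = 0.5,
    min_frac_peak: float = 0.2,
    quantile: float = 0.25,
    use_method2: bool = True,
) -> list[AccessibilityCall]:
    """Call accessible TEs per (tissue, stage).

    ``peaks_by_library`` maps (tissue, stage) -> replicate-merged peak
    intervals; ``tracks_by_library`` maps (tissue, stage) -> list of
    per-replicate InsertionTracks.  Returns one call per TE that touches
    a peak in that tissue/stage (called or not); TEs touching no peak
    are omitted (trivially closed).
    """
    for key in peaks_by_library:
        if use_method2 and key not in tracks_by_library:
            raise ValueError(f"no insertion tracks for declared library {key}")

    te_intervals = tes.intervals()
    calls: list[AccessibilityCall] = []
    for (tissue, stage), peaks in sorted(peaks_by_library.items()):
        peaks = merge_intervals(peaks)
        for i, p in enumerate(peaks):
            peaks[i] = GenomicInterval(p.chrom, p.start, p.end, ".", f"peak{i}")
        # method 1: joint-fraction overlap
        strict = overlap_fractional(te_intervals, peaks, min_frac_te, min_frac_peak)
        method1 = {pr.query_id for pr in strict}
        # any touch at all (candidates for method 2)
        touched = {pr.query_id for pr in overlap_fractional(te_intervals, peaks, 0.0, 0.0)}
        remaining = sorted(touched - method1)

        lib_calls: dict[str, AccessibilityCall] = {}
        for te_id in sorted(touched):
            lib_calls[te_id] = AccessibilityCall(
                te_id, tissue, stage, te_id in method1,
                "overlap" if te_id in method1 else "none",
            )

        if use_method2 and tracks_by_library.get((tissue, stage)):
            rem_ivs = [tes.by_id[t].interval for t in remaining]
            m1_ivs = [tes.by_id[t].interval for t in sorted(method1)]
            for track in tracks_by_library[(tissue, stage)]:
                cutoff = ipkm_cutoff(compute_ipkm(peaks, track), quantile)
                for iv, val in zip(rem_ivs, compute_ipkm(rem_ivs, track)):
                    call = lib_calls[iv.id]
                    call.ipkm[track.library_id] = val.ipkm
                    if val.ipkm > cutoff:
                        call.called = True
                        call.method = "ipkm"
                for iv, val in zip(m1_ivs, compute_ipkm(m1_ivs, track)):
                    call = lib_calls[iv.id]
                    call.ipkm[track.library_id] = val.ipkm
                    if val.ipkm > cutoff:
                        call.method = "both"
        calls.extend(lib_calls.values())
    return calls


def accessible_ids(calls, tissue: str | None = None, stage: str | None = None) -> set[str]:
    """TE ids called accessible, optionally restricted to a tissue/stage."""
    return {
        c.te_id
        for c in calls
        if c.called
        and (tissue is None or c.tissue == tissue)
        and (stage is None or c.stage == stage)
    }


@dataclass(frozen=True)
class K27Peak:
    interval: GenomicInterval
    fragment_count: int
    library_total: int


def annotate_h3k27ac(calls, k27_peaks, te_catalog: TECatalog, min_cpm: float = 3.0):
    """Set ``h3k27ac`` on calls whose TE overlaps the high-confidence
    H3K27ac union set (peaks with fragment CPM > ``min_cpm``, merged)."""
    confident = [
        p.interval
        for p in k27_peaks
        if p.fragment_count * 1e6 / p.library_total > min_cpm
    ]
    union = merge_intervals(confident) if confident else []
    for c in calls:
        te = te_catalog.by_id[c.te_id].interval
        c.h3k27ac = any(te.overlap_bp(u) >= 1 for u in union)
    return calls


def classify_mesc(calls, esc_peaks, te_catalog: TECatalog):
    """Set ``open_in_mesc``: >=1 bp overlap with any mESC OCR peak."""
    merged = merge_intervals(esc_peaks) if esc_peaks else []
    for c in calls:
        te = te_catalog.by_id[c.te_id].interval
        c.open_in_mesc = any(te.overlap_bp(u) >= 1 for u in merged)
    return calls


def write_calls(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("te_id\ttissue\tstage\tcalled\tmethod\tmax_ipkm\th3k27ac\topen_in_mesc\n")
        for c in sorted(calls, key=lambda c: (c.tissue, c.stage, c.te_id)):
            fh.write(
                f"{c.te_id}\t{c.tissue}\t{c.stage}\t{int(c.called)}\t{c.method}\t"
                f"{c.max_ipkm:.6g}\t{int(c.h3k27ac)}\t{int(c.open_in_mesc)}\n"
            )
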