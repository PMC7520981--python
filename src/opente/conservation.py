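"""Evolutionary conservation: alignment-column scores, phastCons-style
meta-profiles around intervals, and orthology bookkeeping.

The alignment column score is the frequency of the most common
nucleotide among the A/T/C/G characters in the column; gaps and N are
excluded from both numerator and denominator.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .intervals import ChromSizes, GenomicInterval

NUCLEOTIDES = frozenset("ACGT")

ORTHOLOGY_CATEGORIES = ("shared_all", "rodent_specific", "mouse_specific", "human_only_anomaly")


@dataclass(frozen=True)
class AlignmentBlock:
    """Equal-length aligned sequences over {A,C,G,T,N,-}."""

    sequences: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs >= 2 rows")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("ragged alignment block: unequal row lengths")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path) -> "AlignmentBlock":
        labels, seqs, cur = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if cur:
                        seqs.append("".join(cur))
                        cur = []
                    labels.append(line[1:].split()[0])
                elif line:
                    cur.append(line.upper())
        if cur:
            seqs.append("".join(cur))
        return cls(tuple(seqs), tuple(labels))


def column_conservation(block: AlignmentBlock) -> list[float | None]:
    """Per-column score: max nucleotide count / counted nucleotides.

    Columns with no A/T/C/G at all are None (missing).  Bounded in
    (0, 1]; equals 1 iff all counted bases are identical.
    """
    scores: list[float | None] = []
    for i in range(block.n_columns):
        counts = Counter(
            s[i] for s in block.sequences if s[i] in NUCLEOTIDES
        )
        if not counts:
            scores.append(None)
        else:
            scores.append(max(counts.values()) / sum(counts.values()))
    return scores


class ScoreTrack:
    """Per-chromosome runs of (start, end, value), values in [0, 1]."""

    def __init__(self, runs_by_chrom: dict[str, list[tuple[int, int, float]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, runs in runs_by_chrom.items():
            runs = sorted(runs)
            starts = np.array([r[0] for r in runs], dtype=np.int64)
            ends = np.array([r[1] for r in runs], dtype=np.int64)
            values = np.array([r[2] for r in runs], dtype=float)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping score runs on {chrom}")
            if ((values < 0) | (values > 1)).any():
                raise ValueError("score values must be in [0, 1]")
            self._starts[chrom], self._ends[chrom], self._values[chrom] = starts, ends, values

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        runs: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split("\t")[:4]
                runs.setdefault(chrom, []).append((int(start), int(end), float(value)))
        return cls(runs)

    def window_sums(self, chrom: str, start: int, end: int) -> tuple[float, int]:
        """(sum of per-base scores, covered bases) over [start, end)."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0.0, 0
        ends, values = self._ends[chrom], self._values[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0, 0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        widths = np.maximum(e - s, 0)
        return float((widths * values[lo:hi]).sum()), int(widths.sum())


def phastcons_profile(
    regions,
    track: ScoreTrack,
    chrom_sizes: ChromSizes,
    flank: int = 5_000,
    bin_size: int = 100,
) -> list[float | None]:
    """Mean conservation per bin over windows centered on the regions.

    Each region contributes a (2*flank)-bp window centered on
    floor((start+end)/2), split into ``bin_size``-bp bins; the per-bin
    mean over covered bases is averaged across regions, with uncovered
    bins treated as missing rather than zero.  Windows running past a
    chromosome end are skipped with a warning.
    """
    n_bins = 2 * flank // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for r in regions:
        center = (r.start + r.end) // 2
        w_start = center - flank
        w_end = center + flank
        if w_start < 0 or w_end > chrom_sizes[r.chrom]:
            warnings.warn(
                f"window for {r.chrom}:{r.start}-{r.end} extends past the chromosome; skipped"
            )
            continue
        for b in range(n_bins):
            total, covered = track.window_sums(
                r.chrom, w_start + b * bin_size, w_start + (b + 1) * bin_size
            )
            if covered:
                sums[b] += total / covered
                counts[b] += 1
    return [sums[b] / counts[b] if counts[b] else None for b in range(n_bins)]


def sample_regions(regions, n: int, seed: int):
    """Seeded sample (without replacement) of regions for profiling."""
    rng = np.random.default_rng(seed)
    if len(regions) <= n:
        return list(regions)
    idx = rng.choice(len(regions), size=n, replace=False)
    return [regions[i] for i in sorted(idx)]


@dataclass(frozen=True)
class OrthologyCall:
    region_id: str
    in_rat: bool
    in_human: bool
    category: str


def classify_orthology(flags) -> list[OrthologyCall]:
    """Categorize regions from liftOver-style mapping flags:
    rat only -> rodent_specific; rat and human -> shared_all; neither ->
    mouse_specific; human only -> human_only_anomaly."""
    out = []
    for region_id, in_rat, in_human in flags:
        if in_rat and in_human:
            cat = "shared_all"
        elif in_rat:
            cat = "rodent_specific"
        elif in_human:
            cat = "human_only_anomaly"
        else:
            cat = "mouse_specific"
        out.append(OrthologyCall(region_id, bool(in_rat), bool(in_human), cat))
    return out


def read_orthology_flags(path):
    """Read (region_id, in_rat, in_human) tab table with header."""
    flags = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            flags.append((fields[0], fields[1] in ("1", "True"), fields[2] in ("1", "True")))
    return flags


def project_coords_through_alignment(
    block: AlignmentBlock,
    src_label: str,
    dst_label: str,
    positions,
) -> list[int | None]:
    """Map ungapped sequence positions of one alignment row onto another.

    A source position maps to the count of non-gap characters of the
    destination row up to (and excluding) that column; positions landing
    on a destination gap return None.
    """
    src = block.sequences[block.labels.index(src_label)]
    dst = block.sequences[block.labels.index(dst_label)]
    # column index for each ungapped src position
    src_cols = [i for i, c in enumerate(src) if c != "-"]
    dst_pos = np.cumsum([c != "-" for c in dst]) - 1  # dst coord at each column
    out: list[int | None] = []
    for p in positions:
        if p < 0 or p >= len(src_cols):
            out.append(None)
            continue
        col = src_cols[p]
        out.append(int(dst_pos[col]) if dst[col] != "-" else None)
    return out
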