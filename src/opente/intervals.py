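"""Genomic interval model, standard-format I/O, and overlap primitives.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  GTF input (1-based, inclusive) is converted on read.
Strand is ignored by the overlap operations, matching the bedtools
defaults the rest of the package assumes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Length of the intersection with ``other`` (0 if disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class OverlapPair:
    """One query/subject intersection with both overlap fractions."""

    query_id: str
    subject_id: str
    overlap_bp: int
    frac_query: float
    frac_subject: float


class ChromSizes(dict):
    """Chromosome name -> length (bp).  All lengths must be positive."""

    def __setitem__(self, key: str, value: int) -> None:
        if value <= 0:
            raise ValueError(f"chromosome length must be > 0, got {value} for {key}")
        super().__setitem__(key, int(value))

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        sizes = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                name, length = line.split("\t")[:2]
                sizes[name] = int(length)
        return sizes

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.items():
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 (extra columns ignored beyond strand).

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or '.'}\t0\t{iv.strand}\n")


def read_narrowpeak(path) -> list[GenomicInterval]:
    """narrowPeak is BED6+4; the extra stat columns are not needed here."""
    return read_bed(path)


# ---------------------------------------------------------------------------
# Overlap primitives
# ---------------------------------------------------------------------------

def _tree_by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, iv in enumerate(intervals):
        trees[iv.chrom].addi(iv.start, iv.end, i)
    return trees


def overlap_fractional(
    queries: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
    min_frac_query: float = 0.0,
    min_frac_subject: float = 0.0,
) -> list[OverlapPair]:
    """All query/subject pairs whose intersection satisfies BOTH fraction
    thresholds simultaneously (bedtools joint ``-f``/``-F`` semantics).

    Thresholds are inclusive ("at least"); an overlap of >=1 bp is always
    required.  A query may appear in several pairs.
    """
    if min_frac_query < 0 or min_frac_subject < 0:
        raise ValueError("overlap fractions must be non-negative")
    trees = _tree_by_chrom(subjects)
    pairs: list[OverlapPair] = []
    for q in queries:
        tree = trees.get(q.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(q.start, q.end), key=lambda h: (h.begin, h.data)):
            s = subjects[hit.data]
            ov = min(q.end, s.end) - max(q.start, s.start)
            if ov < 1:
                continue
            fq = ov / len(q)
            fs = ov / len(s)
            if fq >= min_frac_query and fs >= min_frac_subject:
                pairs.append(OverlapPair(q.id, s.id, ov, fq, fs))
    return pairs


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals (bedtools mergeBed, -d 0).

    Output is sorted by (chrom, start) and strand/name information is
    dropped (merged records get strand ".").
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def _gap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Gap between closest edges; 0 when overlapping or book-ended."""
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def nearest_gene(
    te: GenomicInterval,
    genes: Sequence,
    max_distance: int = 20_000,
):
    """Nearest gene (by body span) within ``max_distance`` bp, or ``None``.

    ``genes`` may be GenomicIntervals or objects with a ``.span`` interval
    and ``.gene_id``.  Distance is the gap in bp between closest edges
    (0 when overlapping); the bound is strict (``distance < max_distance``).
    Ties break by (chrom, start, gene id).
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    best = None
    best_key = None
    for g in genes:
        span = g if isinstance(g, GenomicInterval) else g.span
        gid = span.id if isinstance(g, GenomicInterval) else g.gene_id
        if span.chrom != te.chrom:
            continue
        d = _gap_bp(te, span)
        if d >= max_distance:
            continue
        key = (d, span.chrom, span.start, gid)
        if best_key is None or key < best_key:
            best, best_key = gid, key
    return best


def assign_feature(
    intervals: Sequence[GenomicInterval],
    gene_model: Sequence,
) -> list[frozenset]:
    """Label each interval with every genomic feature class it overlaps.

    Classes: ``first_exon`` (strand-aware 5'-most exon of a transcript,
    which also counts as ``exon``), ``exon``, ``intron`` (inside a gene
    body but outside that gene's exons), and ``intergenic`` (no gene-body
    overlap at all).  A >=1 bp overlap suffices for each label.
    """
    exons: list[GenomicInterval] = []
    first_exons: list[GenomicInterval] = []
    bodies: list[GenomicInterval] = []
    introns: list[GenomicInterval] = []
    for gene in gene_model:
        gene_exons: list[GenomicInterval] = []
        for tx in gene.transcripts:
            gene_exons.extend(tx.exons)
            if gene.strand == "-":
                fe = max(tx.exons, key=lambda e: e.end)
            else:
                fe = min(tx.exons, key=lambda e: e.start)
            first_exons.append(fe)
        exons.extend(gene_exons)
        body = gene.span
        bodies.append(body)
        # intron = gene body minus union of this gene's exons
        covered = merge_intervals(gene_exons)
        pos = body.start
        for ex in covered:
            if ex.start > pos:
                introns.append(GenomicInterval(body.chrom, pos, ex.start))
            pos = max(pos, ex.end)
        if pos < body.end:
            introns.append(GenomicInterval(body.chrom, pos, body.end))

    exon_t = _tree_by_chrom(exons)
    first_t = _tree_by_chrom(first_exons)
    body_t = _tree_by_chrom(bodies)
    intron_t = _tree_by_chrom(introns)

    def hits(trees, iv):
        tree = trees.get(iv.chrom)
        return bool(tree) and bool(tree.overlap(iv.start, iv.end))

    labels = []
    for iv in intervals:
        lab = set()
        if hits(first_t, iv):
            lab.update(("first_exon", "exon"))
        if hits(exon_t, iv):
            lab.add("exon")
        if hits(intron_t, iv):
            lab.add("intron")
        if not hits(body_t, iv):
            lab.add("intergenic")
        labels.append(frozenset(lab))
    return labels


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total covered bp after merging."""
    return sum(len(iv) for iv in merge_intervals(intervals))
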