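"""Gene/transcript models and a GTF-lite reader.

A transcript's TSS is its 5'-most coordinate in BED space: ``start`` for
a + strand transcript and ``end`` for a - strand transcript (the
half-open end, one past the last transcribed base).  Every promoter and
TSS-containment computation in the package uses this single convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .intervals import ChromSizes, GenomicInterval

GENE_TYPES = ("protein_coding", "lincRNA", "antisense", "other")


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    strand: str

    @property
    def tss(self) -> int:
        """5'-most coordinate: min exon start (+) or max exon end (-)."""
        if self.strand == "-":
            return max(e.end for e in self.exons)
        return min(e.start for e in self.exons)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_type: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def span(self) -> GenomicInterval:
        chrom = self.transcripts[0].exons[0].chrom
        start = min(e.start for t in self.transcripts for e in t.exons)
        end = max(e.end for t in self.transcripts for e in t.exons)
        return GenomicInterval(chrom, start, end, self.strand, self.gene_id)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].exons[0].chrom


def furthest_5prime_tss(gene: GeneModel) -> int:
    """The furthest-5' TSS across all transcripts of a gene.

    min of transcript TSSs on +, max on -.  A gene with zero transcripts
    is an error.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id} has no transcripts")
    positions = [t.tss for t in gene.transcripts]
    return max(positions) if gene.strand == "-" else min(positions)


def tss_point_interval(tss: int, strand: str, chrom: str, id: str = "") -> GenomicInterval:
    """1-bp interval covering the TSS base itself."""
    if strand == "-":
        return GenomicInterval(chrom, tss - 1, tss, strand, id)
    return GenomicInterval(chrom, tss, tss + 1, strand, id)


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _normalize_gene_type(raw: str) -> str:
    return raw if raw in GENE_TYPES else "other"


def read_gtf(path) -> list[GeneModel]:
    """Read a GTF-lite file (exon features with gene_id/transcript_id).

    GTF 1-based inclusive coordinates are converted to 0-based half-open.
    Gene type comes from a ``gene_type`` attribute (default "other").
    """
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, gene_type, strand)
    gene_order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            seqname, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            a = dict(_ATTR_RE.findall(attrs))
            try:
                gid, tid = a["gene_id"], a["transcript_id"]
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: missing gene_id/transcript_id") from exc
            iv = GenomicInterval(seqname, int(start) - 1, int(end), strand, tid)
            if tid not in tx_exons:
                tx_exons[tid] = []
                tx_meta[tid] = (gid, _normalize_gene_type(a.get("gene_type", "other")), strand)
                if gid not in gene_order:
                    gene_order.append(gid)
            tx_exons[tid].append(iv)

    genes: dict[str, list[Transcript]] = {g: [] for g in gene_order}
    gtype: dict[str, str] = {}
    gstrand: dict[str, str] = {}
    for tid, exons in tx_exons.items():
        gid, typ, strand = tx_meta[tid]
        genes[gid].append(Transcript(tid, tuple(sorted(exons, key=lambda e: e.start)), strand))
        gtype[gid] = typ
        gstrand[gid] = strand
    return [
        GeneModel(gid, gtype[gid], gstrand[gid], tuple(genes[gid]))
        for gid in gene_order
    ]


def write_gtf(genes, path) -> None:
    """Write GeneModels back out as GTF-lite exon records."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for ex in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'gene_type "{gene.gene_type}";'
                    )
                    fh.write(
                        f"{ex.chrom}\topente\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )
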