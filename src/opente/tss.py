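"""TE-derived transcription start sites.

A TE "derives" a gene's TSS when the gene's furthest-5' TSS (across all
of its transcripts) falls inside an accessible TE — making the TE part
of the gene's promoter/first exon.  CAGE peaks provide independent
experimental validation of such TSSs via a 1-bp overlap rule.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .accessibility import AccessibilityCall
from .genes import GeneModel, furthest_5prime_tss
from .intervals import ChromSizes, GenomicInterval, overlap_fractional
from .te_annotation import TECatalog


@dataclass
class TETSSRecord:
    te_id: str
    subfamily: str
    gene_id: str
    gene_type: str
    tss_position: int
    tissues_accessible: frozenset
    cage_validated: bool = False


def promoter_regions(genes, chrom_sizes: ChromSizes | None = None, upstream: int = 500):
    """500-bp (by default) promoter upstream of each gene's furthest-5'
    TSS: [t-500, t) on +, [t, t+500) on -, clipped to the chromosome."""
    out = []
    for gene in genes:
        t = furthest_5prime_tss(gene)
        chrom = gene.chrom
        limit = chrom_sizes.get(chrom) if chrom_sizes else None
        if gene.strand == "-":
            start, end = t, t + upstream
        else:
            start, end = t - upstream, t
        start = max(0, start)
        if limit is not None:
            end = min(end, limit)
        if end > start:
            out.append(GenomicInterval(chrom, start, end, gene.strand, gene.gene_id))
    return out


def detect_te_tss(accessible_calls, genes, te_catalog: TECatalog) -> list[TETSSRecord]:
    """One record per (TE, gene) pair where the gene's furthest-5' TSS
    lies inside an accessible TE.  Records carry the tissues in which
    the TE is accessible; pairs are deduplicated, with no arbitration
    when one TE hosts the TSSs of several genes.
    """
    tissues_by_te: dict[str, set] = defaultdict(set)
    for c in accessible_calls:
        if isinstance(c, AccessibilityCall):
            if c.called:
                tissues_by_te[c.te_id].add(c.tissue)
        else:  # bare te_id (truth-set mode)
            tissues_by_te[c]
    acc_ids = sorted(tissues_by_te)

    by_chrom: dict[str, list] = defaultdict(list)
    for te_id in acc_ids:
        te = te_catalog.by_id.get(te_id)
        if te is not None:
            by_chrom[te.interval.chrom].append(te)

    records = []
    for gene in genes:
        t = furthest_5prime_tss(gene)
        for te in by_chrom.get(gene.chrom, ()):
            if te.interval.start <= t < te.interval.end:
                records.append(
                    TETSSRecord(
                        te.te_id,
                        te.subfamily,
                        gene.gene_id,
                        gene.gene_type,
                        t,
                        frozenset(tissues_by_te[te.te_id]),
                    )
                )
    records.sort(key=lambda r: (r.te_id, r.gene_id))
    return records


def promoter_te_fraction(
    accessible_te_intervals,
    genes,
    chrom_sizes: ChromSizes | None = None,
    upstream: int = 500,
) -> tuple[float, float]:
    """(fraction of accessible TEs overlapping a promoter by >=1 bp,
    fraction containing a gene's furthest-5' TSS)."""
    n = len(accessible_te_intervals)
    if n == 0:
        return (0.0, 0.0)
    promoters = promoter_regions(genes, chrom_sizes, upstream)
    in_promoter = {
        pr.query_id
        for pr in overlap_fractional(accessible_te_intervals, promoters, 0.0, 0.0)
    }
    tss_points = [
        (gene.chrom, furthest_5prime_tss(gene)) for gene in genes
    ]
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, t in tss_points:
        by_chrom[chrom].append(t)
    contains = sum(
        1
        for iv in accessible_te_intervals
        if any(iv.start <= t < iv.end for t in by_chrom.get(iv.chrom, ()))
    )
    return (len(in_promoter) / n, contains / n)


def cage_validate(records, cage_peaks, te_catalog: TECatalog):
    """Set ``cage_validated``: >=1 bp overlap between the hosting TE and
    any CAGE peak."""
    for r in records:
        te = te_catalog.by_id[r.te_id].interval
        r.cage_validated = any(te.overlap_bp(p) >= 1 for p in cage_peaks)
    return records


def write_te_tss_table(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("te_id\tsubfamily\tgene_id\tgene_type\ttss\ttissues\tcage_validated\n")
        for r in records:
            tissues = ",".join(sorted(r.tissues_accessible)) or "."
            fh.write(
                f"{r.te_id}\t{r.subfamily}\t{r.gene_id}\t{r.gene_type}\t"
                f"{r.tss_position}\t{tissues}\t{int(r.cage_validated)}\n"
            )
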