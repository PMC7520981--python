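"""Promoter usage: how much of a gene's expression initiates from
TE-derived versus canonical TSSs.

Two independent estimates are implemented: one from transcript-level
expression (FPKM) with transcripts labelled by whether their own TSS
lies inside an accessible TE, and one from CAGE peak expression
assigned to TE-derived or non-TE TSSs by 1-bp overlap.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .genes import GeneModel, tss_point_interval
from .intervals import GenomicInterval

USAGE_CATEGORIES = ("te_only", "non_te_only", "both", "not_expressed")


@dataclass(frozen=True)
class CagePeak:
    interval: GenomicInterval
    expression: dict  # stage -> expression level

    @property
    def peak_id(self) -> str:
        return self.interval.id


def read_cage_table(path) -> list[CagePeak]:
    """Read the CAGE dialect: chrom, start, end, id, then one expression
    column per stage (stage names in the header)."""
    peaks = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        stages = header[4:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), ".", fields[3])
            expr = {s: float(v) for s, v in zip(stages, fields[4:])}
            peaks.append(CagePeak(iv, expr))
    return peaks


@dataclass
class UsageClass:
    gene_id: str
    category: str
    contribution: dict = field(default_factory=dict)  # (tissue, stage) -> fraction


def _mean_over_replicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Average FPKM across replicates per transcript/tissue/stage."""
    keys = ["transcript_id", "gene_id", "tissue", "stage"]
    extra = [c for c in ("tss_is_te",) if c in expr.columns]
    return expr.groupby(keys + extra, as_index=False)["fpkm"].mean()


def classify_tss_usage(
    expr: pd.DataFrame,
    min_mean_fpkm: float = 0.1,
) -> list[UsageClass]:
    """Classify TSS usage per gene from a transcript expression table
    with columns transcript_id, gene_id, tissue, stage, replicate, fpkm,
    tss_is_te.

    A gene is expressed when its replicate-mean total FPKM exceeds
    ``min_mean_fpkm`` in at least one tissue/stage.  Across the
    tissue/stages where it is expressed, a gene whose expressed
    transcripts (fpkm > 0) are all TE-TSS is ``te_only``; none ->
    ``non_te_only``; a mix -> ``both``.  Contributions (TE-TSS share of
    gene FPKM) are attached per tissue/stage where total FPKM > 0.
    """
    if expr.empty:
        return []
    mean = _mean_over_replicates(expr)
    out = []
    for gid, g in mean.groupby("gene_id"):
        if g.empty:
            raise ValueError(f"gene {gid} has zero transcripts")
        totals = g.groupby(["tissue", "stage"])["fpkm"].sum()
        expressed_ts = totals[totals > min_mean_fpkm]
        uc = UsageClass(gid, "not_expressed")
        for (tissue, stage), total in totals.items():
            if total > 0:
                te_sum = g[
                    (g.tissue == tissue) & (g.stage == stage) & g.tss_is_te
                ]["fpkm"].sum()
                uc.contribution[(tissue, stage)] = te_sum / total
        if len(expressed_ts) == 0:
            out.append(uc)
            continue
        used_te = False
        used_non = False
        for (tissue, stage) in expressed_ts.index:
            sub = g[(g.tissue == tissue) & (g.stage == stage) & (g.fpkm > 0)]
            used_te = used_te or bool(sub.tss_is_te.any())
            used_non = used_non or bool((~sub.tss_is_te).any())
        if used_te and used_non:
            uc.category = "both"
        elif used_te:
            uc.category = "te_only"
        else:
            uc.category = "non_te_only"
        out.append(uc)
    return out


def te_contribution(
    expr: pd.DataFrame,
    gene_id: str,
    tissue: str,
    stage: str,
) -> float | None:
    """TE-TSS share of a gene's expression in one tissue/stage:
    sum of TE-TSS transcript FPKM over total gene FPKM (replicate-mean).
    Undefined (None) when the gene total is 0."""
    g = _mean_over_replicates(
        expr[(expr.gene_id == gene_id) & (expr.tissue == tissue) & (expr.stage == stage)]
    )
    total = g["fpkm"].sum()
    if total == 0:
        return None
    return float(g[g.tss_is_te]["fpkm"].sum() / total)


def cage_contribution(
    cage_peaks,
    te_tss_records,
    gene: GeneModel,
) -> dict[str, float | None]:
    """TE-derived TSS contribution from CAGE expression, per stage.

    CAGE peaks are assigned by 1-bp overlap either to the accessible TE
    hosting the gene's TE-derived TSS or to the gene's other (non-TE)
    transcript TSS positions; unassigned peaks are ignored.  Returns
    stage -> TE share of assigned CAGE expression (None when no peak is
    assigned at all).
    """
    te_tss_positions = {
        r.tss_position for r in te_tss_records if r.gene_id == gene.gene_id
    }
    te_ivs = [
        tss_point_interval(t, gene.strand, gene.chrom) for t in te_tss_positions
    ]
    non_te_ivs = [
        tss_point_interval(tx.tss, gene.strand, gene.chrom)
        for tx in gene.transcripts
        if tx.tss not in te_tss_positions
    ]

    def assigned(peak, ivs):
        return any(peak.interval.overlap_bp(iv) >= 1 for iv in ivs)

    stages = sorted({s for p in cage_peaks for s in p.expression})
    out: dict[str, float | None] = {}
    for stage in stages:
        te_expr = 0.0
        non_expr = 0.0
        any_assigned = False
        for p in cage_peaks:
            e = p.expression.get(stage, 0.0)
            if assigned(p, te_ivs):
                te_expr += e
                any_assigned = True
            elif assigned(p, non_te_ivs):
                non_expr += e
                any_assigned = True
        if not any_assigned:
            out[stage] = None
        elif te_expr + non_expr == 0:
            out[stage] = None
        else:
            out[stage] = te_expr / (te_expr + non_expr)
    return out


def read_expression_table(path) -> pd.DataFrame:
    """Expression table: transcript_id, gene_id, tissue, stage,
    replicate, fpkm (tab-separated with header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "tissue", "stage", "replicate", "fpkm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    if (df.fpkm < 0).any():
        raise ValueError("FPKM values must be >= 0")
    return df


def label_te_transcripts(expr: pd.DataFrame, genes, accessible_te_intervals) -> pd.DataFrame:
    """Add a ``tss_is_te`` column: a transcript's own TSS lies inside an
    accessible TE."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in accessible_te_intervals:
        by_chrom[iv.chrom].append(iv)
    flags = {}
    for gene in genes:
        for tx in gene.transcripts:
            t = tx.tss
            flags[tx.transcript_id] = any(
                iv.start <= t < iv.end for iv in by_chrom.get(gene.chrom, ())
            )
    expr = expr.copy()
    expr["tss_is_te"] = expr.transcript_id.map(flags).fillna(False).astype(bool)
    return expr


def write_usage_report(usage_classes, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\tcontributions\n")
        for uc in sorted(usage_classes, key=lambda u: u.gene_id):
            contrib = ";".join(
                f"{t}:{s}={v:.4f}" for (t, s), v in sorted(uc.contribution.items())
            )
            fh.write(f"{uc.gene_id}\t{uc.category}\t{contrib or '.'}\n")
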