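"""Developmental-stage dynamics of accessible TEs.

Accessible TEs overlapping a differential accessible region (DAR,
|log2FC| > 1 and FDR < 0.05) are classified as stage-specific (more
open at P0 when the fold-change is positive, at E14.5 when negative);
the rest are shared.  Expression shifts of genes near stage-specific
TEs are assessed with the Wilcoxon signed-rank test, and HOMER-style
motif-enrichment tables are filtered by the standard selection rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, nearest_gene, overlap_fractional

STAGE_LABELS = ("E14.5_specific", "P0_specific", "shared")


@dataclass(frozen=True)
class DARRecord:
    interval: GenomicInterval
    log2fc: float  # P0 vs E14.5
    fdr: float

    def __post_init__(self) -> None:
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"FDR must be in [0,1], got {self.fdr}")

    def passes(self, min_abs_log2fc: float = 1.0, max_fdr: float = 0.05) -> bool:
        return abs(self.log2fc) > min_abs_log2fc and self.fdr < max_fdr


@dataclass(frozen=True)
class StageClass:
    te_id: str
    tissue: str
    label: str
    ambiguous: bool = False


@dataclass(frozen=True)
class MotifResultRow:
    motif_id: str
    pct_targets: float
    match_score: float
    p_value: float


def read_dar_table(path) -> list[DARRecord]:
    """Read a (chrom, start, end, log2fc, fdr) tab table, header optional."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 DAR columns")
            out.append(
                DARRecord(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                    float(fields[3]),
                    float(fields[4]),
                )
            )
    return out


def classify_stage_specific(
    accessible_te_intervals,
    dars,
    tissue: str,
    min_abs_log2fc: float = 1.0,
    max_fdr: float = 0.05,
) -> list[StageClass]:
    """Label each accessible TE by overlap (>=1 bp) with passing DARs.

    A TE hit by passing DARs of both signs takes the sign of the larger
    |log2FC| and is flagged ambiguous.  TEs with no passing DAR overlap
    are shared.  Labels partition the accessible set.
    """
    passing = [d for d in dars if d.passes(min_abs_log2fc, max_fdr)]
    dar_ivs = [
        GenomicInterval(d.interval.chrom, d.interval.start, d.interval.end, ".", str(i))
        for i, d in enumerate(passing)
    ]
    pairs = overlap_fractional(accessible_te_intervals, dar_ivs, 0.0, 0.0)
    hits: dict[str, list[DARRecord]] = {}
    for pr in pairs:
        hits.setdefault(pr.query_id, []).append(passing[int(pr.subject_id)])
    out = []
    for te in accessible_te_intervals:
        dhits = hits.get(te.id)
        if not dhits:
            out.append(StageClass(te.id, tissue, "shared"))
            continue
        signs = {np.sign(d.log2fc) for d in dhits}
        best = max(dhits, key=lambda d: abs(d.log2fc))
        label = "P0_specific" if best.log2fc > 0 else "E14.5_specific"
        out.append(StageClass(te.id, tissue, label, ambiguous=len(signs) > 1))
    return out


@dataclass(frozen=True)
class ExpressionShiftResult:
    tissue: str
    label: str
    n: int
    statistic: float | None
    p_value: float | None
    underpowered: bool
    gene_ids: tuple


def wilcoxon_paired(x, y, min_n: int = 5):
    """Wilcoxon signed-rank on paired samples.

    Zero differences are dropped (Wilcoxon convention); the exact null
    is enumerated for n <= 25, otherwise the normal approximation with
    continuity correction is used.  Fewer than ``min_n`` informative
    pairs -> (None, None, n) flagged underpowered by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y - x
    d = d[d != 0]
    n = len(d)
    if n < min_n:
        return None, None, n
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue), n


def stage_expression_test(
    stage_classes,
    te_catalog,
    genes,
    expr_e14: dict[str, float],
    expr_p0: dict[str, float],
    max_distance: int = 20_000,
    min_n: int = 5,
) -> list[ExpressionShiftResult]:
    """Per (tissue, stage-specific label): assign each TE to its nearest
    gene within ``max_distance`` bp, deduplicate by gene, and test the
    paired (E14.5, P0) expression shift."""
    grouped: dict[tuple[str, str], set] = {}
    for sc in stage_classes:
        if sc.label == "shared":
            continue
        te = te_catalog.by_id.get(sc.te_id)
        if te is None:
            continue
        gid = nearest_gene(te.interval, genes, max_distance)
        if gid is None:
            continue
        grouped.setdefault((sc.tissue, sc.label), set()).add(gid)
    results = []
    for (tissue, label), gids in sorted(grouped.items()):
        gids = sorted(g for g in gids if g in expr_e14 and g in expr_p0)
        x = [expr_e14[g] for g in gids]
        y = [expr_p0[g] for g in gids]
        statistic, p, n = wilcoxon_paired(x, y, min_n)
        results.append(
            ExpressionShiftResult(
                tissue, label, n, statistic, p, p is None, tuple(gids)
            )
        )
    return results


def filter_motif_results(
    rows,
    min_pct: float = 0.10,
    min_score: float = 0.9,
    max_p: float = 1e-11,
) -> list[MotifResultRow]:
    """Selection rules for de novo motif results: pct_targets >= 10%
    (inclusive, "at least"), match score > 0.9 and p < 1e-11 (strict)."""
    return [
        r
        for r in rows
        if r.pct_targets >= min_pct and r.match_score > min_score and r.p_value < max_p
    ]


def read_motif_table(path) -> list[MotifResultRow]:
    """Read a HOMER-style tab table: motif, p-value, % of targets (may
    carry a trailing '%'), best-match score."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            pct = fields[2].rstrip("%")
            pct = float(pct) / 100 if fields[2].endswith("%") else float(pct)
            rows.append(
                MotifResultRow(fields[0], pct, float(fields[3]), float(fields[1]))
            )
    return rows


def naive_differential(
    counts_a: dict[str, int],
    counts_b: dict[str, int],
    total_a: int,
    total_b: int,
) -> dict[str, tuple[float, float]]:
    """Simple per-region differential accessibility: log2 CPM ratio with
    an add-0.5 pseudocount and a BH-adjusted exact binomial test.

    This is a self-test convenience for synthetic data and is not
    equivalent to a dispersion-aware negative-binomial fit.
    """
    from statsmodels.stats.multitest import multipletests

    regions = sorted(set(counts_a) | set(counts_b))
    p_null = total_b / (total_a + total_b)
    log2fc = {}
    pvals = []
    for r in regions:
        ca, cb = counts_a.get(r, 0), counts_b.get(r, 0)
        cpm_a = (ca + 0.5) * 1e6 / total_a
        cpm_b = (cb + 0.5) * 1e6 / total_b
        log2fc[r] = float(np.log2(cpm_b / cpm_a))
        pvals.append(stats.binomtest(cb, ca + cb, p_null).pvalue if ca + cb else 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return {r: (log2fc[r], float(q)) for r, q in zip(regions, fdr)}
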