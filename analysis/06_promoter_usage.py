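"""Quantify TE-derived promoter usage per gene from transcript
expression and, independently, from CAGE peak expression."""

import os

import numpy as np
from scipy import stats

from _common import RESULTS, TISSUES, get_calls, load_annotation
from opente.accessibility import accessible_ids
from opente.simulate import STAGES
from opente.tss import detect_te_tss
from opente.usage import (
    cage_contribution,
    classify_tss_usage,
    label_te_transcripts,
    read_cage_table,
    read_expression_table,
    te_contribution,
    write_usage_report,
)


def main():
    d, truth, catalog, genes, _sizes = load_annotation()
    calls, _peaks = get_calls(catalog, d)
    union_ivs = [catalog.by_id[t].interval for t in sorted(accessible_ids(calls))]
    expr = label_te_transcripts(
        read_expression_table(os.path.join(d, "expression.tsv")), genes, union_ivs
    )
    records = detect_te_tss(calls, genes, catalog)
    te_tss_genes = {r.gene_id for r in records}
    usage = classify_tss_usage(expr[expr.gene_id.isin(te_tss_genes)])
    write_usage_report(usage, os.path.join(RESULTS, "06_tss_usage.tsv"))
    counts = {}
    for u in usage:
        counts[u.category] = counts.get(u.category, 0) + 1
    n = len(usage)
    print(f"TSS usage among {n} TE-TSS genes: "
          + ", ".join(f"{k} {v} ({v / n:.0%})" for k, v in sorted(counts.items())))

    cage = read_cage_table(os.path.join(d, "cage.tsv"))
    by_id = {g.gene_id: g for g in genes}
    pairs = []
    for gid, c_true in truth["contribution"].items():
        vals = [te_contribution(expr, gid, t, s) for t in TISSUES for s in STAGES]
        est_e = float(np.mean([v for v in vals if v is not None]))
        cc = cage_contribution(cage, records, by_id[gid])
        vv = [v for v in cc.values() if v is not None]
        est_c = float(np.mean(vv)) if vv else None
        pairs.append((gid, c_true, est_e, est_c))
    with_cage = [(e, c) for _g, _t, e, c in pairs if c is not None]
    rho = stats.spearmanr(*zip(*with_cage)).statistic
    mae = float(np.mean([abs(e - t) for _g, t, e, _c in pairs]))
    print(f"planted contributions: expression MAE {mae:.3f}; "
          f"expression vs CAGE Spearman rho {rho:.3f} over {len(with_cage)} genes")


if __name__ == "__main__":
    main()
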