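"""Classify accessible TEs by developmental-stage specificity from the
differential-accessibility tables, test expression shifts of nearby
genes, and filter the motif-enrichment table."""

import os

from _common import RESULTS, TISSUES, get_calls, load_annotation
from opente.accessibility import accessible_ids
from opente.dynamics import (
    classify_stage_specific,
    filter_motif_results,
    read_dar_table,
    read_motif_table,
    stage_expression_test,
)
from opente.usage import read_expression_table


def main():
    d, truth, catalog, genes, _sizes = load_annotation()
    calls, _peaks = get_calls(catalog, d)
    expr = read_expression_table(os.path.join(d, "expression.tsv"))
    gene_spans = [g.span for g in genes]

    rows = []
    with open(os.path.join(RESULTS, "05_stage_dynamics.tsv"), "w") as fh:
        fh.write("tissue\tlabel\tn_te\twilcoxon_n\twilcoxon_p\n")
        for tissue in TISSUES:
            dars = read_dar_table(os.path.join(d, "dar", f"{tissue}.tsv"))
            acc = [
                catalog.by_id[t].interval
                for t in sorted(accessible_ids(calls, tissue=tissue))
            ]
            classes = classify_stage_specific(acc, dars, tissue)
            counts = {}
            for c in classes:
                counts[c.label] = counts.get(c.label, 0) + 1
            e14 = expr[(expr.tissue == tissue) & (expr.stage == "E14.5")]
            p0 = expr[(expr.tissue == tissue) & (expr.stage == "P0")]
            tests = stage_expression_test(
                classes, catalog, gene_spans,
                e14.groupby("gene_id")["fpkm"].mean().to_dict(),
                p0.groupby("gene_id")["fpkm"].mean().to_dict(),
            )
            print(f"{tissue}: {counts}")
            for t in tests:
                p_str = "NA" if t.p_value is None else f"{t.p_value:.2e}"
                print(f"  {t.label}: n={t.n} nearby genes, Wilcoxon p={p_str}")
                fh.write(f"{tissue}\t{t.label}\t{counts.get(t.label, 0)}\t{t.n}\t{p_str}\n")

    motifs = read_motif_table(os.path.join(d, "motifs.tsv"))
    kept = filter_motif_results(motifs)
    print(f"motif filter: {len(kept)}/{len(motifs)} rows pass "
          f"(>=10% targets, score>0.9, p<1e-11): {sorted(m.motif_id for m in kept)}")


if __name__ == "__main__":
    main()
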