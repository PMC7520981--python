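"""Subfamily enrichment (LER), genomic-feature enrichment, tissue
sharing of accessible TEs, and the permutation overlap test of TEs in
open chromatin."""

import os

from _common import RESULTS, TISSUES, get_calls, load_annotation
from opente.accessibility import accessible_ids
from opente.enrichment import (
    enriched_subfamilies,
    feature_enrichment,
    merge_intervals,
    open_regions_with_te_bp,
    permutation_overlap_test,
    subfamily_ler,
    tissue_sharing,
    write_ler_table,
)


def main():
    d, truth, catalog, genes, sizes = load_annotation()
    calls, peaks = get_calls(catalog, d)
    union = accessible_ids(calls)
    union_ivs = [catalog.by_id[t].interval for t in sorted(union)]
    all_peaks = [p for ps in peaks.values() for p in ps]

    open_bp = open_regions_with_te_bp(all_peaks, union_ivs)
    records = subfamily_ler(union, catalog, open_bp, sum(sizes.values()))
    enriched = enriched_subfamilies(records)
    write_ler_table(records, os.path.join(RESULTS, "03_subfamily_ler.tsv"))
    print(f"open-regions-with-TE length: {open_bp:,} bp of {sum(sizes.values()):,}")
    print(f"enriched subfamilies (copies>10, LER>3): "
          f"{sorted(r.subfamily for r in enriched)} "
          f"(planted: {truth['enriched_subfamilies']})")

    ratios = feature_enrichment(union_ivs, catalog.intervals(), genes)
    print("feature enrichment (accessible/all):",
          {k: (None if v is None else round(v, 3)) for k, v in ratios.items()})

    sharing = tissue_sharing(
        {t: accessible_ids(calls, tissue=t) for t in TISSUES},
        n_total_tissues=len(TISSUES),
    )
    counts = {}
    for s in sharing:
        counts[s.category] = counts.get(s.category, 0) + 1
    print(f"tissue sharing: {counts} "
          f"({counts.get('tissue_specific', 0) / len(sharing):.0%} single-tissue)")

    perm = permutation_overlap_test(
        union_ivs, merge_intervals(all_peaks), sizes, n_perm=100, seed=7
    )
    print(f"permutation test (TEs in OCRs): observed {perm.observed_stat}, "
          f"null max {max(perm.null_stats)}, p(enrichment) = {perm.p_enrichment:.4f}")
    with open(os.path.join(RESULTS, "03_permutation_test.json"), "w") as fh:
        fh.write(perm.to_json())


if __name__ == "__main__":
    main()
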