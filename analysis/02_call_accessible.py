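"""Call accessible TEs with the two-method caller (joint-fraction peak
overlap, then IPKM rescue against the 25%-quantile peak cutoff) and
score the calls against the planted truth."""

import os

from _common import RESULTS, TISSUES, get_calls, load_annotation
from opente.accessibility import accessible_ids, write_calls
from opente.simulate import STAGES


def main():
    d, truth, catalog, _genes, _sizes = load_annotation()
    calls, _peaks = get_calls(catalog, d)
    write_calls(calls, os.path.join(RESULTS, "02_accessibility_calls.tsv"))

    truth_triples = {
        (t, tis, st)
        for tis, dd in truth["open"].items()
        for st, ids in dd.items()
        for t in ids
    }
    called = {(c.te_id, c.tissue, c.stage) for c in calls if c.called}
    tp = len(called & truth_triples)
    print(f"accessible TE calls: {len(called)} (union {len(accessible_ids(calls))} TEs)")
    print(f"recall vs planted truth: {tp / len(truth_triples):.3f}")
    print(f"precision vs planted truth: {tp / len(called):.3f}")
    with open(os.path.join(RESULTS, "02_caller_summary.tsv"), "w") as fh:
        fh.write("tissue\tstage\tcalled\tmethod_overlap\tmethod_ipkm\n")
        for tissue in TISSUES:
            for stage in STAGES:
                sub = [c for c in calls if c.called and c.tissue == tissue and c.stage == stage]
                n_ov = sum(1 for c in sub if c.method in ("overlap", "both"))
                n_ip = sum(1 for c in sub if c.method == "ipkm")
                fh.write(f"{tissue}\t{stage}\t{len(sub)}\t{n_ov}\t{n_ip}\n")
                print(f"  {tissue} {stage}: {len(sub)} called ({n_ip} via IPKM rescue)")


if __name__ == "__main__":
    main()
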