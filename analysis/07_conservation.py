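"""Conservation: the meta-profile of the score track around accessible
TEs, orthology categories of accessible TEs, and the alignment-column
conservation of the toy subfamily alignment."""

import os
import warnings

import numpy as np

from _common import RESULTS, get_calls, load_annotation
from opente.accessibility import accessible_ids
from opente.conservation import (
    AlignmentBlock,
    ScoreTrack,
    classify_orthology,
    column_conservation,
    phastcons_profile,
    read_orthology_flags,
    sample_regions,
)


def main():
    d, truth, catalog, _genes, sizes = load_annotation()
    calls, _peaks = get_calls(catalog, d)
    union_ivs = [catalog.by_id[t].interval for t in sorted(accessible_ids(calls))]

    track = ScoreTrack.from_bedgraph(os.path.join(d, "phastcons.bedgraph"))
    regions = sample_regions(union_ivs, 2000, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = phastcons_profile(regions, track, sizes)
    with open(os.path.join(RESULTS, "07_conservation_profile.tsv"), "w") as fh:
        fh.write("bin\tmean_score\n")
        for i, v in enumerate(prof):
            fh.write(f"{i}\t{'NA' if v is None else f'{v:.5f}'}\n")
    center = prof[len(prof) // 2]
    outer = [v for v in prof[:10] + prof[-10:] if v is not None]
    print(f"profile over {len(regions)} accessible TEs: center bin {center:.3f} "
          f"vs outermost bins {float(np.mean(outer)):.3f} (dip at TE centers)")

    ortho = classify_orthology(read_orthology_flags(os.path.join(d, "orthology.tsv")))
    counts = {}
    for o in ortho:
        counts[o.category] = counts.get(o.category, 0) + 1
    print(f"orthology of accessible TEs: {counts}")

    block = AlignmentBlock.from_fasta(os.path.join(d, "alignment.fa"))
    scores = [s for s in column_conservation(block) if s is not None]
    print(f"alignment block: {len(block.sequences)} rows, "
          f"mean column conservation {float(np.mean(scores)):.3f}")


if __name__ == "__main__":
    main()
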