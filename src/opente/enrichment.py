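"""Enrichment statistics for accessible TEs.

Includes the subfamily log2 enrichment ratio (LER), genomic-feature
enrichment ratios, tissue-sharing classes, and an interval permutation
overlap test (a self-contained stand-in for spatial-correlation
batteries such as GenometriCorr).
"""

from __future__ import annotations

import json
import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, merge_intervals, overlap_fractional
from .te_annotation import TECatalog


@dataclass(frozen=True)
class LERRecord:
    subfamily: str
    te_class: str
    observed: int
    copies: int
    ler: float  # -inf when observed == 0
    enriched: bool


@dataclass(frozen=True)
class SharingClass:
    te_id: str
    n_tissues: int
    category: str  # tissue_specific | shared | constitutive


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: int
    null_stats: tuple
    p_enrichment: float
    p_depletion: float
    p_two_sided: float
    n_perm: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "observed_stat": self.observed_stat,
                "null_stats": list(self.null_stats),
                "p_enrichment": self.p_enrichment,
                "p_depletion": self.p_depletion,
                "p_two_sided": self.p_two_sided,
                "n_perm": self.n_perm,
                "seed": self.seed,
            },
            sort_keys=True,
        )


def feature_enrichment(accessible_tes, all_tes, gene_model) -> dict[str, float | None]:
    """Per-feature ratio: accessible TEs overlapping the feature over all
    TEs overlapping it.  Features with zero total TEs are ``None``
    (undefined), not 0.
    """
    from .intervals import assign_feature

    accessible_labels = assign_feature(accessible_tes, gene_model)
    all_labels = assign_feature(all_tes, gene_model)
    features = ("first_exon", "exon", "intron", "intergenic")
    out: dict[str, float | None] = {}
    for f in features:
        total = sum(1 for lab in all_labels if f in lab)
        acc = sum(1 for lab in accessible_labels if f in lab)
        out[f] = acc / total if total else None
    return out


def open_regions_with_te_bp(peaks, accessible_te_intervals) -> int:
    """Summed bp of merged OCR peaks that contain >=1 accessible TE.

    This is the "length of open regions with TE" term of the LER
    denominator.
    """
    # merged peaks lose their ids; re-id them for the overlap pass
    merged = [
        GenomicInterval(p.chrom, p.start, p.end, ".", f"m{i}")
        for i, p in enumerate(merge_intervals(peaks))
    ]
    hit = {
        pr.query_id
        for pr in overlap_fractional(merged, accessible_te_intervals, 0.0, 0.0)
    }
    return sum(len(p) for p in merged if p.id in hit)


def subfamily_ler(
    accessible_te_ids,
    catalog: TECatalog,
    open_te_bp: int,
    genome_bp: int,
) -> list[LERRecord]:
    """LER_j = log2( observed_j / (copies_j * open_te_bp / genome_bp) ).

    ``observed_j`` counts accessible TEs in subfamily j; the denominator
    is the length-scaled expectation.  Subfamilies with zero accessible
    copies get LER = -inf and are never enriched.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if not 0 < open_te_bp <= genome_bp:
        raise ValueError("open_te_bp must be in (0, genome_bp]")
    accessible = set(accessible_te_ids)
    obs = Counter(catalog.by_id[t].subfamily for t in accessible if t in catalog.by_id)
    frac = open_te_bp / genome_bp
    records = []
    for sf in sorted(catalog.by_subfamily):
        tes = catalog.by_subfamily[sf]
        copies = len(tes)
        observed = obs.get(sf, 0)
        expected = copies * frac
        ler = math.log2(observed / expected) if observed > 0 else -math.inf
        records.append(
            LERRecord(sf, tes[0].te_class, observed, copies, ler, False)
        )
    return records


def enriched_subfamilies(records, min_copies: int = 10, min_ler: float = 3.0):
    """Keep subfamilies with copies > min_copies AND LER > min_ler (both
    strict, as the selection rule is stated)."""
    return [
        LERRecord(r.subfamily, r.te_class, r.observed, r.copies, r.ler, True)
        for r in records
        if r.copies > min_copies and r.ler > min_ler
    ]


def write_ler_table(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("subfamily\tte_class\tcopies\tobserved\tler\tenriched\n")
        for r in records:
            fh.write(
                f"{r.subfamily}\t{r.te_class}\t{r.copies}\t{r.observed}\t"
                f"{r.ler:.6g}\t{int(r.enriched)}\n"
            )


def tissue_sharing(calls_by_tissue: dict[str, set], n_total_tissues: int | None = None):
    """Sharing class per TE from per-tissue accessible id sets.

    A TE accessible (in either stage) in exactly one tissue is
    tissue_specific; in all tissues constitutive; otherwise shared.
    """
    if n_total_tissues is None:
        n_total_tissues = len(calls_by_tissue)
    counts: dict[str, int] = defaultdict(int)
    for ids in calls_by_tissue.values():
        for te_id in ids:
            counts[te_id] += 1
    out = []
    for te_id in sorted(counts):
        n = counts[te_id]
        if n == 1:
            cat = "tissue_specific"
        elif n == n_total_tissues:
            cat = "constitutive"
        else:
            cat = "shared"
        out.append(SharingClass(te_id, n, cat))
    return out


def _overlap_counts(starts, lengths, ref_starts, ref_ends) -> int:
    """Count intervals [s, s+l) overlapping any merged reference run."""
    if len(ref_starts) == 0:
        return 0
    ends = starts + lengths
    idx = np.searchsorted(ref_ends, starts, side="right")
    ok = idx < len(ref_starts)
    hit = np.zeros(len(starts), dtype=bool)
    hit[ok] = ref_starts[idx[ok]] < ends[ok]
    return int(hit.sum())


def permutation_overlap_test(
    query,
    reference,
    chrom_sizes: ChromSizes,
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of query/reference interval overlap.

    The statistic is the number of query intervals with >=1 bp reference
    overlap.  The null re-places each query interval uniformly on its own
    chromosome (length preserved, start drawn from [0, chrom_len - len]).
    Empirical p-values use the add-one convention, so p is never 0;
    two-sided is 2*min(enrich, deplete) capped at 1.
    """
    rng = np.random.default_rng(seed)
    ref_merged = merge_intervals(reference) if reference else []
    ref_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in ref_merged}:
        runs = [r for r in ref_merged if r.chrom == chrom]
        ref_by_chrom[chrom] = (
            np.array([r.start for r in runs], dtype=np.int64),
            np.array([r.end for r in runs], dtype=np.int64),
        )
    empty = (np.array([], dtype=np.int64), np.array([], dtype=np.int64))

    by_chrom: dict[str, np.ndarray] = {}
    obs = 0
    for chrom in sorted({q.chrom for q in query}):
        qs = [q for q in query if q.chrom == chrom]
        lens = np.array([len(q) for q in qs], dtype=np.int64)
        if (lens > chrom_sizes[chrom]).any():
            raise ValueError(f"query interval longer than chromosome {chrom}")
        starts = np.array([q.start for q in qs], dtype=np.int64)
        rs, re = ref_by_chrom.get(chrom, empty)
        obs += _overlap_counts(starts, lens, rs, re)
        by_chrom[chrom] = lens

    null = np.zeros(n_perm, dtype=np.int64)
    for chrom, lens in by_chrom.items():
        max_start = chrom_sizes[chrom] - lens
        rs, re = ref_by_chrom.get(chrom, empty)
        for i in range(n_perm):
            starts = rng.integers(0, max_start + 1)
            null[i] += _overlap_counts(starts, lens, rs, re)

    p_enr = (1 + int((null >= obs).sum())) / (1 + n_perm)
    p_dep = (1 + int((null <= obs).sum())) / (1 + n_perm)
    p_two = min(1.0, 2 * min(p_enr, p_dep))
    return PermutationResult(obs, tuple(int(x) for x in null), p_enr, p_dep, p_two, n_perm, seed)
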