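"""Transposable-element annotation: loading, filtering, and the
subfamily/family/class hierarchy.

The annotation filter keeps only transposon-derived repeats: simple
repeats, satellites and (by default) low-complexity records are dropped,
as are copies shorter than 100 bp.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "other")

#: RepeatMasker class labels that are not transposons.
NON_TE_CLASSES = frozenset({"Simple_repeat", "Satellite", "Low_complexity"})

MIN_TE_LENGTH = 100


def normalize_class(raw: str) -> str:
    """Collapse RepeatMasker class variants (LTR?, DNA?, RC, ...) onto the
    four major TE classes, with everything else as "other"."""
    base = raw.rstrip("?").split("/")[0]
    return base if base in TE_CLASSES[:4] else "other"


@dataclass(frozen=True)
class TEInstance:
    interval: GenomicInterval
    subfamily: str
    family: str
    te_class: str

    @property
    def te_id(self) -> str:
        return self.interval.id

    def __len__(self) -> int:
        return len(self.interval)


class TECatalog:
    """Filtered TE instances indexed by subfamily."""

    def __init__(self, instances):
        self.instances: list[TEInstance] = list(instances)
        self.by_subfamily: dict[str, list[TEInstance]] = defaultdict(list)
        self.by_id: dict[str, TEInstance] = {}
        for te in self.instances:
            self.by_subfamily[te.subfamily].append(te)
            self.by_id[te.te_id] = te

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def copy_counts(self) -> dict[str, int]:
        return {sf: len(tes) for sf, tes in self.by_subfamily.items()}

    def intervals(self) -> list[GenomicInterval]:
        return [te.interval for te in self.instances]


def read_rmsk(path) -> list[dict]:
    """Read a UCSC rmsk-style 7-column table:
    genoName, genoStart, genoEnd, strand, repName, repClass, repFamily.
    Returns raw records (unfiltered) for :func:`filter_te_annotation`.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 rmsk columns")
            records.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                    "strand": fields[3] if fields[3] in "+-" else ".",
                    "subfamily": fields[4],
                    "rep_class": fields[5],
                    "family": fields[6],
                }
            )
    return records


def filter_te_annotation(
    raw_records,
    min_length: int = MIN_TE_LENGTH,
    drop_classes: frozenset = NON_TE_CLASSES,
) -> TECatalog:
    """Apply the annotation filter and index the survivors.

    Records whose class is in ``drop_classes`` are removed, as are
    records shorter than ``min_length`` bp (a 100-bp copy is retained:
    the rule is "shorter than").  TE ids are assigned positionally as
    ``te<k>`` over the raw input when the record has no id, so ids are
    stable across filter settings.
    """
    instances = []
    for k, rec in enumerate(raw_records):
        if "rep_class" not in rec:
            raise ValueError(f"record {k} is missing the repeat class field")
        if rec["rep_class"] in drop_classes:
            continue
        if rec["end"] - rec["start"] < min_length:
            continue
        te_id = rec.get("te_id") or f"te{k}"
        iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"], te_id)
        instances.append(
            TEInstance(iv, rec["subfamily"], rec["family"], normalize_class(rec["rep_class"]))
        )
    return TECatalog(instances)


def subfamily_census(catalog: TECatalog) -> pd.DataFrame:
    """Per-subfamily copy number, total bp and class."""
    rows = []
    for sf, tes in catalog.by_subfamily.items():
        rows.append(
            {
                "subfamily": sf,
                "copies": len(tes),
                "total_bp": sum(len(t) for t in tes),
                "te_class": Counter(t.te_class for t in tes).most_common(1)[0][0],
            }
        )
    return (
        pd.DataFrame(rows, columns=["subfamily", "copies", "total_bp", "te_class"])
        .sort_values("subfamily")
        .reset_index(drop=True)
    )
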