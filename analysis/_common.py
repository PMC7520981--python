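"""Shared plumbing for the numbered analysis drivers: the default
synthetic dataset (seed 7) lives under scratch/ and is generated on
first use; summary tables go to results/."""

import json
import os

from opente.accessibility import InsertionTrack, call_accessible
from opente.genes import read_gtf
from opente.intervals import ChromSizes, read_narrowpeak
from opente.simulate import STAGES, SimConfig, generate
from opente.te_annotation import filter_te_annotation, read_rmsk

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
DATASET = os.path.join(ROOT, "scratch", "dataset_seed7")
RESULTS = os.path.join(ROOT, "results")
TISSUES = ("intestine", "liver", "lung")


def ensure_dataset():
    os.makedirs(RESULTS, exist_ok=True)
    if not os.path.exists(os.path.join(DATASET, "truth.json")):
        generate(SimConfig(seed=7), DATASET)
    truth = json.load(open(os.path.join(DATASET, "truth.json")))
    return DATASET, truth


def load_annotation():
    d, truth = ensure_dataset()
    catalog = filter_te_annotation(read_rmsk(os.path.join(d, "te_annotation.tsv")))
    genes = read_gtf(os.path.join(d, "genes.gtf"))
    sizes = ChromSizes.from_file(os.path.join(d, "chrom.sizes"))
    return d, truth, catalog, genes, sizes


def load_peaks_tracks(d):
    peaks, tracks = {}, {}
    for tissue in TISSUES:
        for stage in STAGES:
            ps, ts = [], []
            for rep in (1, 2):
                base = f"{tissue}_{stage}_rep{rep}"
                ps.extend(read_narrowpeak(os.path.join(d, "peaks", base + ".narrowPeak")))
                ts.append(
                    InsertionTrack.from_file(
                        os.path.join(d, "insertions", base + ".tsv"), base
                    )
                )
            peaks[(tissue, stage)] = ps
            tracks[(tissue, stage)] = ts
    return peaks, tracks


def get_calls(catalog, d):
    peaks, tracks = load_peaks_tracks(d)
    return call_accessible(catalog, peaks, tracks), peaks
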