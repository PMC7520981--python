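"""Shared fixtures: a session-scoped synthetic dataset (seed 7) and the
derived catalog / gene models / accessibility calls."""

from __future__ import annotations

import json
import os

import pytest

from opente.accessibility import InsertionTrack, call_accessible
from opente.genes import read_gtf
from opente.intervals import ChromSizes, read_narrowpeak
from opente.simulate import STAGES, SimConfig, generate
from opente.te_annotation import filter_te_annotation, read_rmsk

TISSUES = ("intestine", "liver", "lung")


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default synthetic dataset (seed 7) plus its truth tables."""
    d = tmp_path_factory.mktemp("dataset")
    truth = generate(SimConfig(seed=7), str(d))
    return str(d), truth


@pytest.fixture(scope="session")
def catalog(dataset):
    d, _ = dataset
    return filter_te_annotation(read_rmsk(os.path.join(d, "te_annotation.tsv")))


@pytest.fixture(scope="session")
def gene_models(dataset):
    d, _ = dataset
    return read_gtf(os.path.join(d, "genes.gtf"))


@pytest.fixture(scope="session")
def chrom_sizes(dataset):
    d, _ = dataset
    return ChromSizes.from_file(os.path.join(d, "chrom.sizes"))


@pytest.fixture(scope="session")
def peaks_and_tracks(dataset):
    d, _ = dataset
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


@pytest.fixture(scope="session")
def calls(catalog, peaks_and_tracks):
    peaks, tracks = peaks_and_tracks
    return call_accessible(catalog, peaks, tracks)
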