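"""Synthetic dataset generator with machine-readable planted truth.

Emits a fully self-contained dataset — TE annotation, gene models,
per-library ATAC peaks and Tn5 insertion tracks, transcript expression,
CAGE peaks, differential-accessibility tables, a conservation score
track, mESC peaks, orthology flags and a toy alignment — in exactly the
text dialects the pipeline reads, together with a ``truth.json``
recording every planted signal so each pipeline stage can be scored.

The generator plants, in order: a TE catalog whose subfamilies carry
differential open-chromatin probability (a small set of strongly
enriched subfamilies over a quiet background); per-tissue/stage open-TE
sets with a controlled tissue-sharing distribution and
developmental-stage dynamics; genes whose furthest-5' TSS sits inside
an open TE for a planted subset, with per-gene TE-promoter usage
categories and contributions; CAGE signal proportional to expression at
a controlled detection rate; and a conservation dip centered on open
TEs.  All randomness flows from one seed through named substreams.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .genes import furthest_5prime_tss
from .intervals import GenomicInterval, merge_intervals

TISSUES_DEFAULT = ("intestine", "liver", "lung")
STAGES = ("E14.5", "P0")


@dataclass
class SimConfig:
    seed: int = 7
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    # TE catalog
    n_te: int = 5000
    n_subfamilies: int = 30
    k_enriched: int = 3
    enriched_copies: int = 60
    te_len_min: int = 150
    te_len_max: int = 3000
    n_filler: int = 60  # simple repeats / satellites / sub-100-bp records
    # accessibility
    open_prob_background: float = 0.03
    open_prob_enriched: float = 0.8
    tissues: tuple = TISSUES_DEFAULT
    n_replicates: int = 2
    sharing_probs: dict = field(default_factory=lambda: {1: 0.45, 2: 0.45, 3: 0.10})
    stage_specific_fraction: float = 0.3
    true_abs_log2fc: float = 2.0
    method2_fraction: float = 0.15  # open TEs whose peak fails the joint fractions
    decoy_fraction: float = 0.01  # closed TEs touched by a weak peak
    # insertion model (per library)
    open_insertion_density: float = 0.02  # per bp of open TE (~30 for a 1.5-kb TE)
    background_insertion_rate: float = 0.002  # per genomic bp
    noise_peak_density: float = 0.012  # per bp of non-TE noise peaks
    decoy_peak_density: float = 0.004
    n_noise_peaks: int = 80
    # genes / expression
    n_genes: int = 300
    te_tss_fraction: float = 0.15
    te_tss_host_min_len: int = 600
    te_tss_jitter_bp: float = 0.0  # sd of TSS placement jitter (0 = noiseless)
    usage_split: dict = field(
        default_factory=lambda: {"te_only": 0.60, "both": 0.35, "non_te_only": 0.05}
    )
    expr_mu: float = 1.0  # log-normal location of gene expression (natural log)
    expr_sigma: float = 1.0
    replicate_noise_sigma: float = 0.08
    stage_shift_multiplier: float = 2.0
    silent_gene_fraction: float = 0.1  # non-TE genes below the expression threshold
    # CAGE
    cage_rate: float = 0.6  # per-gene detection probability at TE-TSS genes
    cage_scale: float = 50.0  # expected CAGE counts per FPKM unit
    # conservation
    phastcons_base: float = 0.5
    phastcons_dip: float = 0.12
    # chromatin marks / orthology
    h3k27ac_rate: float = 0.4
    mesc_constitutive_rate: float = 0.8
    orthology_probs: dict = field(
        default_factory=lambda: {
            "shared_all": 0.20,
            "rodent_specific": 0.35,
            "mouse_specific": 0.44,
            "human_only_anomaly": 0.01,
        }
    )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("te", "genes", "atac", "expr", "cage", "cons", "misc")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _validate(cfg: SimConfig) -> None:
    for name, p in (
        ("open_prob_background", cfg.open_prob_background),
        ("open_prob_enriched", cfg.open_prob_enriched),
        ("te_tss_fraction", cfg.te_tss_fraction),
        ("cage_rate", cfg.cage_rate),
        ("stage_specific_fraction", cfg.stage_specific_fraction),
    ):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be in [0,1], got {p}")
    if abs(sum(cfg.sharing_probs.values()) - 1) > 1e-9:
        raise ValueError("sharing_probs must sum to 1")
    if abs(sum(cfg.usage_split.values()) - 1) > 1e-9:
        raise ValueError("usage_split must sum to 1")
    mean_len = (cfg.te_len_min + cfg.te_len_max) / 2
    for chrom, size in cfg.chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size")
    genome = sum(cfg.chrom_sizes.values())
    if cfg.n_te * mean_len > 0.9 * genome:
        raise ValueError("TE catalog does not fit the genome (reduce n_te or lengths)")
    n_tss = round(cfg.n_genes * cfg.te_tss_fraction)
    # rough expectation of available open host TEs
    expected_open = cfg.n_te * max(cfg.open_prob_background, 0.0)
    if n_tss > cfg.n_te * cfg.open_prob_enriched + expected_open:
        raise ValueError("more TE-TSS genes requested than open TEs can host")


# ---------------------------------------------------------------------------
# internal record types used during generation
# ---------------------------------------------------------------------------

@dataclass
class _TE:
    te_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    gap_left: int
    gap_right: int
    open_union: bool = False
    tissues: tuple = ()
    stage_label: dict = field(default_factory=dict)  # tissue -> label
    method2: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.te_id)

    def open_at(self, tissue: str, stage: str) -> bool:
        if tissue not in self.tissues:
            return False
        label = self.stage_label[tissue]
        return label == "shared" or label == f"{stage}_specific"


@dataclass
class _Gene:
    gene_id: str
    chrom: str
    strand: str
    gene_type: str
    tss: int  # furthest-5' TSS, package convention
    span: tuple
    transcripts: list  # (transcript_id, [(start, end)], tss)
    host_te: str | None = None
    category: str | None = None  # planted usage category for TE-TSS genes
    contribution: float | None = None
    base_expr: float = 1.0
    stage_mult: dict = field(default_factory=dict)  # (tissue, stage) -> multiplier


def _place_tes(cfg: SimConfig, rng: np.random.Generator) -> list[_TE]:
    chroms = sorted(cfg.chrom_sizes)
    genome = sum(cfg.chrom_sizes.values())
    n_by_chrom = {c: int(round(cfg.n_te * cfg.chrom_sizes[c] / genome)) for c in chroms}
    n_by_chrom[chroms[-1]] += cfg.n_te - sum(n_by_chrom.values())

    # subfamily labels: enriched subfamilies get fixed copy numbers
    subfams = [f"SF{i + 1:02d}" for i in range(cfg.n_subfamilies)]
    enriched = subfams[: cfg.k_enriched]
    labels = []
    for sf in enriched:
        labels.extend([sf] * cfg.enriched_copies)
    background = subfams[cfg.k_enriched:]
    n_bg = cfg.n_te - len(labels)
    if n_bg < 0:
        raise ValueError("enriched copies exceed n_te")
    labels.extend(rng.choice(background, size=n_bg))
    labels = list(rng.permutation(np.array(labels)))

    tes: list[_TE] = []
    idx = 0
    for chrom in chroms:
        n = n_by_chrom[chrom]
        lens = rng.integers(cfg.te_len_min, cfg.te_len_max + 1, size=n)
        free = cfg.chrom_sizes[chrom] - int(lens.sum())
        if free <= n:
            raise ValueError(f"TEs do not fit chromosome {chrom}")
        gaps = rng.dirichlet(np.ones(n + 1)) * free
        gaps = np.floor(gaps).astype(int)
        pos = 0
        starts = []
        for i in range(n):
            pos += int(gaps[i])
            starts.append(pos)
            pos += int(lens[i])
        for i in range(n):
            gap_l = int(gaps[i]) if i > 0 else starts[0]
            gap_r = int(gaps[i + 1]) if i < n - 1 else cfg.chrom_sizes[chrom] - (starts[i] + int(lens[i]))
            strand = "+" if rng.random() < 0.5 else "-"
            tes.append(
                _TE(
                    f"te{idx}", chrom, starts[i], starts[i] + int(lens[i]), strand,
                    str(labels[idx]), gap_l, gap_r,
                )
            )
            idx += 1
    return tes


def _assign_accessibility(cfg: SimConfig, tes: list[_TE], rng: np.random.Generator) -> None:
    enriched = {f"SF{i + 1:02d}" for i in range(cfg.k_enriched)}
    n_tissues_opts = sorted(cfg.sharing_probs)
    n_tissues_p = [cfg.sharing_probs[k] for k in n_tissues_opts]
    for te in tes:
        p = cfg.open_prob_enriched if te.subfamily in enriched else cfg.open_prob_background
        te.open_union = bool(rng.random() < p)
        if not te.open_union:
            continue
        n_t = int(rng.choice(n_tissues_opts, p=n_tissues_p))
        n_t = min(n_t, len(cfg.tissues))
        chosen = sorted(rng.choice(len(cfg.tissues), size=n_t, replace=False))
        te.tissues = tuple(cfg.tissues[i] for i in chosen)
        for tissue in te.tissues:
            if rng.random() < cfg.stage_specific_fraction:
                te.stage_label[tissue] = (
                    "P0_specific" if rng.random() < 0.5 else "E14.5_specific"
                )
            else:
                te.stage_label[tissue] = "shared"
        te.method2 = bool(rng.random() < cfg.method2_fraction)


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    for s, e in intervals:
        if s <= pos < e:
            return True
    return False


def _near_any(pos: int, intervals: list[tuple[int, int]], margin: int = 10) -> bool:
    for s, e in intervals:
        if s - margin <= pos < e + margin:
            return True
    return False


def _build_genes(cfg: SimConfig, tes: list[_TE], rng: np.random.Generator) -> list[_Gene]:
    open_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_sizes}
    for te in tes:
        if te.open_union:
            open_by_chrom[te.chrom].append((te.start, te.end))

    n_tss = round(cfg.n_genes * cfg.te_tss_fraction)
    hosts = [
        te for te in tes
        if te.open_union and te.length >= cfg.te_tss_host_min_len
    ]
    if len(hosts) < n_tss:
        raise ValueError(
            f"only {len(hosts)} open TEs can host a TSS but {n_tss} TE-TSS genes requested"
        )
    host_idx = rng.choice(len(hosts), size=n_tss, replace=False)
    host_tes = [hosts[i] for i in sorted(host_idx)]

    cats = list(cfg.usage_split)
    cat_p = [cfg.usage_split[c] for c in cats]
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_sizes}
    genes: list[_Gene] = []

    def overlaps_placed(chrom, s, e):
        return any(s < pe and e > ps for ps, pe in placed[chrom])

    def secondary_tss(chrom, strand, t0, L, avoid):
        """A downstream (3'-ward) TSS outside every open TE."""
        for _ in range(80):
            delta = int(rng.integers(600, max(700, L - 500)))
            t1 = t0 + delta if strand == "+" else t0 - delta
            probe = t1 if strand == "+" else t1 - 1
            if not _near_any(probe, avoid, margin=10):
                return t1
        return None

    # --- TE-TSS genes -----------------------------------------------------
    for k, host in enumerate(host_tes):
        gid = f"gtss{k}"
        chrom = host.chrom
        strand = "+" if rng.random() < 0.5 else "-"
        center = (host.start + host.end) // 2
        t0 = center
        if cfg.te_tss_jitter_bp > 0:
            t0 = center + int(round(rng.normal(0, cfg.te_tss_jitter_bp)))
        L = int(rng.integers(4000, 15000))
        category = str(rng.choice(cats, p=cat_p))
        n_tx = 1 if category == "te_only" else 2
        if strand == "+":
            span = (t0, t0 + L)
        else:
            span = (t0 - L, t0)
        if span[0] < 0 or span[1] > cfg.chrom_sizes[chrom] or overlaps_placed(chrom, *span):
            # fall back: single-transcript gene at a shifted length
            L = 4000
            span = (t0, t0 + L) if strand == "+" else (t0 - L, t0)
            if span[0] < 0 or span[1] > cfg.chrom_sizes[chrom] or overlaps_placed(chrom, *span):
                continue  # drop this host; truth only records emitted genes
        txs = []
        if strand == "+":
            txs.append((f"{gid}.t0", [(t0, t0 + 200), (span[1] - 200, span[1])], t0))
        else:
            txs.append((f"{gid}.t0", [(span[0], span[0] + 200), (t0 - 200, t0)], t0))
        if n_tx == 2:
            t1 = secondary_tss(chrom, strand, t0, L, open_by_chrom[chrom])
            if t1 is None:
                category = "te_only"
            else:
                if strand == "+":
                    txs.append((f"{gid}.t1", [(t1, t1 + 200), (span[1] - 200, span[1])], t1))
                else:
                    txs.append((f"{gid}.t1", [(span[0], span[0] + 200), (t1 - 200, t1)], t1))
        gtype = "protein_coding" if rng.random() < 0.7 else "lincRNA"
        contribution = None
        if category == "both":
            contribution = float(np.round(rng.uniform(0.1, 0.9), 4))
        genes.append(
            _Gene(gid, chrom, strand, gtype, t0, span, txs, host.te_id, category, contribution)
        )
        placed[chrom].append(span)

    # --- background genes -------------------------------------------------
    chroms = sorted(cfg.chrom_sizes)
    n_bg = cfg.n_genes - len(genes)
    made = 0
    attempts = 0
    while made < n_bg and attempts < n_bg * 300:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = int(rng.integers(3000, 12000))
        strand = "+" if rng.random() < 0.5 else "-"
        a = int(rng.integers(500, cfg.chrom_sizes[chrom] - L - 500))
        t0 = a if strand == "+" else a + L
        span = (a, a + L)
        probe = t0 if strand == "+" else t0 - 1
        if _near_any(probe, open_by_chrom[chrom], margin=10):
            continue
        if overlaps_placed(chrom, *span):
            continue
        gid = f"g{made}"
        n_tx = int(rng.integers(1, 3))
        txs = []
        if strand == "+":
            txs.append((f"{gid}.t0", [(t0, t0 + 200), (span[1] - 200, span[1])], t0))
        else:
            txs.append((f"{gid}.t0", [(span[0], span[0] + 200), (t0 - 200, t0)], t0))
        if n_tx == 2:
            t1 = secondary_tss(chrom, strand, t0, L, open_by_chrom[chrom])
            if t1 is not None:
                if strand == "+":
                    txs.append((f"{gid}.t1", [(t1, t1 + 200), (span[1] - 200, span[1])], t1))
                else:
                    txs.append((f"{gid}.t1", [(span[0], span[0] + 200), (t1 - 200, t1)], t1))
        gtype = "protein_coding" if rng.random() < 0.8 else "lincRNA"
        genes.append(_Gene(gid, chrom, strand, gtype, t0, span, txs))
        placed[chrom].append(span)
        made += 1
    return genes


def _ext(rng: np.random.Generator, gap: int, cap: int, margin: int = 25) -> int:
    """Random outward peak extension that never reaches a neighboring TE."""
    hi = min(cap, max(0, gap - margin))
    return int(rng.integers(0, hi + 1))


def _peak_for(te: _TE, rng: np.random.Generator) -> tuple[int, int]:
    """A method-1 peak: covers the TE with small outward extensions."""
    return te.start - _ext(rng, te.gap_left, 100), te.end + _ext(rng, te.gap_right, 100)


def _method2_peak_for(te: _TE, rng: np.random.Generator) -> tuple[int, int]:
    """A peak covering only ~30% of the TE (fails the -f 0.5 fraction)."""
    cover = max(1, int(0.3 * te.length))
    return te.start - _ext(rng, te.gap_left, 100), te.start + cover


def _decoy_peak_for(te: _TE, rng: np.random.Generator) -> tuple[int, int]:
    """A weak peak touching ~20% of a closed TE."""
    cover = max(1, int(0.2 * te.length))
    return te.start - _ext(rng, te.gap_left, 200), te.start + cover


def generate(cfg: SimConfig, out_dir: str) -> dict:
    """Generate the dataset into ``out_dir`` and return the truth tables
    (also serialized as ``truth.json``).  Same config -> byte-identical
    output."""
    _validate(cfg)
    rngs = _streams(cfg.seed)

    tes = _place_tes(cfg, rngs["te"])
    _assign_accessibility(cfg, tes, rngs["te"])
    # feasibility: enough open TEs to host the requested TE-TSS genes,
    # checked before any file is written
    n_tss = round(cfg.n_genes * cfg.te_tss_fraction)
    n_hosts = sum(
        1 for te in tes if te.open_union and te.length >= cfg.te_tss_host_min_len
    )
    if n_tss > n_hosts:
        raise ValueError(
            f"only {n_hosts} open TEs can host a TSS but {n_tss} TE-TSS genes requested"
        )

    os.makedirs(out_dir, exist_ok=True)
    for sub in ("peaks", "insertions", "dar"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)

    # --- TE annotation file (with filler that the filter must remove) -----
    class_cycle = ("LINE", "SINE", "LTR", "DNA")
    sf_class = {
        f"SF{i + 1:02d}": class_cycle[i % 4] for i in range(cfg.n_subfamilies)
    }
    sf_family = {sf: f"{sf_class[sf]}_fam{(i % 5) + 1}" for i, sf in enumerate(sorted(sf_class))}
    rows = []
    for te in tes:
        rows.append(
            (te.chrom, te.start, te.end, te.strand, te.subfamily,
             sf_class[te.subfamily], sf_family[te.subfamily])
        )
    rng_f = rngs["misc"]
    chroms = sorted(cfg.chrom_sizes)
    filler_specs = [
        ("(TA)n", "Simple_repeat", "Simple_repeat", 50, 400),
        ("SATMIN", "Satellite", "Satellite", 200, 1500),
        ("G-rich", "Low_complexity", "Low_complexity", 40, 200),
        ("B1_short", "SINE", "Alu", 40, 99),
    ]
    for i in range(cfg.n_filler):
        name, klass, fam, lo, hi = filler_specs[i % len(filler_specs)]
        chrom = chroms[int(rng_f.integers(len(chroms)))]
        length = int(rng_f.integers(lo, hi + 1))
        start = int(rng_f.integers(0, cfg.chrom_sizes[chrom] - length))
        rows.append((chrom, start, start + length, "+", name, klass, fam))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    # te ids are positional over the emitted file; remap to match the
    # filter's enumeration before genes reference their host TEs
    id_map = {}
    for k, row in enumerate(rows):
        id_map[(row[0], row[1], row[2], row[4])] = f"te{k}"
    for te in tes:
        te.te_id = id_map[(te.chrom, te.start, te.end, te.subfamily)]
    with open(os.path.join(out_dir, "te_annotation.tsv"), "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    genes = _build_genes(cfg, tes, rngs["genes"])

    with open(os.path.join(out_dir, "chrom.sizes"), "w") as fh:
        for chrom in chroms:
            fh.write(f"{chrom}\t{cfg.chrom_sizes[chrom]}\n")

    # --- gene models -------------------------------------------------------
    with open(os.path.join(out_dir, "genes.gtf"), "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
            for tid, exons, _tss in g.transcripts:
                for (es, ee) in sorted(exons):
                    attrs = (
                        f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                        f'gene_type "{g.gene_type}";'
                    )
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n"
                    )

    # --- peaks and insertion tracks per library ---------------------------
    rng_a = rngs["atac"]
    open_tes = [te for te in tes if te.open_union]
    closed_tes = [te for te in tes if not te.open_union]

    # noise peak slots: gaps wide enough to hold a peak with margins
    gap_slots = []
    for te in tes:
        if te.gap_right >= 350:
            gap_slots.append((te.chrom, te.end + 25, te.end + te.gap_right - 25))

    # peak geometry is shared between replicates of a tissue/stage (a real
    # peak has signal in both replicates); insertions are drawn per replicate
    for tissue in cfg.tissues:
        for stage in STAGES:
            signal_regions = []  # (chrom, peak_s, peak_e, ins_s, ins_e, density)
            for te in open_tes:
                if not te.open_at(tissue, stage):
                    continue
                if te.method2:
                    s, e = _method2_peak_for(te, rng_a)
                else:
                    s, e = _peak_for(te, rng_a)
                signal_regions.append(
                    (te.chrom, s, e, te.start, te.end, cfg.open_insertion_density)
                )
            n_d = int(round(cfg.decoy_fraction * len(closed_tes)))
            idx = rng_a.choice(len(closed_tes), size=n_d, replace=False)
            for te in (closed_tes[i] for i in sorted(idx)):
                s, e = _decoy_peak_for(te, rng_a)
                signal_regions.append((te.chrom, s, e, s, e, cfg.decoy_peak_density))
            n_slots = min(cfg.n_noise_peaks, len(gap_slots))
            slot_idx = rng_a.choice(len(gap_slots), size=n_slots, replace=False)
            for i in sorted(slot_idx):
                chrom, lo, hi = gap_slots[i]
                length = min(int(rng_a.integers(200, 600)), hi - lo)
                if length < 100:
                    continue
                s = int(rng_a.integers(lo, hi - length + 1))
                signal_regions.append(
                    (chrom, s, s + length, s, s + length, cfg.noise_peak_density)
                )

            for rep in range(1, cfg.n_replicates + 1):
                ins: dict[str, dict[int, int]] = {c: {} for c in chroms}

                def add_insertions(chrom, start, end, mean_count):
                    n = int(rng_a.poisson(mean_count))
                    for p in rng_a.integers(start, end, size=n):
                        ins[chrom][int(p)] = ins[chrom].get(int(p), 0) + 1

                peak_rows = sorted((c, s, e) for c, s, e, _is, _ie, _d in signal_regions)
                for chrom, _s, _e, is_, ie_, dens in signal_regions:
                    add_insertions(chrom, is_, ie_, dens * (ie_ - is_))
                for chrom in chroms:
                    n_bg = int(
                        rng_a.poisson(cfg.background_insertion_rate * cfg.chrom_sizes[chrom])
                    )
                    for p in rng_a.integers(0, cfg.chrom_sizes[chrom], size=n_bg):
                        ins[chrom][int(p)] = ins[chrom].get(int(p), 0) + 1

                base = f"{tissue}_{stage}_rep{rep}"
                with open(os.path.join(out_dir, "peaks", base + ".narrowPeak"), "w") as fh:
                    for j, (chrom, s, e) in enumerate(peak_rows):
                        fh.write(f"{chrom}\t{s}\t{e}\t{base}_p{j}\t0\t.\t0\t-1\t-1\t-1\n")
                with open(os.path.join(out_dir, "insertions", base + ".tsv"), "w") as fh:
                    for chrom in chroms:
                        for p in sorted(ins[chrom]):
                            fh.write(f"{chrom}\t{p}\t{ins[chrom][p]}\n")

    # --- DAR tables per tissue --------------------------------------------
    for tissue in cfg.tissues:
        rows_d = []
        for te in open_tes:
            if tissue not in te.tissues:
                continue
            label = te.stage_label[tissue]
            if label == "shared":
                if rng_a.random() < 0.5:
                    lfc = float(rng_a.normal(0, 0.4))
                    fdr = float(rng_a.uniform(0.1, 0.9))
                    rows_d.append((te.chrom, te.start, te.end, lfc, fdr))
                continue
            sign = 1.0 if label == "P0_specific" else -1.0
            lfc = sign * (cfg.true_abs_log2fc + float(rng_a.normal(0, 0.2)))
            fdr = float(10 ** -rng_a.uniform(2, 5))
            rows_d.append((te.chrom, te.start, te.end, lfc, fdr))
        rows_d.sort(key=lambda r: (r[0], r[1]))
        with open(os.path.join(out_dir, "dar", f"{tissue}.tsv"), "w") as fh:
            fh.write("chrom\tstart\tend\tlog2fc\tfdr\n")
            for chrom, s, e, lfc, fdr in rows_d:
                fh.write(f"{chrom}\t{s}\t{e}\t{lfc:.4f}\t{fdr:.3e}\n")

    # --- expression with planted stage shifts and contributions -----------
    rng_e = rngs["expr"]
    for g in genes:
        g.base_expr = float(np.exp(rng_e.normal(cfg.expr_mu, cfg.expr_sigma)))
        if g.host_te is None and rng_e.random() < cfg.silent_gene_fraction:
            g.base_expr = float(rng_e.uniform(0.001, 0.05))

    # stage shifts: nearest gene within 20 kb of each stage-specific TE
    gene_spans = [
        GenomicInterval(g.chrom, g.span[0], g.span[1], g.strand, g.gene_id) for g in genes
    ]
    gene_by_id = {g.gene_id: g for g in genes}
    from .intervals import nearest_gene as _nearest

    shift_truth: dict[str, dict[str, str]] = {t: {} for t in cfg.tissues}
    for te in open_tes:
        for tissue in te.tissues:
            label = te.stage_label[tissue]
            if label == "shared":
                continue
            gid = _nearest(te.interval(), gene_spans, 20_000)
            if gid is None:
                continue
            g = gene_by_id[gid]
            existing = shift_truth[tissue].get(gid)
            if existing is not None and existing != label:
                continue
            shift_truth[tissue][gid] = label
            boosted = "P0" if label == "P0_specific" else "E14.5"
            for stage in STAGES:
                g.stage_mult[(tissue, stage)] = (
                    cfg.stage_shift_multiplier if stage == boosted else 1.0
                )

    expr_path = os.path.join(out_dir, "expression.tsv")
    with open(expr_path, "w") as fh:
        fh.write("transcript_id\tgene_id\ttissue\tstage\treplicate\tfpkm\n")
        for g in sorted(genes, key=lambda g: g.gene_id):
            # per-transcript base shares
            if g.host_te is not None and g.category == "both" and len(g.transcripts) == 2:
                shares = {
                    g.transcripts[0][0]: g.contribution,      # TE-TSS transcript
                    g.transcripts[1][0]: 1 - g.contribution,  # downstream transcript
                }
            elif g.host_te is not None and g.category == "non_te_only" and len(g.transcripts) == 2:
                shares = {g.transcripts[0][0]: 0.0, g.transcripts[1][0]: 1.0}
            else:
                n = len(g.transcripts)
                shares = {tid: 1.0 / n for tid, _, _ in g.transcripts}
            for tissue in cfg.tissues:
                for stage in STAGES:
                    mult = g.stage_mult.get((tissue, stage), 1.0)
                    for rep in range(1, cfg.n_replicates + 1):
                        for tid, _, _ in g.transcripts:
                            base = g.base_expr * shares[tid] * mult
                            noise = float(np.exp(rng_e.normal(0, cfg.replicate_noise_sigma)))
                            fpkm = base * noise if base > 0 else 0.0
                            fh.write(
                                f"{tid}\t{g.gene_id}\t{tissue}\t{stage}\t{rep}\t{fpkm:.6g}\n"
                            )

    # --- CAGE peaks --------------------------------------------------------
    rng_c = rngs["cage"]
    cage_rows = []
    cage_covered = []
    te_tss_genes = [g for g in genes if g.host_te is not None]

    def tss_base(g: _Gene, t: int) -> int:
        return t if g.strand == "+" else t - 1

    def mean_fpkm(g: _Gene, tid: str, stage: str) -> float:
        if g.category == "both":
            share = g.contribution if tid.endswith(".t0") else 1 - g.contribution
        elif g.category == "non_te_only":
            share = 0.0 if tid.endswith(".t0") else 1.0
        else:
            share = 1.0 / len(g.transcripts)
        mults = [g.stage_mult.get((tissue, stage), 1.0) for tissue in cfg.tissues]
        return g.base_expr * share * float(np.mean(mults))

    cage_id = 0
    for g in sorted(te_tss_genes, key=lambda g: g.gene_id):
        if rng_c.random() >= cfg.cage_rate:
            continue
        cage_covered.append(g.gene_id)
        for tid, _exons, t in g.transcripts:
            b = tss_base(g, t)
            expr = {}
            for stage in STAGES:
                lam = cfg.cage_scale * mean_fpkm(g, tid, stage)
                expr[stage] = int(rng_c.poisson(lam))
            cage_rows.append((g.chrom, b - 5, b + 6, f"cage{cage_id}", expr))
            cage_id += 1
    # background CAGE at non-TE gene TSSs (never inside open TEs)
    bg_genes = [g for g in genes if g.host_te is None and g.base_expr > 0.1]
    n_bg_cage = min(100, len(bg_genes))
    idx = rng_c.choice(len(bg_genes), size=n_bg_cage, replace=False)
    for i in sorted(idx):
        g = bg_genes[i]
        b = tss_base(g, g.tss)
        expr = {s: int(rng_c.poisson(cfg.cage_scale * g.base_expr / len(g.transcripts)))
                for s in STAGES}
        cage_rows.append((g.chrom, b - 5, b + 6, f"cage{cage_id}", expr))
        cage_id += 1
    cage_rows.sort(key=lambda r: (r[0], r[1]))
    with open(os.path.join(out_dir, "cage.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tid\t" + "\t".join(STAGES) + "\n")
        for chrom, s, e, cid, expr in cage_rows:
            vals = "\t".join(str(expr[st]) for st in STAGES)
            fh.write(f"{chrom}\t{s}\t{e}\t{cid}\t{vals}\n")

    # --- phastCons track with a dip over open TEs --------------------------
    rng_k = rngs["cons"]
    with open(os.path.join(out_dir, "phastcons.bedgraph"), "w") as fh:
        for chrom in chroms:
            dips = merge_intervals(
                [te.interval() for te in open_tes if te.chrom == chrom]
            )
            pos = 0
            for d in dips:
                if d.start > pos:
                    v = cfg.phastcons_base + float(rng_k.uniform(-0.05, 0.05))
                    fh.write(f"{chrom}\t{pos}\t{d.start}\t{v:.4f}\n")
                v = cfg.phastcons_dip + float(rng_k.uniform(-0.02, 0.02))
                fh.write(f"{chrom}\t{d.start}\t{d.end}\t{v:.4f}\n")
                pos = d.end
            if pos < cfg.chrom_sizes[chrom]:
                v = cfg.phastcons_base + float(rng_k.uniform(-0.05, 0.05))
                fh.write(f"{chrom}\t{pos}\t{cfg.chrom_sizes[chrom]}\t{v:.4f}\n")

    # --- mESC peaks: constitutive open TEs are mostly already open --------
    rng_m = rngs["misc"]
    mesc_rows = []
    for te in open_tes:
        if len(te.tissues) == len(cfg.tissues) and rng_m.random() < cfg.mesc_constitutive_rate:
            mesc_rows.append((te.chrom, max(0, te.start - 50), te.end + 50))
    mesc_rows.sort()
    with open(os.path.join(out_dir, "mesc_peaks.bed"), "w") as fh:
        for chrom, s, e in mesc_rows:
            fh.write(f"{chrom}\t{s}\t{e}\tmesc\t0\t.\n")

    # --- H3K27ac fragments -------------------------------------------------
    k27_total = 2_000_000
    k27_rows = []
    for te in open_tes:
        if rng_m.random() < cfg.h3k27ac_rate:
            k27_rows.append((te.chrom, te.start, te.end, int(rng_m.poisson(60))))
    # low-signal peaks that the CPM filter must drop
    for _ in range(30):
        chrom = chroms[int(rng_m.integers(len(chroms)))]
        s = int(rng_m.integers(0, cfg.chrom_sizes[chrom] - 500))
        k27_rows.append((chrom, s, s + 500, int(rng_m.poisson(2))))
    k27_rows.sort()
    with open(os.path.join(out_dir, "h3k27ac.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tfragments\tlibrary_total\n")
        for chrom, s, e, frag in k27_rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{frag}\t{k27_total}\n")

    # --- orthology flags for accessible TEs --------------------------------
    cats = sorted(cfg.orthology_probs)
    cat_p = [cfg.orthology_probs[c] for c in cats]
    ortho_truth = {}
    with open(os.path.join(out_dir, "orthology.tsv"), "w") as fh:
        fh.write("region_id\tin_rat\tin_human\n")
        for te in sorted(open_tes, key=lambda t: t.te_id):
            cat = str(rng_m.choice(cats, p=cat_p))
            in_rat = cat in ("shared_all", "rodent_specific")
            in_human = cat in ("shared_all", "human_only_anomaly")
            ortho_truth[te.te_id] = cat
            fh.write(f"{te.te_id}\t{int(in_rat)}\t{int(in_human)}\n")

    # --- toy alignment block (synthetic stand-in for a subfamily MSA) ------
    bases = np.array(list("ACGT"))
    ncol = 300
    consensus = bases[rng_m.integers(0, 4, size=ncol)]
    seqs = {"consensus": "".join(consensus)}
    for i in range(8):
        row = consensus.copy()
        mut = rng_m.random(ncol) < 0.1
        row[mut] = bases[rng_m.integers(0, 4, size=int(mut.sum()))]
        row = row.astype(object)
        gap = rng_m.random(ncol) < 0.03
        row[gap] = "-"
        seqs[f"copy{i + 1}"] = "".join(row)
    with open(os.path.join(out_dir, "alignment.fa"), "w") as fh:
        for label, seq in seqs.items():
            fh.write(f">{label}\n{seq}\n")

    # --- motif result table -------------------------------------------------
    motif_rows = [
        ("motif-FOXA1", 1e-14, "22.5%", 0.95),
        ("motif-NF1", 1e-20, "15.0%", 0.93),
        ("motif-HNF4A", 5e-13, "12.0%", 0.97),
        ("motif-lowpct", 1e-15, "4.0%", 0.95),
        ("motif-lowscore", 1e-15, "18.0%", 0.85),
        ("motif-weakp", 1e-9, "25.0%", 0.96),
        ("motif-edge-p", 1e-11, "12.0%", 0.95),
        ("motif-edge-score", 1e-14, "12.0%", 0.90),
        ("motif-edge-pct", 1e-14, "10.0%", 0.95),
        ("motif-all-fail", 1e-3, "2.0%", 0.50),
    ]
    with open(os.path.join(out_dir, "motifs.tsv"), "w") as fh:
        fh.write("motif\tp_value\tpct_targets\tmatch_score\n")
        for name, p, pct, score in motif_rows:
            fh.write(f"{name}\t{p:.3g}\t{pct}\t{score}\n")
    motif_truth = ["motif-FOXA1", "motif-NF1", "motif-HNF4A", "motif-edge-pct"]

    # --- truth tables -------------------------------------------------------
    truth = {
        "config": {
            k: (v if not isinstance(v, (dict, tuple)) else
                (dict(v) if isinstance(v, dict) else list(v)))
            for k, v in asdict(cfg).items()
        },
        "open_union": sorted(te.te_id for te in open_tes),
        "open": {
            tissue: {
                stage: sorted(te.te_id for te in open_tes if te.open_at(tissue, stage))
                for stage in STAGES
            }
            for tissue in cfg.tissues
        },
        "open_by_tissue": {
            tissue: sorted(te.te_id for te in open_tes if tissue in te.tissues)
            for tissue in cfg.tissues
        },
        "n_tissues": {te.te_id: len(te.tissues) for te in open_tes},
        "enriched_subfamilies": [f"SF{i + 1:02d}" for i in range(cfg.k_enriched)],
        "method2_te": sorted(te.te_id for te in open_tes if te.method2),
        "te_tss_pairs": sorted(
            [g.host_te, g.gene_id] for g in genes if g.host_te is not None
        ),
        "te_tss_category": {
            g.gene_id: g.category for g in genes if g.host_te is not None
        },
        "contribution": {
            g.gene_id: g.contribution
            for g in genes
            if g.host_te is not None and g.contribution is not None
        },
        "cage_covered_genes": sorted(cage_covered),
        "stage_labels": {
            tissue: {
                te.te_id: te.stage_label[tissue]
                for te in open_tes
                if tissue in te.tissues
            }
            for tissue in cfg.tissues
        },
        "stage_shift_genes": shift_truth,
        "orthology": ortho_truth,
        "motif_passing": motif_truth,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
    return truth
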