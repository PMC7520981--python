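"""Configuration-driven orchestration of the full accessible-TE analysis.

Stages run in dependency order: annotation -> accessibility -> enrichment
and tissue sharing -> TE-derived TSS -> stage dynamics -> promoter usage
-> conservation.  Every output table is written together with a config
snapshot and the seed, and the run is byte-reproducible under a fixed
config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import yaml

from . import accessibility as acc
from . import conservation as cons
from . import dynamics as dyn
from . import enrichment as enr
from . import tss as tssmod
from . import usage as usg
from .genes import read_gtf
from .intervals import ChromSizes, read_bed, read_narrowpeak
from .te_annotation import filter_te_annotation, read_rmsk

STAGES = ("E14.5", "P0")


@dataclass
class PipelineConfig:
    dataset_dir: str
    out_dir: str
    tissues: tuple = ("intestine", "liver", "lung")
    n_replicates: int = 2
    # thresholds, each defaulted to its published value
    frac_te: float = 0.5
    frac_peak: float = 0.2
    ipkm_quantile: float = 0.25
    min_te_len: int = 100
    promoter_bp: int = 500
    ler_min: float = 3.0
    min_copies: int = 10
    dar_log2fc: float = 1.0
    dar_fdr: float = 0.05
    near_gene_bp: int = 20_000
    expr_fpkm: float = 0.1
    k27_cpm: float = 3.0
    n_perm: int = 100
    n_profile_regions: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)


def _dataset_paths(cfg: PipelineConfig) -> dict:
    d = cfg.dataset_dir
    return {
        "te": os.path.join(d, "te_annotation.tsv"),
        "gtf": os.path.join(d, "genes.gtf"),
        "chrom_sizes": os.path.join(d, "chrom.sizes"),
        "peaks": os.path.join(d, "peaks"),
        "insertions": os.path.join(d, "insertions"),
        "dar": os.path.join(d, "dar"),
        "expression": os.path.join(d, "expression.tsv"),
        "cage": os.path.join(d, "cage.tsv"),
        "phastcons": os.path.join(d, "phastcons.bedgraph"),
        "mesc": os.path.join(d, "mesc_peaks.bed"),
        "h3k27ac": os.path.join(d, "h3k27ac.tsv"),
        "orthology": os.path.join(d, "orthology.tsv"),
        "motifs": os.path.join(d, "motifs.tsv"),
    }


def _read_k27(path) -> list[acc.K27Peak]:
    from .intervals import GenomicInterval

    peaks = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, s, e, frag, total = line.rstrip("\n").split("\t")[:5]
            peaks.append(
                acc.K27Peak(GenomicInterval(chrom, int(s), int(e)), int(frag), int(total))
            )
    return peaks


def run(cfg: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to
    ``report.json`` in the output directory)."""
    paths = _dataset_paths(cfg)
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"config": asdict(cfg), "seed": cfg.seed, "stages": {}}

    # --- annotation --------------------------------------------------------
    raw = read_rmsk(paths["te"])
    catalog = filter_te_annotation(raw, min_length=cfg.min_te_len)
    genes = read_gtf(paths["gtf"])
    chrom_sizes = ChromSizes.from_file(paths["chrom_sizes"])
    report["stages"]["annotation"] = {
        "raw_records": len(raw),
        "retained_te": len(catalog),
        "genes": len(genes),
    }

    # --- accessibility -----------------------------------------------------
    peaks_by_library: dict = {}
    tracks_by_library: dict = {}
    for tissue in cfg.tissues:
        for stage in STAGES:
            peaks = []
            tracks = []
            for rep in range(1, cfg.n_replicates + 1):
                base = f"{tissue}_{stage}_rep{rep}"
                peaks.extend(read_narrowpeak(os.path.join(paths["peaks"], base + ".narrowPeak")))
                tracks.append(
                    acc.InsertionTrack.from_file(
                        os.path.join(paths["insertions"], base + ".tsv"), base
                    )
                )
            peaks_by_library[(tissue, stage)] = peaks
            tracks_by_library[(tissue, stage)] = tracks
    calls = acc.call_accessible(
        catalog, peaks_by_library, tracks_by_library,
        cfg.frac_te, cfg.frac_peak, cfg.ipkm_quantile,
    )
    acc.annotate_h3k27ac(calls, _read_k27(paths["h3k27ac"]), catalog, cfg.k27_cpm)
    acc.classify_mesc(calls, read_bed(paths["mesc"]), catalog)
    acc.write_calls(calls, os.path.join(cfg.out_dir, "accessibility_calls.tsv"))
    union = acc.accessible_ids(calls)
    report["stages"]["accessibility"] = {
        "accessible_union": len(union),
        "calls": sum(1 for c in calls if c.called),
    }

    # --- enrichment & sharing ----------------------------------------------
    union_intervals = [catalog.by_id[t].interval for t in sorted(union)]
    all_peaks = [p for ps in peaks_by_library.values() for p in ps]
    open_bp = enr.open_regions_with_te_bp(all_peaks, union_intervals)
    genome_bp = sum(chrom_sizes.values())
    ler = enr.subfamily_ler(union, catalog, open_bp, genome_bp)
    enriched = enr.enriched_subfamilies(ler, cfg.min_copies, cfg.ler_min)
    enr.write_ler_table(ler, os.path.join(cfg.out_dir, "subfamily_ler.tsv"))
    feat = enr.feature_enrichment(union_intervals, catalog.intervals(), genes)
    sharing = enr.tissue_sharing(
        {t: acc.accessible_ids(calls, tissue=t) for t in cfg.tissues},
        n_total_tissues=len(cfg.tissues),
    )
    perm = enr.permutation_overlap_test(
        union_intervals,
        enr.merge_intervals(all_peaks),
        chrom_sizes,
        n_perm=cfg.n_perm,
        seed=cfg.seed,
    )
    with open(os.path.join(cfg.out_dir, "permutation_test.json"), "w") as fh:
        fh.write(perm.to_json())
    report["stages"]["enrichment"] = {
        "open_te_bp": open_bp,
        "enriched_subfamilies": sorted(r.subfamily for r in enriched),
        "feature_enrichment": {k: v for k, v in feat.items()},
        "sharing_counts": {
            cat: sum(1 for s in sharing if s.category == cat)
            for cat in ("tissue_specific", "shared", "constitutive")
        },
        "permutation_p_enrichment": perm.p_enrichment,
    }

    # --- TE-derived TSS -----------------------------------------------------
    te_tss = tssmod.detect_te_tss(calls, genes, catalog)
    cage = usg.read_cage_table(paths["cage"])
    tssmod.cage_validate(te_tss, [p.interval for p in cage], catalog)
    tssmod.write_te_tss_table(te_tss, os.path.join(cfg.out_dir, "te_tss.tsv"))
    prom_frac, tss_frac = tssmod.promoter_te_fraction(
        union_intervals, genes, chrom_sizes, cfg.promoter_bp
    )
    report["stages"]["te_tss"] = {
        "records": len(te_tss),
        "cage_validated": sum(1 for r in te_tss if r.cage_validated),
        "promoter_fraction": prom_frac,
        "tss_fraction": tss_frac,
    }

    # --- stage dynamics -----------------------------------------------------
    expr = usg.read_expression_table(paths["expression"])
    gene_spans = [g.span for g in genes]
    stage_rows = []
    shift_results = []
    for tissue in cfg.tissues:
        dars = dyn.read_dar_table(os.path.join(paths["dar"], f"{tissue}.tsv"))
        acc_ivs = [
            catalog.by_id[t].interval
            for t in sorted(acc.accessible_ids(calls, tissue=tissue))
        ]
        classes = dyn.classify_stage_specific(
            acc_ivs, dars, tissue, cfg.dar_log2fc, cfg.dar_fdr
        )
        stage_rows.extend(classes)
        e14 = expr[(expr.tissue == tissue) & (expr.stage == "E14.5")]
        p0 = expr[(expr.tissue == tissue) & (expr.stage == "P0")]
        expr_e14 = e14.groupby("gene_id")["fpkm"].mean().to_dict()
        expr_p0 = p0.groupby("gene_id")["fpkm"].mean().to_dict()
        shift_results.extend(
            dyn.stage_expression_test(
                classes, catalog, gene_spans, expr_e14, expr_p0, cfg.near_gene_bp
            )
        )
    with open(os.path.join(cfg.out_dir, "stage_classes.tsv"), "w") as fh:
        fh.write("te_id\ttissue\tlabel\tambiguous\n")
        for sc in sorted(stage_rows, key=lambda s: (s.tissue, s.te_id)):
            fh.write(f"{sc.te_id}\t{sc.tissue}\t{sc.label}\t{int(sc.ambiguous)}\n")
    motifs = dyn.filter_motif_results(dyn.read_motif_table(paths["motifs"]))
    report["stages"]["dynamics"] = {
        "stage_specific": sum(1 for s in stage_rows if s.label != "shared"),
        "shift_tests": [
            {"tissue": r.tissue, "label": r.label, "n": r.n, "p": r.p_value}
            for r in shift_results
        ],
        "motifs_passing": sorted(m.motif_id for m in motifs),
    }

    # --- promoter usage -----------------------------------------------------
    expr_flagged = usg.label_te_transcripts(expr, genes, union_intervals)
    te_tss_genes = {r.gene_id for r in te_tss}
    usage_classes = usg.classify_tss_usage(
        expr_flagged[expr_flagged.gene_id.isin(te_tss_genes)], cfg.expr_fpkm
    )
    usg.write_usage_report(usage_classes, os.path.join(cfg.out_dir, "tss_usage.tsv"))
    report["stages"]["usage"] = {
        "category_counts": {
            cat: sum(1 for u in usage_classes if u.category == cat)
            for cat in usg.USAGE_CATEGORIES
        }
    }

    # --- conservation -------------------------------------------------------
    track = cons.ScoreTrack.from_bedgraph(paths["phastcons"])
    sampled = cons.sample_regions(union_intervals, cfg.n_profile_regions, cfg.seed)
    profile = cons.phastcons_profile(sampled, track, chrom_sizes)
    ortho = cons.classify_orthology(cons.read_orthology_flags(paths["orthology"]))
    block = cons.AlignmentBlock.from_fasta(os.path.join(cfg.dataset_dir, "alignment.fa"))
    col_scores = cons.column_conservation(block)
    with open(os.path.join(cfg.out_dir, "conservation_profile.tsv"), "w") as fh:
        fh.write("bin\tmean_score\n")
        for i, v in enumerate(profile):
            fh.write(f"{i}\t{'NA' if v is None else f'{v:.6g}'}\n")
    report["stages"]["conservation"] = {
        "profile_center": profile[len(profile) // 2],
        "profile_edges": profile[0],
        "orthology_counts": {
            cat: sum(1 for o in ortho if o.category == cat)
            for cat in cons.ORTHOLOGY_CATEGORIES
        },
        "alignment_mean_conservation": (
            sum(s for s in col_scores if s is not None)
            / max(1, sum(1 for s in col_scores if s is not None))
        ),
    }

    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report
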