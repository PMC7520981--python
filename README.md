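# opente — accessible transposable elements from ATAC-seq-style data

Transposable elements (TEs) cover roughly half of mammalian genomes, and a
subset of them sit in open chromatin where they act as tissue-specific
regulatory elements and even donate alternative transcription start sites
(TSSs) to genes. `opente` implements, as a tested and reusable pipeline, the
analyses needed to characterize this: calling *accessible TEs* from
open-chromatin peak sets and Tn5 insertion counts, quantifying repeat
*subfamily enrichment*, detecting *TE-derived TSSs* and validating them with
CAGE, classifying *developmental-stage dynamics* (embryonic day 14.5 vs
postnatal day 0), and quantifying *TE-promoter usage* from transcript
expression. It is aimed at regulatory-genomics analysts who have standard
ATAC/RNA/CAGE-style processed tables and want the TE-centric downstream
analysis as a library rather than a pile of one-off scripts.

Because the full mouse-tissue data behind this kind of study needs terabytes
of ENCODE/FANTOM5 input and external tool runs, the package ships a
first-class **synthetic-data generator** that emulates the structure of such
a study — TE subfamilies with planted differential open-chromatin
probability, genes whose furthest-5′ TSS is planted inside an open TE,
tissue/stage-structured peak and insertion libraries, expression and CAGE
signal consistent with the planted promoter usage — together with
machine-readable ground truth, so every stage of the pipeline is scored
against what was planted.

## The statistics at the core

**Accessible-TE caller (two methods).** A TE is accessible in a tissue/stage
if (1) it overlaps an open-chromatin region (OCR) with at least 50% of the
TE and at least 20% of the peak covered by the same intersection (bedtools
`-f 0.5 -F 0.2` joint semantics), or (2) it touches a peak and its Tn5
insertion density exceeds the library's peak-level cutoff. Insertion density
is normalized as

```
IPKM = insertions / (region length / 1000) / (library total insertions / 10^6)
```

and the cutoff is the 25% quantile of the peak IPKMs in each replicate
library; a TE passes if it exceeds the cutoff in any replicate.

**Subfamily enrichment (LER).** For subfamily *j* with `N_j` copies, of
which `obs_j` are accessible,

```
LER_j = log2( obs_j / ( N_j × open_te_bp / genome_bp ) )
```

where `open_te_bp` is the summed length of merged OCRs containing at least
one accessible TE. Subfamilies with `N_j > 10` and `LER_j > 3` are reported
as enriched.

**TE-derived TSS.** A gene's TSS is TE-derived when its furthest-5′ TSS
(minimum transcript start on +, maximum end on −) lies inside an accessible
TE; CAGE peaks validate such TSSs by ≥1 bp overlap with the TE. Per-gene
TE-promoter usage is `Σ FPKM(TE-TSS transcripts) / Σ FPKM(all transcripts)`,
with an independent CAGE-based estimate from peak expression assigned to
TE-derived vs other TSSs.

**Stage dynamics.** Accessible TEs overlapping a differential accessible
region with `|log2FC| > 1` and `FDR < 0.05` are P0-specific (positive fold
change) or E14.5-specific (negative); expression shifts of genes within
20 kb are tested with the Wilcoxon signed-rank test.

**Conservation.** Meta-profiles average a phastCons-style score track in
100-bp bins over 10-kb windows centered on regions of interest; alignment
columns are scored as `max base count / counted bases` (gaps and N
excluded); liftOver-style mapping flags are folded into orthology classes.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic dataset (seed 7; generated under `scratch/` on first use) and
write summary tables to `results/`:

```
cd analysis
python 01_simulate.py
python 02_call_accessible.py
```

prints

```
accessible TE calls: 697 (union 255 TEs)
recall vs planted truth: 0.997
precision vs planted truth: 0.994
  intestine E14.5: 117 called (22 via IPKM rescue)
  ...
```

i.e. the two-method caller recovers 99.7% of the planted open TEs at 99.4%
precision, and the IPKM rescue (method 2) contributes the calls whose peaks
deliberately fail the joint overlap fractions. Continuing,

```
python 03_subfamily_enrichment.py
```

```
enriched subfamilies (copies>10, LER>3): ['SF01', 'SF02', 'SF03'] (planted: ['SF01', 'SF02', 'SF03'])
tissue sharing: {'shared': 115, 'tissue_specific': 118, 'constitutive': 22} (46% single-tissue)
permutation test (TEs in OCRs): observed 255, null max 66, p(enrichment) = 0.0099
```

exactly the three planted subfamilies pass the enrichment filter, the
tissue-sharing split matches the planted distribution (45% single-tissue),
and accessible TEs are enriched in open chromatin far beyond the
chromosome-preserving shuffle null. `04`–`07` detect the 45 planted
TE-derived TSSs (69% CAGE-validated at a planted 60% detection rate),
classify stage dynamics with significant expression shifts near
stage-specific TEs, recover planted per-gene TE-promoter contributions
(expression MAE 0.005, CAGE concordance ρ = 0.97), and show the
conservation dip at accessible-TE centers (0.125 vs 0.484 in the flanks).

The same pipeline is available as a CLI (`opente simulate`, `opente all`)
and as a library (`opente.pipeline.run`).

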