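# Methods

This note documents the models and procedures implemented in `opente`,
the assumptions behind them, the synthetic data they are exercised on,
and the numerical choices that were genuinely open.

## Coordinate and annotation model

All intervals are BED-convention: 0-based, half-open `[start, end)`.
GTF input (1-based inclusive) is converted on read. A transcript's TSS
is its 5′-most coordinate in this convention — `start` for + strand,
`end` for − strand — and every promoter, TSS-containment and CAGE
assignment computation uses that single definition, so the two strands
are exact mirrors of each other.

The TE annotation filter removes simple repeats, satellites and
low-complexity records, plus any copy shorter than 100 bp. Grouping
low-complexity with simple repeats is a deliberate choice (annotation
pipelines split them into separate classes, but neither is a
transposon); the dropped-class set is a parameter for users who want a
different slice. RepeatMasker class variants (`LTR?`, `DNA?`, `RC`, …)
are normalized onto the four major classes LINE/SINE/LTR/DNA plus
`other`.

## The accessible-TE caller

Accessibility is decided per (tissue, stage), with replicate peak sets
merged first (mergeBed semantics, distance 0: book-ended intervals
merge).

* **Method 1 (overlap).** A TE is called when one contiguous TE–peak
  intersection covers ≥50% of the TE *and* ≥20% of the peak. Both
  fractions are evaluated on the same intersection (bedtools joint
  `-f`/`-F` behaviour); this matters for long peaks, where per-flag
  evaluation would be more permissive.
* **Method 2 (IPKM rescue).** TEs that touch a peak by ≥1 bp but fail
  the fractions are re-examined via insertion density. IPKM is
  insertions per kilobase of region per million library insertions;
  insertions are point events (the Tn5 cut site), and an insertion at
  position *p* belongs to `[start, end)` iff `start ≤ p < end`. The
  cutoff is the 25% quantile (linear interpolation between order
  statistics, the numpy default; nearest-rank would differ by at most
  one order statistic) of the merged-peak IPKMs, computed separately in
  each replicate library; a TE is rescued if it exceeds the cutoff in
  *any* replicate. Restricting method 2 to peak-touching TEs is a
  deliberate reading of "remaining TEs": evaluating every genome-wide TE
  would flood the rescue with background regions whose IPKM is noise.

Both methods are invariant under uniform sequencing-depth rescaling:
IPKM is a ratio, and the cutoff is computed from the same library.
Method-1 calls that also exceed the cutoff are labelled `both`;
the union of methods is the accessible set.

## Enrichment statistics

**LER.** `LER_j = log2(obs_j / (N_j · open_te_bp / genome_bp))`. The
"length of open regions with TE" term is operationalized as the summed
bp of merged OCR peaks containing ≥1 accessible TE; an alternative
(summed accessible-TE bp) gives systematically smaller denominators and
is not used. Subfamilies with zero accessible copies get LER = −∞.
The enrichment filter is strict on both rules as printed: copies > 10
and LER > 3. LER is computed here on the pooled (union) accessible set;
per-tissue use is a matter of passing per-tissue id sets.

**Feature enrichment** divides, per genomic feature (first exon, exon,
intron, intergenic), the number of accessible TEs overlapping it by the
number of all TEs overlapping it; a feature with no TEs at all is
undefined (reported missing), not zero. First exons are the
strand-aware 5′-most exon per transcript and also count as exons;
intergenic means no gene-body overlap whatsoever.

**Permutation overlap test.** The statistic is the number of query
intervals with ≥1 bp reference overlap. The null re-places each query
interval uniformly on its own chromosome with its length preserved
(start drawn from `[0, chrom_len − len]`), 100 permutations by default.
Chromosome-preserving uniform shuffling is the simplest defensible
null; richer spatial-correlation batteries (relative distance,
projection, Jaccard) are out of scope. Empirical p-values use the
add-one convention `p = (1 + #{null ≥ obs}) / (1 + n_perm)` so p is
never 0; the two-sided p is `2·min(enrich, deplete)` capped at 1. Under
a simulated null the p-values are approximately uniform (checked by KS
test in the acceptance suite).

## TE-derived TSSs and promoter usage

A gene's furthest-5′ TSS is the minimum transcript TSS on + (maximum on
−), across all transcripts of all types of that gene; one TSS is
attributed per gene. A (TE, gene) record is emitted when that position
lies inside an accessible TE; a TE hosting the TSSs of two genes yields
two records with no arbitration. Promoters are the 500 bp upstream of
the furthest-5′ TSS, clipped at chromosome bounds. CAGE validation
requires ≥1 bp overlap between the hosting TE and any CAGE peak.

For usage, transcripts are labelled TE-derived when their *own* TSS
lies inside an accessible TE. A gene is expressed when its
replicate-mean total FPKM exceeds 0.1 in at least one tissue/stage; the
expressed-transcript threshold within a tissue is FPKM > 0 (the
published rule thresholds genes, not transcripts; the transcript
threshold is a config knob). Categories: all expressed transcripts
TE-derived → `te_only`; none → `non_te_only`; a mix → `both`. The
TE contribution is the TE-derived share of gene FPKM (scale-invariant);
the CAGE-based contribution assigns peaks by 1-bp overlap to the
TE-derived TSS (via its hosting TE's TSS position) or to the gene's
other transcript TSSs and ignores unassigned peaks.

## Stage dynamics

Differential accessible regions (DARs) are an *input contract* —
interval, log2 fold-change (P0 vs E14.5), FDR — produced upstream by a
count-based differential test; this package does not reimplement
dispersion-aware testing. A small self-test helper
(`naive_differential`: log2 CPM ratio with add-0.5 pseudocount,
BH-adjusted binomial test) exists for synthetic data only and is not
equivalent to a negative-binomial fit.

A passing DAR has |log2FC| > 1 and FDR < 0.05. An accessible TE
overlapping (≥1 bp) a passing DAR takes the sign of the fold change
(positive → P0-specific); a TE hit by passing DARs of both signs takes
the larger |log2FC| and is flagged ambiguous (possible for long TEs;
the choice is a tie-break, not a claim). Everything else is `shared`,
so the three labels partition the accessible set per tissue.

Expression shifts are tested per (tissue, label): each stage-specific
TE is assigned to its nearest gene within 20 kb (gap distance between
closest edges, strict bound, ties broken by genomic order), genes are
deduplicated (a gene near two TEs is counted once), and the paired
(E14.5, P0) expression values go into a two-sided Wilcoxon signed-rank
test. Zero differences are dropped; the exact null is used for n ≤ 25
and the normal approximation with continuity correction above that
(the two agree within |Δp| < 0.02 at the crossover in the test suite);
fewer than 5 informative pairs is reported as underpowered with a
missing p rather than a number.

Motif-enrichment tables are consumed, not produced; the selection rule
keeps rows with ≥10% of target regions containing the motif
(inclusive, "at least"), match score > 0.9 and p < 1e-11 (both strict).

## Conservation

Alignment-column conservation is `max(base count among A/T/C/G) /
(count of A/T/C/G)`; gaps and N are excluded from numerator and
denominator, and a column with no counted base is missing. The score
is in (0, 1], equals 1 iff all counted bases agree, and is ¼ at worst
for a gap-free 4-row column.

Meta-profiles take a 10-kb window centered on `floor((start+end)/2)`
(no rounding rule is canonical; floor is fixed here), split it into
100-bp bins, average the track over covered bases per bin, and average
bins across regions. Bases without track coverage are *missing*, not
zero (a zero-fill flag would bias dips downward); windows running past
a chromosome end are skipped with a warning. Region sampling for large
inputs is seeded and reproducible.

Orthology classification is pure bookkeeping over liftOver-style
mapping flags: rat and human → shared_all, rat only → rodent_specific,
neither → mouse_specific, human only → a flagged anomaly class.
`project_coords_through_alignment` maps ungapped coordinates of one
alignment row onto another (positions landing on a destination gap are
missing), which is what is needed to transfer motif-hit coordinates
across aligned TE copies.

## The synthetic dataset

The generator emulates the *structure* of a multi-tissue developmental
open-chromatin study at desk scale: 2 chromosomes × 5 Mb, 5 000 TEs
(uniform 150–3 000 bp, placed without overlap), 30 subfamilies of which
3 are planted enriched (open probability 0.8 vs 0.03 background, ≥8×),
3 tissues × 2 stages × 2 replicates, 300 genes of which 15% have their
furthest-5′ TSS planted inside an open TE. Tissue sharing of open TEs
is drawn as 45% single-tissue / 45% two-tissue / 10% all-tissue;
30% of per-tissue open TEs are stage-specific with a true |log2FC| of 2.
Per-gene usage categories are planted 60/35/5 (te_only/both/non_te_only),
with the `both` contribution drawn uniformly in (0.1, 0.9); CAGE covers
a gene with probability 0.6, with peak counts Poisson around 50× FPKM.
Expression is log-normal (ln-scale μ=1, σ=1) with multiplicative
replicate noise (σ=0.08); genes nearest to stage-specific TEs get a 2×
shift in the corresponding stage. The conservation track is ~0.5
baseline with a planted dip (~0.12) across open TEs.

Insertion signal is planted at a *density* of 0.02 insertions/bp of
open TE (≈30 insertions for an average 1.5-kb copy, Poisson), over a
genome-wide background of 0.002/bp; non-TE noise peaks carry 0.012/bp.
A constant per-TE count regardless of length would make the IPKM of
long rescued TEs indistinguishable from noise peaks, which is an
artifact of small synthetic libraries rather than of the method, so
density is the planted quantity. 15% of open TEs get peaks that
deliberately fail the 50%/20% joint fractions (recoverable only via
IPKM), exercising both arms of the caller; 1% of closed TEs get weak
"decoy" peaks touching 20% of the TE, which the IPKM cutoff must
reject. Peak geometry is shared between replicates of a tissue/stage
(a called peak has signal in both replicates); insertions are drawn per
replicate. All randomness flows from one seed through named substreams
(te, genes, atac, expr, cage, cons, misc), and a fixed config is
byte-reproducible.

What the generator does **not** emulate: sequence content (no read- or
motif-level signal), mappability and GC artifacts, overlapping/nested
TE copies, peak-caller boundary noise beyond simple jitter, biological
replicate variability beyond log-normal expression noise, and
dispersion structure in the DAR tables (they are drawn from the planted
truth with noise). Passing tests therefore demonstrate that the
*implementations* are correct against planted truth and exhaustive
oracles — not that the thresholds would behave identically on real
libraries.

## Problem sizes and defaults

The default dataset (5 000 TEs, 12 libraries, ~25 000 insertions per
library) generates in about two seconds and the full pipeline runs in a
few more; the acceptance script regenerates everything from one seed in
under ten seconds. These sizes were chosen so that planted effects sit
comfortably above sampling noise (e.g., ~60 copies per enriched
subfamily gives LER ≈ 4 against the >3 filter) while the whole study
remains interactive.

## Known limitations

* The caller's precision/recall guarantees are measured under the
  generator's noise model; heavy-tailed insertion noise or peak-caller
  artifacts could shift the IPKM cutoff behaviour.
* LER uses a genome-fraction expectation; subfamilies with strong
  length or compositional biases relative to open regions would need a
  stratified expectation.
* The permutation null shuffles only within chromosomes and ignores
  mappability/blacklist structure.
* CAGE assignment is purely positional (1-bp overlap); promiscuous CAGE
  peaks spanning two close TSSs are credited to the TE-derived one.
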