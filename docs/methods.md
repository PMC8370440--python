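# Methods

`fracir` analyses intron retention in poly(A) RNA-seq of nuclear and
cytoplasmic fractions: it quantifies percent intron retention (PIR) per
sample, detects genotype-dependent (aberrant) retention per fraction and
timepoint, classifies events by their nucleocytoplasmic distribution,
and characterizes the classes by cis sequence features and RBP
crosslink-event enrichment. A seeded generator with planted ground
truth emulates the fractionated time-course design used for testing and
calibration.

## Retention quantification

Reads informative for one intron fall into four classes: **EI** — a
contiguous alignment across the transcription-order 5′ exon–intron
boundary with at least `min_overhang` (default 8) aligned bases on each
side; **IE** — the same at the 3′ intron–exon boundary; **EE** — a split
alignment whose skipped segment equals the intron exactly; **body** — an
alignment fully inside the intron. Per (read, intron) the priority is
EE > EI/IE > body; a read contiguously spanning a whole short intron
counts once, as EI. The retention estimate is

    PIR = 100 · mean(EI, IE) / (mean(EI, IE) + EE)

Averaging the boundary counts treats both boundaries symmetrically and
is robust to one noisy boundary. A cell is reported missing when
EI + IE + EE < `min_junction_reads` (default 10). Body counts feed only
the fractionation-leakage QC, keeping the estimator purely
junction-based and exactly testable against read-level round trips.

The estimator is consistent under a molecule model: a transcript
retains the intron with probability *p* (the true PIR as a fraction) or
is spliced; a retained molecule presents two junction-informative
boundaries where a spliced one presents one EE junction, so junction
reads hit the retention arm with probability ρ = 2p/(1+p), and
mean(EI,IE)/(mean(EI,IE)+EE) → p.

## Differential retention

Per fraction × timepoint stratum, counts are pooled across lines within
genotype and each intron is tested with a two-sided Fisher exact test
on [[EI+IE, 2·EE]ctrl, [EI+IE, 2·EE]mut]. The splicing arm is doubled
because one retained molecule contributes two boundary reads while one
spliced molecule contributes a single EE read; doubling balances the
per-molecule evidence (switchable to raw EE). Benjamini–Hochberg
correction is applied within the stratum. An event is significant when
q < 0.05, |ΔPIR| ≥ 10 percentage points, pooled junction coverage ≥ 20
per genotype, and the per-line PIR difference agrees in sign with the
pooled estimate in at least ⌈2/3⌉ of control×mutant line pairs — the
consistency filter replaces per-line modelling and guards against
single-line artifacts. All four thresholds are config-exposed; the
defaults are explicit stand-ins, since published event lists rarely
state their exact cutoffs.

## Nucleocytoplasmic taxonomy

At one timepoint (by default the stratum with the most significant
events — the analysis peak), significant inclusion events are
partitioned by where they reach significance: nuclear only →
*nuclear_predominant*; cytoplasmic only → *cytoplasmic_predominant*;
both → *both_compartments*. Skipped-direction events are excluded. The
rule-based partition is a surrogate for manual curation; an override
list (include/exclude with a forced category) reproduces hand curation
when available. An intron untested in one fraction is classified from
the tested fraction and flagged low-confidence.

Category-wise retention in an external PIR dataset is compared between
genotypes with a **line-stratified permutation test**: per-line mean
retention over the category's introns is the exchangeable unit and
genotype labels are permuted across lines — exhaustively when C(n, k)
assignments are enumerable, otherwise by a seeded random subset. This
replaces a linear mixed model with an exact, assumption-light procedure
that respects line-level pseudoreplication; the cost is reduced power
at very small line counts (with 3+3 lines the smallest attainable
two-sided p is 0.1).

## Cis features and expression coupling

Per intron: length; GC fraction (N bases excluded from numerator and
denominator; reported as % in outputs); mean per-base conservation from
a bedGraph track (length-weighted over covered bases, missing below 50%
coverage; mean rather than median, config-switchable). Categories are
compared pairwise and against the background of **all introns of genes
hosting ≥ 1 aberrant event** with two-sided Mann–Whitney tests — exact
enumeration for untied groups of ≤ 12, normal approximation with tie
correction otherwise — BH-corrected across comparisons. Host-gene
expression coupling reports per category × fraction the distribution of
log2 fold-changes of genotype-mean log2(CPM+1) with a sign test against
zero.

## RBP crosslink enrichment

The enrichment score of an RBP in an intron is a pseudocounted log2
density ratio against the background introns:

    density_i = events with midpoint inside intron i / length_i   [events/kb]
    score_i   = log2((density_i + c) / (median background density + c)),  c = 0.1

The midpoint rule treats crosslink events as point-like and avoids
double counting at boundaries; stranded events on the opposite strand
are ignored, strandless BEDs match both. RBPs are ranked by a
Mann–Whitney test of cytoplasmic-category vs nuclear-category scores,
BH across RBPs; *enriched* requires q < 0.05 and a positive median
difference.

The score is only informative when typical introns carry more than a
handful of events: at sparse densities the per-intron density of short
introns is zero-inflated, which shifts its median relative to long
introns and biases any rank comparison between length-imbalanced
categories. The synthetic generator therefore defaults to a background
of 20 events/kb (tens of contacts per intron, as seen in iCLIP tracks
of abundant RBPs); with real sparse tracks, users should aggregate
related tracks or interpret the ranking cautiously.

## Synthetic study design

Defaults encode the emulated design: 4 control and 3 mutant lines, six
timepoints (DIV 0, 3, 7, 14, 22, 35), nuclear and cytoplasmic fractions
per sample; 700 genes with 2–4 introns each (≈ 2100 introns); planted
aberrant events in 237 nuclear-predominant, 63 both-compartments and 49
cytoplasmic-predominant introns, each +25 PIR percentage points in the
affected fraction(s), scaled by a triangular ramp that is zero at the
first and last timepoints and peaks at DIV 14 (per-day magnitudes are
not published, so the simplest peaked profile is used). Baseline PIR is
Beta-distributed (nuclear mean 0.20, cytoplasmic mean 0.08 — retention
is nuclear-biased at baseline). Junction depth per intron per sample is
negative-binomial (mean 100, dispersion 0.05 — pooled per-genotype
depth ≥ 400/300); retention reads split EI/IE as Binomial(½).
Fractionation leakage mixes the nuclear retention signal into
cytoplasmic samples on the retention-arm scale (default 5%).
Housekeeping genes (5) have zero baseline cytoplasmic retention,
emulating a cytosolic marker whose intronic RNA is nuclear-only. 72
designated splicing-factor genes are down-shifted by −1 log2 unit in
mutant cytoplasm at the peak timepoint. Cis features per category:
log-normal lengths with medians 300 (nuclear) / 1500 (both) / 2000
(cytoplasmic) / 800 (background) nt; GC targets 0.60 / 0.45 / 0.40 /
0.50; conservation base 0.40 with +0.25 in cytoplasmic-predominant
introns. 27 of 100 RBPs receive a 4-fold crosslink-density increase
inside cytoplasmic-category introns over a 20 events/kb background.
Every artifact (counts, FASTA, GTF, BED, bedGraph, SAM) is a
deterministic function of the seed; each RBP track uses its own
substream so a track depends only on its own parameters.

What the generator does **not** emulate: realistic read sequences and
qualities, positional coverage bias, PCR duplicates, multi-mapping,
overlapping genes, alternative splicing classes other than intron
retention, and line-level biological heterogeneity (the per-line jitter
defaults to zero, so the pooled Fisher test is exactly calibrated; with
real lines the sign-consistency filter carries that burden). Passing
the planted-recovery checks therefore demonstrates correctness of the
estimators and decision rules under the assumed counting model, not
robustness to those unmodelled features of real data.

## Numerical choices and degenerate inputs

Fisher tables with a zero margin return p = 1 with a degenerate flag.
Fully tied Mann–Whitney inputs return p = 1. PIR is undefined (missing)
at zero junction coverage. True PIR values are clipped to [0, 0.97] so
planted shifts never saturate. Strata missing a genotype are skipped
with a warning; groups below 3 members skip their comparison with a
flag. SVD uses gene-centered (optionally unit-variance) values;
variance fractions are squared singular values over their sum.
Clustering uses 1 − Spearman correlation with complete linkage;
dendrograms serialize to Newick. Ties in the RBP ranking are broken by
name for determinism.

## Problem sizes used in the checks

The packaged checks run the full default design (≈ 2100 introns × 84
samples), a null design of the same size for calibration, 20 seeds of
null RBP rankings, and a reduced (150-gene) end-to-end pipeline for
byte-level determinism. These sizes give stable recovery and
calibration estimates at desk scale; all scale linearly for larger
configurations.

## Known limitations

Real-data mode expects junction counts, a sample sheet and an intron
BED produced upstream; the included SAM counter is exact but
single-threaded and intended for moderate files. The taxonomy is a
strict significance partition — a large but sub-threshold ΔPIR in the
other fraction does not block a "predominant" call; the override list
is the escape hatch. The permutation test's resolution is limited by
the number of lines. GC and conservation are the only sequence-level
features; splice-site strength and structure are out of scope.
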