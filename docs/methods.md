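# Methods

## Scar metrics

The package computes the three canonical HRD scar metrics from
allele-specific copy-number segments and reports their sum (HRDsum).
Segments carry a total and a minor-allele copy number on a genome model of
chromosome lengths and centromere intervals; coordinates are converted to
0-based half-open on input (segment tables use the 1-based inclusive
seg-file convention), so length is always `end − start`.

**LOH.** A region is a maximal run of consecutive segments with
minor CN = 0 and total CN > 0. Its length is the *sum* of segment lengths
in the run rather than the genomic span, which keeps WES coverage gaps from
inflating region sizes. Regions longer than `loh_min_len` (default 15 Mb,
strict >) count, except a region covering every observed segment of its
chromosome ("whole chromosome"). Whole-chromosome status is defined
against the observed segments, not the nominal chromosome length, because
exome-derived calls never reach the literal ends.

**LST.** Each chromosome is split at the centromere; a segment spanning it
contributes its clipped pieces to both arms, which automatically prevents
counting a centromere-spanning breakpoint. Abutting equal-state segments
are merged first, so counts are invariant under refinements of the
segmentation. Per arm, segments shorter than `lst_smooth_len` (3 Mb) are
removed and flanking equal-state segments rejoined when the resulting gap
is below the smoothing window. Every junction between remaining adjacent
segments with both flanks ≥ `lst_min_flank` (10 Mb, inclusive) and
inter-segment gap < 3 Mb counts as one transition. Smoothing is a single
pass (filter, then rejoin); this is deterministic and differs from
iterative removal only for pathological stacks of sub-3 Mb segments.

**TAI.** A region is a maximal run of allelic imbalance
(minor ≠ major CN). It counts when it reaches a chromosome end within
`telomere_tolerance` (1 kb — WES segments rarely touch position 0 or the
chromosome length), has no observed bases on both sides of the centromere,
and does not span the whole observed chromosome; at most two regions per
chromosome (one per telomere). A region crossing the centromere is
excluded outright — the canonical telomeric-AI rule — rather than split
into arm-level halves, which would wrongly promote the telomere-reaching
half. An optional minimum region length (`tai_min_len`, default 0) is
exposed because published implementations differ on whether one exists.

All four lengths live in `ScarParams` and are parameters, not constants.

## Harmonization

Scores from different copy-number sources are merged in three steps:
per-sample medians over the samples present in every dataset; a per-dataset
least-squares fit of a natural cubic spline basis (patsy `cr`, default
df = 4, knots at quantiles of the raw scores) predicting those medians from
raw scores; transformation of all scores, clamping at 0 (HRDsum is a
count), and per-sample averaging. Natural splines are linear beyond the
boundary knots, so extrapolation is the linear extension of the fit —
important because non-consensus samples can exceed the fitted range. The
spline span contains affine maps exactly, so identical datasets are a fixed
point of the whole procedure (verified to 1e-6). df is configurable; 4 is
a smooth default and the fit requires at least df + 2 common samples and
non-constant raw scores.

## Classification

The HRD cutoff is the interpolated 5th percentile (linear interpolation
between order statistics, the common statistical-environment default) of
summary scores among deficiency-labeled samples, rounded to the nearest
integer because the cutoff is conventionally reported as an integer; the
unrounded value is retained alongside. Score ≥ cutoff ⇒ HRD-high
(inclusive). CHORD-probability classification is strict: p > 0.4 ⇒ HRD,
and MSI samples are excluded before classification because indels in
repeat regions dominate the mutation-context signal in MSI genomes.

## Gene labels

Deficient: any mutation with allele frequency > 0.85 (homozygosity proxy)
that is ClinVar-pathogenic or VEP HIGH-impact, or a deep deletion. ClinVar
matching is a case-insensitive containment of "pathogenic" excluding
"conflicting" and "benign". Proficient: no mutations of any kind (silent
variants included — the rule is deliberately unqualified), no deep
deletion, and expression above the gene's lower quartile of log2(TPM+1).
Likely silenced: expression below the lower quartile and promoter
methylation fraction > 0.3. Deficiency takes precedence over silencing
over proficiency, making labels mutually exclusive. Literature knowledge
(reversion events, methylation reported outside the input tables) enters
only through an explicit overrides mapping, never hard-coded.

## Variant filtering and contexts

Variants are normalized before anything else: multiallelic records are
decomposed, multi-nucleotide substitutions are split into their
constituent SNVs, and indels are parsimony-trimmed and left-aligned
against the reference (vt-style). Cohort-recurrence keys
(chrom, pos, ref, alt) therefore compare normalized representations. The
small-variant filter is a pure conjunction — panel-of-normals flag,
population blacklists (gnomAD/dbSNP/known indels), recurrence in ≥ 3 cell
lines, non-PASS status, allele frequency < 0.1, and quality below 240
(low-confidence regions) or 170 (high-confidence) — so rule order cannot
matter. Records outside any confidence region use the stricter 240 cutoff.
Structural variants additionally require quality ≥ 1,000 and assembly
support from both breakpoint sides (AS > 0 and RAS > 0).

Breakend pairs are canonically ordered and classified by orientation:
(+,−) deletion, (−,+) tandem duplication, (+,+)/(−,−) inversion on one
chromosome, translocation across chromosomes; intrachromosomal lengths are
`pos2 − pos1` and are binned per decade (1–10 kb, 10–100 kb, …) for
context counts.

Indel contexts: an indel is *repeat-type* when its sequence is k ≥ 1
tandem copies of a primitive unit that continues for at least one further
copy immediately 3′ in the reference, totalling ≥ 2 copies;
*microhomology-type* when ≥ 2 bp of its 5′ end match the reference
immediately 3′ of the variant; otherwise *none*. Repeat takes precedence
over microhomology (a full-length flank match is one extra copy of the
unit). Both minima are parameters. SNVs are assigned to the 96
pyrimidine-strand trinucleotide classes; flanks containing non-ACGT bases
are excluded from counts. MSI is called when the repeat-region indel count
reaches 10,000 (the threshold is a minimum, hence ≥; the comparator is a
parameter because published descriptions are ambiguous one unit apart).

## Statistics

Fisher enrichment tests each gene's 2×2 table of deficiency × HRD with the
one-tailed "greater" alternative (the question is enrichment of deficiency
among HRD lines), restricted to genes deficient in at least one HRD line,
with Benjamini–Hochberg adjustment across included genes. Pearson scans
use pairwise-complete observations per feature, exact t-distribution
p-values on n − 2 df, and report constant features as NA outside the BH
adjustment. Quartile binning uses interpolated breaks with ties assigned
to the lower bin; degenerate breaks collapse bins and the Kruskal–Wallis
test then runs on the surviving groups (H is defined as 0 when every
response is tied). Noncancerous and MSI samples are excluded centrally by
the feature-table mask so every scan obeys the same rule. CRISPR screens:
guide-level log2 fold changes with pseudocount 1, median-centered per
replicate, averaged across replicates, gene score = median over guides.

## Dose–response

Responses are absorbances normalized to the mean of control wells,
expressed as inhibition fractions. The primary model is
y = 1 − 1/(1 + 10^(10^b (x − a))) with x = log10 concentration (nmol/L);
the exponent is read as 10^b · (x − a), making the slope 10^b positive and
the curve increasing with midpoint a — consistent with the fallback
model's |b| device; a flag switches to the 10·b reading if ever needed.
IC50 = 10^a nmol/L and y(a) = 0.5 identically. Fitting is bounded least
squares with multistart over a (spanning the observed dose range) and b;
failure of every start triggers the fallback y = 1/(1 + e^(−|b|(x − a))),
whose reported IC50 convention is the parameter a itself (a log10
concentration); the fit records 10^a alongside for comparability, and
sensitivity voting uses the nmol/L scale on both paths. Maximal response
is the maximum *observed* inhibition, not the model asymptote — the
conservative reading for partial-efficacy compounds. A line is sensitive
when ≥ 66% of replicates show IC50 < 1 µmol/L and maximal response
> 75%, insensitive when ≥ 66% show IC50 ≥ 1 µmol/L and maximal response
< 35%, otherwise excluded; 2 of 3 replicates (66.7%) qualifies.

## Synthetic data

All generators use the counter-based Philox RNG with a single recorded
integer seed, so outputs are reproducible across platforms. The
copy-number planter lays a diploid heterozygous baseline (total 2,
minor 1) and assigns each requested event its own chromosome arm: LOH
events are interior 16–24 Mb copy-neutral LOH segments isolated by 4 Mb
coverage gaps (above the 3 Mb smoothing window, so their boundaries are
never transitions); LST events are 12–20 Mb segments at a different copy
state abutting baseline on exactly one side; TAI events are 16–20 Mb
imbalanced segments anchored at telomeres. Because events are
non-interacting by construction, planted counts are unambiguous; property
tests additionally compare random profiles against an independent
brute-force oracle. The score-matrix generator draws truth scores from a
gamma distribution (shape 1.5, scale 15 — a realistic right-skewed HRDsum
distribution putting roughly a tenth of lines above the high-score range)
and applies monotone distortions plus Gaussian noise (default sd 3); the
recovery analyses use full overlap so every sample is in the consensus
set. The variant planter engineers reference windows so each planted indel
has exactly its intended context and each violation record fails exactly
one filter rule. Plates are sampled from the primary dose–response model
on the assay's 10-point 1:3 dilution grid from a 10 µmol/L top dose, with
an optional amplitude cap emulating partial-efficacy compounds.

What the generators do *not* emulate: real segment-size and copy-number
distributions, interacting or nested scar events, sequencing-error
signatures, mutational-signature composition, plate edge effects, or
batch structure beyond per-dataset monotone distortion. Passing tests
therefore demonstrate correctness of the counting, filtering, fitting and
testing rules under controlled conditions, not calibration against
empirical cell-line panels.

## Problem sizes

The validation analyses use 200 simulated genomes for scar recovery, 300
samples × 3 datasets for harmonization, exhaustive 2×2 enumeration to
total n = 60 in the test suite (n = 45 in the acceptance script), 1,000
random vectors for the BH check, 2,000 permutations for type-I error
calibration, and 50 noisy repetitions for IC50 recovery — sizes chosen so
the full validation completes in about a minute while keeping every check
exact or tightly powered.

## Known limitations

- Scar-metric definitions follow the canonical published forms; the exact
  smoothing order of specific legacy implementations may differ in corner
  cases (stacked sub-3 Mb segments).
- Spline knot placement and degrees of freedom for harmonization are
  conventions (quantile knots, df 4), configurable but not inferred.
- The filter cascade consumes caller annotations (quality, confidence
  region, assembly support) as given; it does not recompute them.
- CHORD probabilities are inputs; the random-forest classifier itself is
  out of scope, as are read alignment, variant calling, and
  variant-effect prediction.
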