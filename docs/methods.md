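# Methods

This note records the models, statistics and design choices behind each
somascape module: what is computed, under which assumptions, which knobs
matter, and what the synthetic-cohort validation does and does not show.

## Coordinate and channel conventions

SNV positions are 1-based (VCF); SV breakends are 1-based breakend pairs;
copy-number segments are 0-based half-open, which makes length arithmetic
and fixed-bin assignment unambiguous. All substitutions are normalized to
the pyrimidine strand, giving six substitution classes and 32
pyrimidine-centred trinucleotides; the 96 SNV channels are ordered
substitution-class major, flanks lexicographic minor. The 32 SV channels
are {del, dup, inv} × {1–10 kb, 10–100 kb, 100 kb–1 Mb, 1–10 Mb, ≥10 Mb} ×
{clustered, non-clustered} plus translocations × {clustered,
non-clustered}. Size bins are half-open `[low, high)` so a 10 Mb event
falls in the top bin; sub-kilobase sizes are clamped into the lowest bin
with a logged warning. Trinucleotide context travels in the VCF INFO tag
`TNC`, so no reference FASTA is ever required (one may be supplied when
the tag is absent).

## Mutational signatures

Catalogues are raw counts (totals conserved by construction). De novo
extraction is Frobenius NMF with multiplicative updates (scikit-learn,
`solver="mu"`), best of 50 random restarts by reconstruction error, with
tolerance 1e-6 and up to 10,000 iterations; factor rows are renormalized
to probability vectors with exposures rescaled. The Frobenius objective is
the simplest defensible choice here and all validation is
objective-agnostic. The signature count k is a configuration value (an
error/stability sweep can be run over a k range); no automatic selection
rule is claimed.

Exposure refitting minimizes ‖m/‖m‖₁ − Sᵀe‖₂² over the probability
simplex. For k ≤ 12 the programme is solved exactly by support
enumeration: each candidate support's equality-constrained KKT system is
solved and the best primal-feasible solution wins; beyond that, SLSQP with
analytic gradient takes over. Tests cross-check the solver against a dense
simplex grid search at 0.01 resolution.

Pruning applies the sub-threshold rule iteratively and smallest-first:
while any retained exposure is below the threshold (default 0.10) and more
than one signature remains, the smallest such exposure is dropped (ties by
signature order) and the sample is refit on the remaining signatures. A
single pass is not guaranteed to reach a fixed point, so iteration is the
well-defined reading; rows stay on the simplex throughout. The pruning
rule is applied to substitution signatures only — rearrangement-signature
exposures are left untouched and thresholded downstream by the presence
rule instead.

Reference catalogues are supplied as TSV (channels × signatures); no
third-party catalogue is embedded. `simulate.reference_signatures` draws
sparse Dirichlet(0.2) profiles, which are near-orthogonal and hence
well-identifiable — real signature catalogues are more collinear, so
recovery on synthetic references is an upper bound on real-data
performance. Rearrangement-signature matches with cosine below 0.80 keep
the reference name with a "-like" suffix, mirroring the convention of
flagging divergent matches.

## Kataegis

For each sample, fixed windows (default 10 kb, step 5 kb) are tested by
the exact binomial upper tail of the window's mutation count under a
per-bp rate equal to the sample's chromosome-wide rate; per-window
trinucleotide-composition binomial tests against the genome model's
chromosome trinucleotide frequencies are available behind a flag.
P-values are BH-adjusted pooled across all windows of the sample (not per
chromosome — the locus family is the sample). Overlapping significant
windows merge; a merged region is a locus iff it carries ≥ 6 mutations at
mean inter-mutation distance ≤ 2 kb. The hypermutation score is the locus
mutation density over the chromosome density; the APOBEC score is the
fraction of member SNVs that are C>T/C>G at TCA/TCT context, with class
APOBEC at score ≥ 0.5 (boundary inclusive). Window size, step, minimum
mutations, maximum IMD, FDR cut and APOBEC cutoff are all configuration
values. These scores are documented equivalents of the upstream
hypermutation/APOBEC scoring tools whose exact formulas are not public, so
absolute locus counts are tool-specific; the validated claims are
sensitivity ≥ 0.8 on planted clusters and ≤ 5% of uniform-background
replicates producing any locus.

## Co-localization

APOBEC loci and SV breakends are pooled cohort-wide into fixed 1 Mb bins
(a locus increments every bin it overlaps; each SV contributes both
breakends). A bin is co-localized when its kataegis count AND its breakend
count are strictly greater than the genome-wide per-bin means — the
simplest self-consistent reading of "more than the mean of the
distribution for both events"; a z-score cut (mean + z·sd) is available
via `coloc_z_threshold` for a stricter Gaussian reading. The genome-wide
mean frequency is the mean over chromosomes of per-chromosome flagged-bin
percentages, and a chromosome is enriched when its frequency strictly
exceeds that mean (recomputed per cohort, never a constant; a
single-chromosome genome can therefore never be enriched). The kataegis
frequency entering the combined percent is the proportion of cohort
samples with ≥ 1 APOBEC locus on the chromosome (a locus-share variant is
available via `coloc_freq_mode`); combined percent multiplies the two
factors as proportions and chromosomes are ranked descending with ties
sharing the minimum rank.

## Copy number and HRD

Ploidy is the length-weighted mean total copy number over covered bases
(a warning fires below 90% coverage). Percent genome altered counts bases
with total CN ≠ 2; a ploidy-relative baseline is a config flag, the
absolute baseline being the simpler default reading. Sub-clonal CNA
percentages count only segments with sub-clonal q below the FDR cut
(default 0.05), dividing summed lengths by chromosome and genome lengths.

HRD components follow the standard genomic-scar conventions: LOH counts
segments with minor allele 0 (total CN > 0) longer than 15 Mb that do not
span a whole chromosome; tAI counts allelic-imbalance segments reaching a
telomere, not crossing the centromere, longer than 11 Mb; LST counts
transitions between adjacent segments in different copy states with both
flanks ≥ 10 Mb, after smoothing away segments < 3 Mb (equal-state
neighbours merge). All four length thresholds are configuration values.
HRD-sum is the unweighted sum; the sample-level call requires HRD-sum > 42
AND an externally supplied HRDetect probability > 0.7 (the trained
classifier is consumed, never recomputed); with the probability absent and
HRD-sum above threshold the call is *indeterminate*.

## Complex events

Intra-chromosomal SVs are intervals; two SVs *interleave* when their
intervals overlap without one containing the other, and clusters are
connected components of that graph. Oscillation counting reports the
longest run of consecutive segment-state alternations confined to ≤ 2
(and separately ≤ 3) distinct total copy numbers, as alternation steps.
Three statistics complete the evidence, each BH-adjusted within its own
family across the cohort:

* chromosomal enrichment — binomial upper tail of the chromosome's
  breakpoint count with success probability = chromosome length / genome
  length (family: sample-chromosomes);
* exponential spacing — Kolmogorov–Smirnov goodness of fit of
  inter-breakpoint distances to the exponential with estimated rate, using
  the Lilliefors correction so the p-value is calibrated despite the
  estimated parameter (family: tested regions). In the calling step the
  spacing family is the chromosome's breakpoints anchored at the
  chromosome ends, so a locally clustered breakpoint set — the
  chromothripsis expectation — yields a small q, while dispersed
  breakpoints fit the exponential;
* fragment joins — multinomial goodness of fit of the four join types
  (deletion-like, duplication-like, head-to-head and tail-to-tail
  inversion) against equal proportions, chi-square with a seeded
  Monte-Carlo fallback when expected counts drop below 5 (family:
  clusters). Breakend orientation is not carried on SV records, so
  inversions split evenly between the two inversion join types.

A chromosome is called under criterion A (interleaved > 10, oscillations
> 6, enrichment q < 0.05, exponential q < 0.05, joins q < 0.2) or
criterion B (interleaved > 30, exponential q < 0.05). A sample is a
complex genome with ≥ 1 called event by default; the stricter
more-than-one reading is exposed as `ce_min_events` because both
definitions circulate.

## Immune TME

Cell-type abundance is proxied by a single-sample rank-based enrichment
score (ssGSEA form): per sample, genes are ranked by expression, in-set
positions accumulate weights (descending rank position)^0.25, and the
score integrates the difference between the weighted in-set ECDF and the
unweighted out-of-set ECDF, normalized by gene count. This is the fully
specifiable stand-in for kernel-based enrichment scoring; the clustering
consumes z-scored values either way, so the subtype structure is
insensitive to the particular single-sample statistic.

Subtyping z-scores each cell type, then votes on k over 2–8 with four
criteria: elbow (max second difference of within-cluster SS), mean
silhouette, the gap statistic (uniform reference boxes, 50 references,
first-k rule) and Calinski–Harabasz. Calinski–Harabasz stands in for an
unspecifiable fourth criterion ("Euclidean distances" names a metric, not
a selection rule). A k needs three of four votes; otherwise the
silhouette winner is taken with a logged warning. The final assignment is
the most stable of n (default 1000) random-restart k-means runs, stability
being the mean consensus co-assignment frequency over the run's
same-cluster pairs. Cluster ids are relabelled by decreasing size, and for
k = 4 semantic labels are assigned greedily: *hot* maximizes lymphoid +
myeloid mean, *suppressed* maximizes myeloid − lymphoid among the rest,
*cold* minimizes the overall mean, the remainder is *moderate*; ties break
by cluster id, and k ≠ 4 falls back to C1..Ck.

The neutrophil/T-cell ratio shifts all three scores by the global minimum
(scores can be negative) and divides neutrophil by CD4 + CD8; zero
denominators yield NaN with the shift recorded in the output metadata.

Differential expression is cluster-versus-rest: log2 fold change of
(mean + 1), two-sided Wilcoxon rank-sum p-values, BH q-values, and the
significant set at |logFC| > 1.5 and q < 0.05. The rank-sum test replaces
a moderated linear model — an off-the-shelf routine deliberately not
re-specified here — while the thresholds are preserved. Pre-ranked GSEA
uses the classic weighted running-sum ES (weight |score|), a gene-label
permutation null, NES = ES / mean |same-sign null ES|, one-sided empirical
p with the +1 correction, and BH q-values.

## Survival

Presence stratification is exposure ≥ 0.15 (boundary inclusive). Tertile
stratification cuts at the 1/3 and 2/3 empirical quantiles with ties to
the lower group — exposure distributions have mass at zero, so tie
direction matters and is fixed. The log-rank statistic is the k-group
observed-minus-expected quadratic form with hypergeometric covariance
(z′V⁻¹z, df = k−1); subject weights multiply every at-risk, observed and
covariance contribution, which with inverse-probability weights gives the
adjusted test. IPW propensities come from the stage × treatment
cross-tabulation — exact for categorical covariates, so no propensity
model needs fitting; strata missing a group get +0.5 smoothing on all
cells and weights are normalized to mean 1 within group, making the
single-stratum case reduce exactly to the unweighted test. The two-sided
binomial enrichment p sums all outcome probabilities ≤ that of the
observed count. Multivariate Cox adjustment is a standard external routine
and out of scope here.

## Synthetic cohorts: what they show and what they do not

The default genome is 22 chromosomes × 100 Mb with Dirichlet(5)
trinucleotide content per chromosome — desk-scale, not GRCh37; real
chromosome lengths can be loaded from any table. Planted kataegis clusters
use gaps uniform on [1, 2000] bp and ≥ 6 mutations, matching the
detector's locus definition so sensitivity is well defined. The
chromothripsis generator chains intervals (breakpoint i joined to i + 2)
with exponential gaps and skewed join types, meeting every calling
criterion by construction. Expression archetypes shift marker genes in log
space (hot: lymphoid + myeloid by the separation parameter, default 3;
suppressed: myeloid only; moderate: lymphoid at half effect; cold: none)
over log-normal noise (sd 0.5). Survival times are exponential per
cluster hazard (defaults 0.01/0.05/0.02/0.03 per month) with independent
exponential censoring truncated at 120 months.

These cohorts validate the *computations*: conservation, boundary
behaviour, planted-quantity recovery, and null calibration. They do not
emulate real-data pathologies — mapping artefacts, purity and subclonal
structure interacting with signature fitting, collinear signature
catalogues, batch effects in expression, or informative censoring — so
passing recovery here bounds implementation correctness, not expected
field performance. Default problem sizes (60-sample cohorts, 100-replicate
calibrations, 100-restart consensus in the timed checks versus 1000 by
API default) were chosen to keep full validation runs in the minutes
range on a single core; all are parameters.
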