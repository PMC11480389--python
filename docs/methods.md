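# Methods

This note documents the statistical procedures `gliostate` implements, the
defaults it ships, the design choices made where the published procedure
left details open, and what the synthetic validation does and does not
establish.

## Malignant-cell calling

The malignancy score of cell *j* is

    m_j = log2( (mean CP10K over amplified-chromosome genes + ε)
              / (mean CP10K over deleted-chromosome genes   + ε) ),

with counts-per-10,000 normalization and pseudocount ε = 0.1 CP10K.
CP10K makes the score library-size-free; the pseudocount keeps it finite
for cells expressing no gene on one chromosome. The published procedure
specifies only a "log-ratio"; base 2 is chosen here (base only rescales
the threshold location) and the normalization is the standard per-cell
depth normalization. For IDH-wild-type glioblastoma the amplified/deleted
pair is Chr7/Chr10; the IDH-mutant variant (unaltered Chr2 over deleted
Chr1) uses the same function with different chromosome arguments.

A two-component univariate Gaussian mixture is fit by EM. Initialization
is deterministic — the scores are split at their median and each half
seeds one component — rather than random-restart, so identical inputs give
identical fits. The log-likelihood is asserted non-decreasing at every
iteration; convergence is a log-likelihood change below 1e-8 (default) or
1000 iterations; standard deviations are floored at 1e-3 to prevent
singular components on near-degenerate data. A fit is flagged `unimodal`
when the component means are closer than half the larger standard
deviation, signalling that thresholding is not meaningful. The decision
threshold is `μ_high − 1.96·σ_high`, i.e. the lower edge of the 95%
interval of the higher (malignant) component.

Classification reconciles the score with an upstream *putative* identity
(in the original procedure, cluster-level marker annotation; here any
caller, supplied as input since clustering is out of scope): putative
tumor cells at or above the threshold are tumor, putative non-tumor cells
below it are non-tumor, and every disagreement is discarded as
non-malignant or a potential multiplet. A score exactly at the threshold
counts as above it (the published rule discards only cells *below* the
threshold). Whether the mixture should be fit on all cells or only
putative tumor cells is not specified in the source procedure; the default
fits on all cells and `fit_on="putative_tumor"` restricts.

## Chromosome copy number from WGS

Per chromosome, the tumor read fraction is divided by the germline read
fraction; the resulting ratio vector is normalized by its median over
somatic (non-sex) chromosomes and multiplied by two. The estimate is
invariant to the total depth of either library, and the median somatic
chromosome sits at copy number 2 by construction — the method therefore
assumes most chromosomes are euploid. Zero germline counts are an error,
not a silent skip.

## Matched-subsample differential expression

Two conditions are compared only after being matched on both cell count
and depth: the larger condition is subsampled without replacement to the
smaller's cell count, then the deeper condition's count entries are
binomially thinned with p = shallow/deep mean molecules per cell
(per-entry binomial thinning is distributionally identical to keeping
each molecule independently). The matched pair is validated to agree on
mean molecules per cell within 1%.

Counts are then normalized by median-scaled library-size factors
(size factor = cell total / median cell total). The original pipeline used
pooled-deconvolution size factors; the median-scaled stand-in removes that
external algorithm while preserving the property that matters after depth
matching — removal of residual per-cell depth variation. On matched
synthetic data the two normalizations give indistinguishable DE outcomes.

Each gene is tested with the two-sided Mann–Whitney U (tie-corrected
normal approximation with continuity correction; an exact mode exists for
tiny inputs and is used in the tests against a full enumeration oracle).
Genes with zero counts in both conditions are excluded and logged; all
other genes are tested by default (the source procedure states no
detection filter). p-values are Benjamini–Hochberg adjusted across all
tested genes. log2FC = log2((mean_A + ε)/(mean_B + ε)), ε = 0.1.

Consistent signatures: with two biological replicates per model, the four
pairwise comparisons {A1B1, A1B2, A2B1, A2B2} are tested separately and a
gene enters the up (down) list when log2FC > 1 (< −1) with FDR < 0.05 in
at least three of the four. A gene meeting both rules across tables is
excluded and logged.

## Signature scoring and state assignment

**Binned-control score.** All analyzed genes are ranked by aggregate
expression — the mean of log2(CP10K+1) across cells, the convention of the
method this follows — and cut into 100 equal-size rank bins (quantile
bins; robust to the heavy-tailed expression distribution). For each
signature gene, 100 control genes are sampled with replacement from its
bin; the cell's score is the mean normalized expression of the signature
minus the mean over the pooled control draws. Control sampling is seeded.
Signature genes absent from the matrix are dropped with a warning.

**Recovery-AUC score.** Genes are ranked per cell by decreasing
expression, ties broken by a seeded jitter of 1e-9 (far below any count
difference); the score is the area under the signature-gene recovery
curve over the top ⌈0.05·G⌉ ranks, normalized by its maximum attainable
value. The score is in [0,1] and depends only on within-cell expression
ranks, hence is invariant to monotone transforms of expression. The top
fraction is exposed (`top_frac`); 0.05 is the cited method's default.

**Lineage.** The six lineage signatures (MES1, MES2, AC, OPC, NPC1, NPC2)
are scored and the argmax taken; MES1/2 and NPC1/2 aggregate to MES and
NPC. Ties break by fixed signature order and are counted in the log.

**Cycle.** Cells with both G1/S and G2/M binned-control scores ≤ 0 are G0
(quiescent); otherwise the larger score names the phase, and any non-G0
phase is proliferative. A caveat the synthetic validation makes explicit:
the ≤ 0 rule is *anti-conservative under score noise*. Quiescent cells'
scores are centred slightly below zero with a spread set by counting
noise, so a noise-dependent fraction of them (≈19% at the default
simulation conditions) crosses zero and the recovered proliferative
fraction overshoots the true one, even though cycler recall is ~100% and
the G1/S-vs-G2/M argmax is ~99% accurate. Users comparing proliferative
fractions across conditions should rely on the contrast, not the absolute
level.

**Correlations.** Signature-score relationships are summarized by
tie-aware Spearman correlation; constant score vectors give NaN, never a
silent zero.

## Preranked GSEA

Genes are ranked by log2FC or by sign(log2FC)·(−log10 q) (q floored at
1e-300), ties broken by gene identifier. The running sum gains
|metric|^w / Σ_hits |metric|^w at set members (w = 1 by default; w = 0
reduces to the unweighted KS statistic) and loses 1/(G − s) elsewhere; the
enrichment score is the extremum of largest magnitude, with the positive
extremum winning an exact magnitude tie (a deterministic convention; ties
only arise on constructed inputs). The null is gene-set permutation —
random same-size sets from the ranked universe, the preranked convention —
with NES = ES / mean |null ES| of matching sign, nominal
p = (1 + #{same-sign null ≥ |ES|}) / (1 + #same-sign null), and FDR by the
standard positive/negative-pool tail-ratio. Set-size filters 5–2000;
1000 permutations by default.

## HTO demultiplexing

Raw tag counts are CLR-transformed per tag across cells
(ln(x+1) − mean ln(x+1)), k-means clustered with k = n_tags + 1 (the
extra cluster absorbs negatives/ambient profiles), and each tag is given a
positivity threshold from a negative-binomial fit to background raw
counts: background = all cells outside the cluster with the highest mean
CLR for the tag, excluding counts further than 10 scaled MADs above the
background median. The exclusion matters: a handful of mis-clustered
doublets carry signal-level counts into the background and would otherwise
dominate the method-of-moments variance, inflating thresholds into the
signal range. The cut sits far below any signal distribution of practical
interest, so the genuine background is untouched. An alternative
background — the cluster with the *lowest* mean CLR per tag, the cited
hashing method's convention — is available but is sensitive to clusters
that split by staining depth. The NB is fit by moments
(size = m²/(v − m), floored at 1e-8; Poisson fallback when v ≤ m, logged)
and the threshold is its 0.99 quantile. Cells are singlets (exactly one
tag above threshold), doublets (≥2) or negatives (0). Note the per-tag
false-positive rate is 1 − q by construction, so ~(n_tags − 1)·(1 − q) of
true singlets are expected to be flagged doublet regardless of
signal/background separation; raising q trades doublet sensitivity for
singlet recall.

## Flow-cytometry summaries

Dye readouts are per-event channel ratios with a floored denominator
(default 1e-6, keeping zero-denominator events finite). Conditions are
compared by gating at the median of a reference condition and reporting
the fraction of test events strictly above the gate; at-gate events count
below, so above + at-or-below = 1 exactly. Inputs are assumed pre-gated
live-event tables; FCS parsing, compensation and scatter gating are
upstream concerns.

## Synthetic-data generator

The generator plants exactly the structure the analysis assumes. Counts
are negative binomial, parameterized by mean and a single global size
(inverse dispersion): per entry a Gamma(size, mean/size) rate is drawn and
Poisson-sampled. The mean of gene g in cell j factorizes as

    μ_gj = base_g · (CN_c(g)/2 if tumor) · (boost if g in state sig)
                 · (boost if g in cycle sig) · lib_j ,

with base means lognormal (σ = 1) scaled to the target library size and
lib_j lognormal (σ = 0.3, mean-normalized). Default study conditions,
chosen once as representative of the system being emulated: 2,000 genes on
22 somatic chromosomes, 2,000 cells per sample, Chr7 at 4 copies and
Chr10 at 1 copy in tumor cells (the canonical glioblastoma karyotype,
giving the 2-log2-unit score contrast), 75% tumor cells, four equal
lineage states with disjoint 50-gene signatures boosted 3-fold, 30%
cycling (15% G1/S + 15% G2/M) with 3-fold cycle-signature boosts, NB size
10, mean library 5,000, seed 17. Signature genes are placed on unaltered
chromosomes so dosage and state effects stay orthogonal in the truth.
Treatment removes each cell of state s with probability depletion[s]
(default: AC at 0.6 — the source system reports only the direction of
state-selective depletion, not a magnitude, so this is a simulation
choice). The HTO layer gives singlets their own tag at NB mean 200 and
other tags at mean 5 (size 5), with 5% doublets carrying two signal-level
tags. WGS tables are proportional to chromosome gene counts times CN/2,
optionally Poisson-sampled at 10^6 total reads.

What the generator does *not* emulate: ambient RNA, batch effects,
expression-matrix doublets, gene–gene correlation beyond the planted
programs, overlapping signatures, segmental (sub-chromosomal) CNV, and
cross-species mapping. Passing the validation therefore shows the
implementations recover the structure they are specified to recover under
a faithful noise model — not that they are robust to every artifact of
real droplet data.

## Problem sizes and determinism

The validation suite runs the full cohort at 2,000×2,000, the DE null
calibration at 20 seeds × (1,000 genes × 250 cells/side), planted-recall
DE at 500 cells/side, GSEA null calibration at 100 runs × 500
permutations, and HTO demultiplexing at 2,000 cells — sizes at which every
recovery statistic is stable across seeds while the whole suite completes
in minutes on one CPU. Every stochastic step (generation, subsampling,
thinning, control sampling, jitter, permutation, k-means) takes an
explicit seed, and CLI reruns with the same seed produce byte-identical
outputs.
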