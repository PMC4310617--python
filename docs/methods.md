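# Methods

## Coordinates, windows, and counting

All intervals are 0-based half-open (BED convention). The proximal promoter
of a transcript is the symmetric window `[tss − h, tss + h)` with half-width
`h` (default 500 bp, i.e. the classic ±500 bp / 1 kb promoter); the window is
strand-agnostic, and the TSS of a −-strand transcript is taken to be the BED
*end* coordinate (the 5′ end in that dialect). Windows are clipped at
chromosome edges and the clipping recorded. A peak counts toward a promoter
when it overlaps the window by ≥ 1 bp (coverageBed semantics); a peak
spanning two windows counts for both. Peak quality filtering is strictly
greater-than the cutoff ("score over 500"), except that cutoff 0 is the
"all data" mode and retains peaks scored exactly 0.

Four per-transcript count metrics are computed: total mapped sites, distinct
TF labels, and both variants excluding a configurable polymerase-class label
set (default `{Pol2, Pol2-4H8, POLR2A, Pol3}`; the SVM's no-polymerase
control additionally excludes TAF1, a constitutive component of the
initiation apparatus). Distinct-label counting guards against one TF with
several merged sites dominating a promoter's count.

Count distributions are summarized with Tukey's five numbers using the
classic hinge rule (hinges are medians of the lower/upper halves including
the overall median when n is odd — the convention R's `fivenum` implements),
plus mean, SD, the 90 % quantile and the percentages of transcripts binding
exactly 1, exactly 2, and 1–5 TFs.

Sequence composition covariates: GC fraction and CpG dinucleotide count with
Ns excluded from the effective length, and
CpGoe = (#CG × L) / (#C × #G), defined as 0 when #C·#G = 0. CpGoe proxies
long-term germline methylation (methylated CpGs decay over evolutionary
time).

## Effective promoter size

Binding-site enrichment is expected to be TSS-proximal, decaying with
distance into a uniform background; the mean count as a function of window
half-width then grows concavely before becoming linear. The estimator sweeps
a grid of half-widths (default {250, 500, 1000, 2000, 3000, 4000, 5000,
7500, 10000}), smooths mean count vs half-width with a local-polynomial
(lowess) fit (default span 0.35, chosen mild so the linearization kink is
not smeared on a 9-point grid), differentiates by first differences, and
reports the smallest grid point after which the absolute change of the
derivative stays below `tolerance × max|derivative|` (default tolerance
0.05) for all larger grid points. On data with no proximal enrichment the
derivative is constant and the first grid point is returned.

## Stacking test

For every promoter with ≥ 2 peaks, all pairwise overlap percentages
`100·|a ∩ b| / |a ∪ b|` are pooled (the union denominator keeps the value in
[0, 100] and symmetric; the alternative denominators — shorter peak, first
peak — are neither). The same promoters are then rebuilt `n_randomizations`
times (default 1) with each peak given a uniform random start that keeps its
length inside the window, and the observed and randomized pools are compared
with a Welch two-sample t-test. Known limitation: pairs within one promoter
share peaks, so with many multi-peak promoters the pooled t-test is mildly
anti-conservative; the calibration property is exact when promoters carry
two peaks each, which is how the test suite checks it.

## Expression metrics

A transcript is 'on' in a sample when TPM strictly exceeds the cutoff
(default 10; 10 TPM ≈ 3 mRNA copies/cell at 300,000 mRNAs/cell, and
`tpm_to_copies` implements exactly `tpm × total/1e6`). BoE is the fraction
of 'on' samples; it is non-increasing in the cutoff by construction. Breadth
classes: unexpressed (BoE = 0), narrow (0 < BoE ≤ 0.33), intermediate
(0.33 < BoE ≤ 0.66), housekeeping (BoE > 0.66); the quadrant classes cross
broad (BoE > 0.33) with Tfbs-rich (count ≥ 10).

Level summaries come in two families: across all samples (mean/median/max),
which is mechanically coupled to breadth because 'off' samples contribute
zeros, and conditioned on the 'on' samples only, which removes that
circularity; the conditioned summaries are flagged (NaN) when no sample
passes the cutoff. PEM divides a transcript's TPM in one sample by its mean
over **all** samples (zeros included, per the definition), so the PEM vector
always averages exactly 1; all-zero transcripts have undefined PEM and are
excluded (and flagged) rather than assigned 0.

## Association machinery

`correlate` returns the coefficient with the t-form test
(t = r·√((n−2)/(1−r²)), df = n−2) for Pearson and Spearman, and the
tie-corrected normal approximation for Kendall. Constant inputs flag the
result as undefined instead of raising, so pipelines can report the failure.

Spearman partial correlations rank-transform all columns and read the
partial coefficient off the inverse of the correlation matrix (the
precision-matrix method); with an empty control set this reduces exactly to
the plain Spearman correlation. A singular matrix raises an error naming the
collinear columns.

The promoter-shuffle null permutes the count vector (sampling without
replacement — a random promoter-to-transcript reassignment) and records the
correlation t-statistic per replicate (default 1,000 replicates for speed;
configurable upward). The empirical two-sided p-value uses the +1
pseudocount, p = (1 + #{|t_rep| ≥ |t_obs|}) / (1 + n_reps), since a
permutation p of zero is impossible.

Column clustering uses 1 − r as the distance with average-linkage
agglomeration; columns are pre-sorted by name so leaf order is deterministic
under ties, and the dendrogram exports to Newick.

The SVM predictor mirrors the libsvm regression setup: radial kernel,
cost = 1, gamma = 0.01, epsilon = 0.1, a random half/half split without
stratification, features scaled and centred on the training half. The
response is standardized internally and predictions back-transformed —
R's e1071 `svm()` scales the response in regression mode, and epsilon = 0.1
on an unscaled variable in [0, 1] would behave very differently. Accuracy is
the Pearson r between predicted and observed response on the held-out half.
The scrambled control permutes the training response (expected r ≈ 0); the
retained control adds the response as a feature (expected r ≈ 1). In binary
mode (narrow vs not at BoE 0.33) accuracy is the ROC AUC averaged over 10
random half splits. Known behaviour: on zero-inflated count features the
*binary* scrambled control can sit above 0.5, because the class imbalance at
the duplicated all-zero feature point shifts the decision score with
distance from it; the regression-mode controls do not show this artifact.

## Paralog divergence

Promoter divergence between paralogs is the Jaccard index of their TF
repertoires — sets of distinct TF labels, not genomic intersection, since
paralog promoters occupy different loci; site multiplicity is ignored. JI of
two empty repertoires is defined as 0. Co-expression is the correlation
(Pearson default; Spearman/Kendall selectable) of the two TPM vectors across
samples.

Families of n genes yield C(n, 2) pairs; because large families would
otherwise dominate, `select_youngest_pairs` keeps, for each gene, only the
pair through its most recent duplication node (ties broken by partner id,
one pair per gene and node), after dropping same-side comparisons (pairs
whose familySide flags agree at their node). Duplication ages use an ordered
taxon-group table (default Primate < Mammalian < Vertebrate < Animal <
Eukaryotic, youngest first, each duplication assigned to its youngest
matching group). Age-group summaries report mean/sd/n of BoE and TfbsNo per
group and all pairwise Wilcoxon rank-sum tests with Holm adjustment; groups
with n < 2 are excluded from testing and flagged.

Event classification of a duplication from its daughters' breadth classes:
both housekeeping → housekeeping-conserved; both narrow →
tissue-specific-conserved; one narrow + one housekeeping → transformative;
any combination involving an intermediate or unexpressed daughter falls into
an explicit *other* class (the trichotomy is silent about them).

## Synthetic data: what is planted, and what is not

The generator reproduces the structural features the analyses rely on, at
desk scale, with full determinism under (config, seed):

- **Richness law.** Per-transcript site counts are zero-inflated
  (P(0) = 0.25) with k ∈ 1..60 drawn from a truncated discrete power law
  P(k) ∝ k^(−1); the truncation at 60 echoes the observed maximum count
  (58) on real clustered data, and the log-log slope of the empirical pmf
  recovers the planted exponent.
- **Peak placement.** Proximal peaks sit at signed TSS offsets drawn from a
  *triangular* density reaching zero at `enrichment_scale` (default
  3,000 bp), mixed with a uniform background (default 0.02 peaks/kb). The
  compactly supported kernel is a deliberate choice: the count-growth
  derivative is then exactly constant beyond the scale, making the planted
  boundary identifiable by the derivative-constancy rule (an exponential
  tail has no well-defined linearization point at the nominal scale). A
  `stacking_weight` fraction of proximal peaks is piled exactly at the TSS.
  TF labels come from a 40-label pool with Zipf-like weights (polymerase
  most frequent); scores are uniform on 0..1000.
- **Breadth link.** P('on' per sample) = sigmoid(−2.4 + 1.15·log1p(k) + ε),
  ε ~ N(0, 1.65), with 15 % of transcripts silenced outright (no expression
  evidence in any sample). The intercept/slope/noise defaults were
  calibrated once, by simulation at the default conditions, so the measured
  Pearson r between the ±500 bp score>500 count and BoE at 10 TPM lands at
  the planted target of 0.45; 'on' samples receive TPM = 10 + lognormal
  (always above the cutoff), 'off' samples uniform sub-threshold TPM. The
  resulting breadth-class mix (≈0.41 narrow / 0.19 intermediate / 0.24
  housekeeping / 0.15 unexpressed) is a realistic transcriptome-scale
  composition.
- **Paralog families.** Families grow by sequential duplications whose ages
  are drawn (weights 0.10/0.15/0.40/0.25/0.10 young→old) and applied
  oldest-first. At an age-a duplication each daughter loses repertoire
  labels with probability drop(a) ∈ {0.08 … 0.60} (gaining fresh labels to
  keep size roughly stable) and its latent expression profile decorrelates
  to ρ(a) ∈ {0.95 … 0.45}; the newly created copy is born at that age, and
  per-gene target breadth and repertoire size are drawn around age-specific
  means (BoE 0.09→0.35, TfbsNo 4→10, young→old) with per-gene SD 0.18 —
  wide enough that the named event classes are populated while group means
  stay monotone in age. Both JI and co-expression therefore decay with
  pair age, producing a positive JI~co-expression correlation that
  randomized pairing destroys. Housekeeping-conserved events remain rare
  under these means (both daughters above BoE 0.66 is improbable when the
  oldest group mean is 0.35); the classifier is exercised directly in unit
  tests.

What the generator does **not** emulate: chromatin state, methylation or
DNase signal beyond independent covariates, chromosomal clustering of
co-expressed genes, antibody redundancy, and tissue-correlated sample
structure (samples are exchangeable given a transcript's 'on' probability).
Passing recovery tests therefore demonstrates that the estimators detect the
effects they target at realistic sizes and noise levels — not that real
promoter data are this clean.

## Problem sizes and numerical choices

The test and acceptance runs use 2,000–10,000 transcripts, 300 families,
and 99–1,000 permutation replicates; these sizes give stable recovery of
every planted effect while keeping a full run in tens of seconds. Pipeline
defaults: window ±500 bp, score cutoff 500, TPM cutoffs 10/100/1000,
permutation replicates 1,000 (configurable), boundary grid as above.
Degenerate inputs are either errors (empty count vectors, all-zero PEM rows,
infeasible TSS spacing, singular correlation matrices — named) or flags
(constant correlation inputs, empty strata, undefined conditioned means),
chosen so pipelines fail loudly at the stage that can explain the failure.
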