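# Methods

## Study design and outcome

The package models a two-cohort biomarker study in locally advanced rectal
cancer. Each patient carries a five-tier tumor regression grade (TRG) after
preoperative chemoradiotherapy; grades 1–2 (complete/near-complete
regression) define the responder class, grades 3–5 the non-responder class.
The training cohort (default n = 60) drives every discovery decision; the
validation cohort (default n = 96) is touched only by the final fitted
model. Cohort sizes, the responder prevalence (72/156) and the
clinicopathological covariate margins are taken from the published study
design the workflow reimplements.

## Normalization

Raw counts are normalized with the standard published nCounter scheme, since
the vendor software's exact internals are not public:

1. per-sample positive-control factor: (mean over samples of the
   positive-control geometric means) / (sample's positive-control geometric
   mean);
2. background threshold per sample: mean + k·SD of the negative controls
   (k = 2 by default), subtracted and floored at zero;
3. per-sample housekeeping factor computed the same geometric-mean way after
   steps 1–2.

Samples with a zero control geometric mean are flagged and excluded. Each
step can be disabled. Under pure library-size variation the scheme is
exactly idempotent; with gene-level noise it is idempotent only to first
order, which is inherent to any two-factor scheme. All downstream statistics
operate on log2(normalized + 1); the +1 offset avoids log 0 at the cost of
compressing genes near background.

## Differential-expression screen

Per endogenous gene, a two-sided pooled-variance Student *t*-test (Welch is
a switch) and a geometric-mean fold change FC = 2^(mean log2 difference),
reported with the signed convention (−1/FC below 1, so |FC| ≥ 1 always). A
gene passes with *p* < 0.05 and |FC| > 1.5. **No multiple-testing correction
is applied** — deliberately, matching the workflow being reimplemented: with
730 genes, roughly 5 % of null genes pass the *t*-test, and the fold-change
filter removes most but not all of them. The univariate logistic filter
(Wald *p* < 0.05) then removes genes whose expression does not monotonically
shift the response odds. Complete separation in a univariate fit is flagged
and the gene retained, with the Wald statistic taken at the last stable
IRLS iterate.

## Combinatorial search and cross-validation ranking

An *n*-gene shortlist spans 2ⁿ − 1 non-empty subsets (exact integer
arithmetic; n = 42 gives 4 398 046 511 103). Exhaustive enumeration is exact
up to a configurable budget; the default strategy is exhaustive for subset
sizes 1–3 plus a forward beam search (width 10) to 12 genes. The beam grows
subsets by in-sample AUC; because AUC saturates once a model separates the
training data, ties break on the training log-likelihood and then on gene
ids, keeping the search deterministic.

A candidate is retained when its multivariable logistic model has
likelihood-ratio *p* < 0.05, AUC > 0.8, and sensitivity and specificity
above 75 % at the 0.5 probability cutoff (in-sample). The printed source
threshold "AUC > 0.08" is treated as a typo for 0.8 — 0.08 would be vacuous
— and is configurable. Retained candidates are ranked by repeated
stratified 2-fold cross-validation: 300 random half-splits, fit on one half,
accuracy on the other at cutoff 0.5. A repetition contributes to the mean
only when the training-half model is significant (LR *p* < 0.05) — one
reading of the ambiguous "accuracy based on a p-value < 0.05 on the test
set" rule, and a toggle. Splits are stratified by class because unstratified
half-splits of n = 60 frequently produce degenerate folds. To bound runtime,
cross-validation covers the best candidates of every subset size (up to 60
total by default) rather than every retained candidate; scoring ties within
a size break by AUC then model *p*. The best candidate is the one with the
highest CV accuracy, ties broken by fewer genes, then lexicographic gene
ids.

The repeated half-splitting happens *inside* the cohort that already
selected the shortlist, so it cannot penalize genes whose association with
response is a fluke of that cohort — only the validation cohort can. This
is a property of the reimplemented design, not an implementation choice;
see Limitations.

## Final model and reports

The selected signature is refitted by plain logistic regression on the
training cohort (statsmodels); under complete separation the fit falls back
to a small L2 ridge and is flagged. Confusion-matrix metrics (accuracy,
sensitivity, specificity, PPV, NPV) are reported per cohort at the 0.5
cutoff; empty denominators yield "undefined", never NaN. For the
clinical-association tables the continuous signature score (training linear
predictor) is dichotomized at its training median — the source's "low vs
high" is never defined, and a Youden-optimal cutpoint is available by
configuration. Regression tables come from binomial GLM/IRLS fits, which
(like R's `glm`) stop with large finite estimates under quasi-separation;
rows with |coef| or SE beyond 50 carry a separation flag. Odds-ratio
confidence intervals are exp(coef ± 1.96·SE).

Cohort-comparability tests: Pearson χ² with Yates continuity correction for
2×2 tables (required to reproduce the published gender *p* = 0.282;
uncorrected gives ≈ 0.21), exact two-sided Fisher tests otherwise — full
enumeration over fixed-margin tables for r×c, scipy's hypergeometric test
for 2×2. `auto` chooses Fisher whenever an expected cell is below 5.
All-zero category levels are dropped before testing.

## Pathway meta-analysis

The proprietary multi-module interaction-mining system used by the source
workflow is replaced by a transparent neighborhood analysis on a
user-supplied PPI edge list: the interactors of the signature are all genes
within a hop limit (default 1); a gene's interaction frequency is the
percentage of in-network signature genes it touches within that limit, with
≥ 75 % labelled high-frequency. Pathways (GMT gene sets) rank by total
signature–member interaction count, then by number of interacting member
genes, ties lexicographic. No enrichment p-values are computed (the
reimplemented workflow computed none), and per-patient pathway matching is
reduced to cohort-level reporting.

## Synthetic-data generator

`generate_cohort` emulates the assay's data structure: 730 endogenous genes
(the nine planted signature genes first), 20 housekeeping, 6 positive and 8
negative controls. Counts are gamma–Poisson (negative binomial) with mean
2^(baseline + class shift)·library factor, baseline log2 means uniform on
(5, 10), log-normal library factors (CV 0.15), positive controls following
the standard four-fold titration (128 fM down to 0.125 fM, lowest level
≈ 25 counts), negative controls Poisson with mean 2, housekeeping genes
high-expressed with no class effect. Planted genes shift by ±effect/2
around their baseline per class, alternating direction along the signature.
Covariates are drawn independently from the pooled published cohort margins;
an optional knob associates pathological T stage with response. Everything
is deterministic given the seed.

**Calibration.** The study's true per-gene effect sizes and dispersions are
unknown; the per-gene noise default was calibrated once against the
pipeline's ability to recover the planted signature at the design effect of
1.0 log2 fold-change, then frozen. The chosen negative-binomial size
r = 5.0 gives a per-gene log2-scale SD around 0.55–0.75, making each
planted gene individually detectable by the screen while no single gene
classifies patients well alone. Smaller r (more noise) floods the shortlist
with false positives whose cohort-specific associations survive the
within-cohort cross-validation; larger r lets tiny subsets saturate the
ranking. Neither failure mode is reachable from the other side: full
recovery of all nine genes by this procedure requires simultaneously a weak
per-gene signal (so the CV ranking climbs to nine genes) and a null-free
shortlist (strong per-gene signal), and both move together with the common
noise scale. The pipeline therefore typically recovers 4–7 of the 9 planted
genes while validating at 85–95 % accuracy on the fresh cohort — selected
signatures are smaller than, and partially overlapping, the planted truth,
exactly the behavior expected of a parsimony-tie-broken CV ranking.

**What the generator does not model:** FFPE RNA degradation, batch effects
beyond library size, gene–gene correlation (planted genes are conditionally
independent given the class), heavy-tailed outlier samples, and vendor QC
flags (field-of-view counts, binding density). Passing tests on synthetic
data therefore demonstrate the statistical machinery, not robustness to
those artifacts.

## Numerical choices

- Hot-path logistic fits (beam scoring, the 300-repetition CV) use a compact
  damped-Newton IRLS solver on numpy arrays (tolerance 1e-8, max 50
  iterations, steps capped at 10 in the max norm); it is cross-checked
  against statsmodels to 1e-6 in the tests. Separation is declared when the
  linear predictor saturates (|η| > 30) or a non-converged fit classifies
  the data perfectly; coefficients then stay at the last stable iterate so
  Wald statistics remain finite.
- AUC is the Mann–Whitney rank statistic with midranks for ties; the test
  suite checks it against exhaustive concordant-pair counting.
- The r×c exact Fisher test enumerates all tables with the observed margins
  (budget 2·10⁶ tables) and sums probabilities ≤ the observed table's with
  a 1e-9 relative tolerance against floating-point ties.
- Degenerate inputs: zero-variance genes with equal means get t = 0,
  p = 1, FC = 1; contingency tables with a single nonzero row/column give
  p = 1 with a warning; empty confusion denominators give "undefined".

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default study size (730 genes, 156 samples) over ten seeds, and the null
calibration over 30–50 replicates; a single discovery run takes roughly
15–25 s on one CPU, dominated by the cross-validation of retained
candidates.

## Limitations

- Within-cohort CV ranking cannot identify selection-induced false
  positives; only the independent validation cohort measures real
  performance. Users should read the training metrics as optimistic.
- The normalization is a documented stand-in for the vendor's unpublished
  pipeline; absolute normalized values may differ even though relative
  structure is preserved.
- The search is exact only for small subset sizes; the beam is greedy and
  can miss interacting gene sets whose members are individually weak.
- No multiple-testing control anywhere in the screen, by design fidelity;
  interpret shortlist sizes accordingly.
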