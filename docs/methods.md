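# Methods

`radsig` implements a two-track analysis of pathological complete response
(pCR) to neoadjuvant chemoradiotherapy in rectal cancer from pre-treatment
bulk expression profiles, together with a synthetic-cohort generator that
supplies the statistical structure every stage assumes, so the whole
pipeline is testable without patient data.

## The synthetic study

`radsig.simulate` generates two discovery cohorts (125 and 124 samples,
pCR prevalence 26% and 19%) and one external validation cohort (107
samples, 21%) over a shared 2,000-gene universe. Gene baselines are drawn
once per study: per-gene means ~ Normal(7, 1.5) and per-gene SDs ~
Lognormal(0, 0.3), resembling log2 microarray ranges. Two opposing signal
blocks are planted — an "immune" block up-regulated in responders and a
"stromal/TGFβ" block up-regulated in non-responders (40 genes each by
default) — with within-block pairwise correlation `block_correlation`
(default 0.3) induced by a shared latent factor per block.

Outcome and expression are generated jointly from a Gaussian two-class
factor model. Ordinal T stage (1–4) and N stage (0–2) are drawn from fixed
multinomials typical of locally advanced disease, and pCR is drawn from a
logistic model on centred stage with per-unit log-odds
`stage_outcome_log_or = 0.3` (higher stage, lower pCR odds); the intercept
is calibrated by root-finding so the marginal prevalence matches the
cohort's target. Conditional on pCR, the latent block factors are shifted
by ±`effect_size_sd_units`/2 (responders high on the immune factor, low on
the stromal factor); by normal-discriminant/logistic duality the class
posterior given the factors is exactly logistic, and each planted gene's
between-class standardized mean difference equals `effect_size_sd_units`
in expectation — which gives the tests closed-form oracles for effect
recovery and a generator-side latent score whose AUC is computable
directly. Per-cohort batch effects are additive location shifts ~
Normal(0, `batch_location_sd` = 0.3) and multiplicative scale factors ~
Lognormal(0, `batch_scale_sd` = 0.1) per gene; the validation cohort's are
three times larger so cross-cohort correction is non-trivial.

What the generator does **not** emulate: probe-level noise, GC and spatial
array artifacts, non-Gaussian expression tails, gene–gene correlation
outside the planted blocks, and cross-platform probe remapping. Passing
tests therefore demonstrate that the statistical machinery behaves as
specified under the assumed model, not that the pipeline would reach any
particular performance on real cohorts.

## Candidate (hypothesis-based) track

Signature scores default to the mean of per-gene z-scores computed within
the scored cohort (scale-free and robust to per-gene offsets); a weighted
sum is available for published coefficient signatures such as the
radiosensitivity index, whose proprietary coefficients the package does
not ship — users supply them as signature tables. Cell-population
abundance uses the marker-mean convention (arithmetic mean of marker-gene
log2 expression, no cross-sample normalization). Molecular subtype calls
use generic nearest-centroid classification (argmax Pearson correlation
over user-supplied centroids, "unclassified" below 0.15) — a structural
approximation to published subtype classifiers that is sufficient when
subtype membership enters the analysis as a binary feature. The
chromosomal-instability flag marks a sample CIN-negative when neutral
copy-number calls cover more than 20% of the combined segment length
(1-based inclusive lengths, strict inequality).

Each candidate is tested by maximum-likelihood logistic regression of pCR
on the score, adjusted for cohort (dummy-coded) and baseline T/N stage
(ordinal numeric by default; categorical by flag). Perfect separation is
flagged with an infinite-odds-ratio sentinel rather than silently
penalized. Backward stepwise selection removes, at each step, the feature
with the largest likelihood-ratio p-value above `alpha_remove = 0.05`,
with adjustment covariates forced; ties break by column order and the
elimination trace is recorded. The compound biology score (the BRSC
analogue) is the linear predictor restricted to the retained biology
terms — covariates excluded — so it is a pure-biology score whose addition
to a stage-only model can be tested by the likelihood-ratio test. AUC is
the Mann–Whitney statistic with ties counting one half. Cross-cohort
pooling uses fixed-effect inverse-variance meta-analysis with Cochran Q
and I² = max(0, (Q − df)/Q)·100, plus DerSimonian–Laird random effects
when at least two cohorts contribute.

## ML (hypothesis-free) track

Quality control drops genes with more than 5% missing values, imputes the
remainder by gene median, and drops samples whose Pearson correlation with
the cohort's median profile falls below 0.7 (aborting if more than half
fail). Class imbalance is handled by repeated downsampling: each of
`n_iter` iterations keeps every minority-class (pCR) sample and a seeded
without-replacement draw of equal size from the majority class.

Differential expression is assessed per balanced subset with two tests: a
moderated t-statistic with empirical-Bayes pooled-variance shrinkage (the
per-gene variances are squeezed toward a scaled-inverse-chi-square prior
fitted by method of moments on log-variances, with the prior degrees of
freedom obtained by trigamma inversion) and the Wilcoxon rank-sum test —
one parametric, one nonparametric. Within each subset each test's p-values
are Benjamini–Hochberg adjusted; a gene is selected in a subset only if
both adjusted p-values are ≤ 0.05, and the **robust** set is the
intersection across all subsets. Note that the all-subsets intersection is
conservative by construction: at a per-gene effect of exactly 1.0 SD with
~57 v 57 balanced subsets, per-subset power of ~0.97 per gene compounds to
roughly 0.8 over 20 partially overlapping subsets, so recovery sensitivity
at that effect sits near 0.8 (with essentially no false positives); at
1.5 SD recovery is complete.

Decision-making genes (DMGs) are found by recursive importance-based
elimination: fit the learner (random forest by default), drop the
lowest-importance decile, record stratified-CV accuracy, and return the
smallest set within `tol_acc = 0.01` of the best accuracy, with a floor of
5 genes. The model tournament evaluates six algorithm families — elastic
net, gradient-boosted trees, L1 logistic, a feed-forward network, random
forest, and an RBF support-vector classifier — each in two feature modes
(all robust DEGs, or the DMG subset), i.e. 12 configurations, by
stratified 10-fold CV accuracy on a balanced design (all minority samples
plus one seeded majority draw; accuracy is only meaningful near balance).
Hyperparameter grids are small and searched inside the CV. The winner
(ties: fewest genes, then fixed algorithm order) is refit on all discovery
samples and frozen into a locked model: algorithm id, gene list,
hyperparameters, fitted estimator, and training seed, serialized as JSON
with a SHA-256 payload fingerprint. Validation applies a locked model but
never refits it; the fingerprint is checked before and after scoring.

## Batch correction

`radsig.combat` is a native implementation of parametric empirical-Bayes
location/scale adjustment: per-gene standardization by the
covariate-adjusted grand mean and pooled variance, per-batch location and
scale estimates shrunk toward cross-gene normal and inverse-gamma priors
(hyperparameters by method of moments) via the standard fixed-point
iteration (relative tolerance 1e-6, at most 1000 iterations; passing 1e-4
reproduces the reference implementation's stopping point exactly), then
removal of the shrunk effects. Two covariate designs are supported:
**supervised** includes the outcome in the design — the estimation of
batch effects is protected from outcome-composition differences between
batches, at the price of disclosing pCR to the correction — and
**agnostic** omits it. The correction is affine per gene and batch, so an
exact inverse is provided and apply-then-invert reproduces the input to
machine precision. Degenerate finite-sample behaviour worth knowing: with
two identical batches the estimated locations are exactly zero and the
scales equal the N/(N−2) denominator factor, so re-application moves
values only by that vanishing compression.

When the outcome prevalence is (near-)equal across batches and batch
effects are independent of outcome, the two designs give near-identical
corrections — the covariate then explains nothing the batch labels do not.
The supervised-vs-agnostic contrast becomes material exactly when batch
and outcome are confounded, e.g. validating against a prevalence-balanced
external cohort from a 23%-prevalence discovery set: agnostic correction
then misattributes part of the outcome signal to batch and shifts planted
genes by a class-composition term. A linear locked model is mathematically
insensitive to such per-gene constant shifts in its AUC (they fold into a
cohort-wide offset), while threshold-based accuracy degrades sharply and
tree-based models degrade in both; the mode-contrast experiments in this
package therefore use a boosted-trees lock and report both metrics. In the
package's experiments the accuracy ordering (supervised > agnostic) is
essentially always reproduced, whereas the AUC ordering is directional but
noisy because the synthetic signal is strong enough to saturate AUC.

## External validation and the permutation null

Validation reports confusion counts at a 0.5 score threshold (recorded in
the report), sensitivity/specificity/accuracy, and AUC with a DeLong
confidence interval. The random-geneset null draws B size-matched gene
sets from the QC-passing universe; per draw, either the same learner
recipe is refit on discovery and scored on validation, or (score-only
mode) the set's mean z-score is used directly. The empirical p-value is
(r + 1)/(B + 1) with r the number of null AUCs ≥ observed (the ≥/add-one
convention; the strict-> variant is reported alongside), so the minimum
attainable p at B = 200 is 1/201 ≈ 0.005. Because the synthetic universe
is small (2,000 genes, 80 of them informative), random draws contain ~3
informative genes on average and the refit null is substantially above
0.5 — as in the original design, the null asks whether the locked gene
list beats random sets under the same recipe, not whether random sets are
uninformative. On outcome-independent data the score-only null mean is
0.5 as expected.

## Downstream biology

Genes are ranked by signed standardized mean difference between two sample
classes (ties broken by gene id). Preranked GSEA uses the weighted
Kolmogorov–Smirnov running sum (weight exponent 1 by default; 0 gives the
classic KS statistic, in which limit the complement-set identity holds),
with a gene-permutation null (the contrast is already summarized as a
ranking), NES = ES / mean |same-sign null ES|, and BH FDR across sets. On
an exact |max| = |min| tie of the running sum the positive extreme is
taken. Two enrichment analyses (e.g. predicted vs actual response status)
are compared by their shared significant sets and direction agreement.
Per-gene association with candidate biology scores uses within-cohort
ordinary least squares pooled by the same meta-analysis machinery.
Cell-type specificity assigns a gene to its top-expressing sorted
population when the linear-scale fold-change over the runner-up is ≥ 2
(inclusive); the reference used in the analysis scripts is a synthetic
stand-in, labelled as such.

## Problem sizes and numerical choices

The shipped experiments use 2,000-gene studies with the cohort sizes
above, 20 balanced iterations for DEG selection (the lean locked-model
recipe uses 10), B = 200 null draws, 500–1000 GSEA permutations, and
five-seed replication where a rate is reported — sizes chosen so a full
run of the analysis scripts completes in minutes on a laptop while leaving
every statistical contrast far from its small-sample breakdown. All
randomized operations take explicit seeds and are byte-reproducible; float
output is written at fixed precision so reruns are byte-identical.

## Known limitations

The nearest-centroid subtype caller is an approximation to published
random-forest subtype classifiers; the candidate gene memberships shipped
in examples are synthetic stand-ins, not curated signatures; nonparametric
and reference-batch variants of the EB correction are out of scope;
and the robust-DEG intersection's sensitivity at marginal effect sizes is
conservative, as quantified above.
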