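# Methods

## Problem setting

`connsel` classifies subjects (cases vs controls) from resting-state
functional connectomes and reports *which* connections carry the
discrimination. A subject's data is a T × P matrix of regional mean BOLD
time series over a P-region parcellation. Pearson correlations between all
region pairs give a symmetric P × P connectivity matrix; the Fisher
z-transform z = atanh(r) stabilizes the variance of the correlations, and
the strictly upper triangle — E = P(P−1)/2 edges — is the feature vector.
For the 273-region whole-brain parcellation the package treats as its
reference bookkeeping (210 cortical, 36 subcortical, 27 cerebellar regions),
E = 37,128. Cortical regions carry one of the seven canonical
resting-state network labels (VN, SMN, dATN, vATN, LN, FPN, DMN);
subcortical and cerebellar regions are UNASSIGNED. Edges are labeled by
their unordered endpoint-network pair so selected edges can be summarized as
intra- vs inter-network connectivity.

Numerical conventions: edge order is row-major over pairs (i, j), i < j
(`numpy.triu_indices`); correlations are clipped to |r| ≤ 1 − 1e−7 before
atanh (|r| = 1 diverges; clipping is warned about because it signals
degenerate input such as duplicated regions); matrices must be symmetric to
1e−8 absolute; atlas files are 1-based, internal indices 0-based; a
zero-variance region column is an error naming the region.

## The ensemble selector

With tens of thousands of edges and dozens-to-hundreds of subjects, single
selectors are unstable. The selector here combines three stages:

1. **Relative-importance ranking.** Five heterogeneous tree ensembles —
   extreme gradient boosting, extremely randomized trees, random forest,
   AdaBoost (depth-1 trees), gradient boosting — are fit on the training
   data; each yields a normalized importance vector. Defaults are small and
   fixed (100 trees; 50 stumps for AdaBoost; `max_features="sqrt"` for the
   forests and gradient boosting, the standard classification setting, which
   also keeps a ranking pass on ~1,200 features well under a second).
2. **Top-2% pooling.** Each ranker nominates its top k = max(1, ⌊0.02·E⌋)
   features (ties broken by ascending index); the union of the five
   nominations, with provenance, is the feature pool — at most 5k features,
   in practice far fewer because informative edges are co-nominated.
3. **SVM-FoBa refinement.** An adaptive forward-backward greedy search over
   the pool. The objective of a candidate subset is the cross-validated
   performance of a linear SVM on that subset (3 stratified folds, frozen
   per search so all candidates see identical splits; features standardized
   on the data given to the search, which is training-fold data only in any
   cross-validated context). A forward step adds the best-improving feature
   and is accepted while the improvement is at least η = 0.005; after each
   forward step, backward steps repeatedly drop the feature whose removal
   costs least, while that cost is below ν = 0.5 × the last forward gain.
   The subset size is capped at 20. All constants are configurable.

**Why the objective is the hinge loss, not accuracy.** The natural first
choice — mean CV accuracy — is a step function with resolution 1/n. On any
data where some small subset separates the sample (which, with a
winner's-curse search over dozens of candidates, happens after three or four
strong features even at realistic effect sizes), measured accuracy hits 1.0
and the search stops: the remaining genuinely informative features are never
collected, which defeats the stability analysis that downstream inference is
built on. The forward-backward greedy literature defines the search on a
continuous loss for exactly this reason. The default objective is therefore
the negative mean validation hinge loss of the same linear SVM on the same
splits: it keeps decreasing while added features genuinely widen the margin,
has a floor at zero that irrelevant features cannot beat, and leaves η and ν
meaningful on a comparable [0, 1] scale. `objective: accuracy` remains
available in the config; the greedy-vs-exhaustive equivalence check runs
under it because the accuracy optimum (perfect classification) is exactly
identifiable, whereas continuous-loss optima differ between search paths by
O(1e−4) fold-fitting noise.

**Prediction.** The five learner families are refit on the FoBa-refined
subspace and predict by unweighted majority vote (five voters — binary votes
cannot tie). The SVM regularization used inside FoBa is tuned beforehand by
stratified nested 3-fold cross-validation over C ∈ {0.01, 0.1, 1, 10}, ties
resolved to the first grid point. If FoBa selects nothing (no single feature
improves on the empty model by η), the single top-pooled feature is used,
with a loud warning.

All randomness flows from one master seed: stage seeds are
SHA-256-derived from `(master, stage-label, ...)` paths, so adding a stage
never shifts the seeds of existing ones, and every derived seed is below
2³¹.

## Baseline selectors

Four classical comparison selectors, plus one optional: Lasso and ElasticNet
(coordinate-descent regression on 0/1 labels with the penalty tuned on the
standard regularization path by inner 3-fold CV; selected = nonzero
coefficients), the Fisher-score filter (between- over within-class scatter
per feature, population variances; zero within-class variance gives an +inf
sentinel), the trace-ratio filter (maximizes tr S_b / tr S_w over k-subsets
by the standard iterative score-and-threshold algorithm, which for k = 1
reduces to the Fisher-score winner), and a two-sample Kolmogorov–Smirnov
filter. Filter methods default to k = max(1, ⌊0.02·E⌋) — one top-2% slice,
keeping their dimensionality comparable to the ensemble pool without running
the rankers inside baseline folds. Downstream classification of every
baseline selection uses the same standardize → nested-tuned linear SVM
harness, so method comparisons differ only in selection.

## Evaluation, stability, transfer

Within-cohort performance uses repeated stratified k-fold CV (5-fold for the
small cohort, 10-fold for large ones, 10 repeats by default; stratification
prevents one-class folds at these sample sizes). The whole pipeline —
ranking, pooling, tuning, FoBa, voting — runs inside each training fold;
test subjects influence nothing but the recorded predictions. Accuracy,
sensitivity (recall on cases) and specificity (recall on controls) are
computed per loop and averaged; a fold with no positives leaves sensitivity
NaN (excluded from means, warned).

Feature stability counts the loops in which each feature was selected;
features with count ≥ 10 (the threshold is a count, not a fraction,
regardless of k × repeats; configurable) form the stable set used for
network summaries, association and transfer. Methods are compared by a
paired two-sided Wilcoxon signed-rank over loop accuracies (paired t and KS
available); identical per-loop accuracies return p = 1.

Cross-cohort transfer applies a source-cohort model — its selected feature
ids and its trained voting ensemble — unchanged to every subject of the
target cohort; features are matched by id, not position, and a missing id is
an error listing the missing edges. A `refit` mode transfers only the
feature set and trains a fresh tuned linear SVM on the target, covering the
other reading of "using the features trained from" the source cohort.

## Symptom association

Per-subject connectivity summaries are correlated with symptom scores.
The default summary is the mean Fisher-z over the stable edges within a
network pair (a per-edge mode is available). Pearson r is reported with the
two-sided t-based p (n − 2 df) within diagnostic subgroups, and as a partial
correlation across all subjects controlling for group: both variables are
residualized on the group indicator (with intercept) and the residuals
correlated, with n − 3 df for the p-value. A constant control degrades to
the plain correlation with a warning. No multiple-testing correction is
applied by default (matching how small symptom batteries are convention-
ally reported); a Benjamini–Hochberg helper is provided.

## The synthetic two-cohort generator

There is no public data at the package's scale, so all validation runs on a
generator that emulates the statistical structure the pipeline assumes — and
deliberately nothing else. Each subject's Fisher-z edge vector is

    z = z_background + δ · 1[planted edge, case] + ε,   ε ~ N(0, σ²) i.i.d.

with z_background = atanh(ρ_in) within a network, atanh(ρ_out) between.
Three planted edge sets drive group differences: shared edges (drawn within
DMN and between DMN–vATN) shift cases of both cohorts by δ_shared;
child-only edges (SMN–dATN) and adult-only edges (DMN–LN) shift only their
cohort's cases. Symptom scores are generated for all subjects as
β · (mean planted-edge z) + group offset + noise, so control-group
score–connectivity correlations exist and are testable.

Defaults — the package's standard study conditions: P = 50 (seven networks
of 7 regions plus one unassigned), 60 cases + 60 controls per cohort, 10
shared + 5 child-only + 5 adult-only edges, δ = 1.0 on the z-scale,
ρ_in = 0.3, ρ_out = 0.05, σ = 0.5, β = 5, score offset 8, score noise 2.
δ/σ = 2 per planted edge is a strong but realistic univariate effect for a
planted-biomarker benchmark; the sizes keep a full 50-loop selector run in
minutes. A time-series mode embeds the same structure into per-subject
correlation matrices (tanh of the z-targets, repaired to the nearest
positive-semidefinite correlation matrix by eigenvalue clipping when
needed) and samples T = 120 multivariate-normal timepoints, exercising the
connectome module end to end.

What the generator does **not** model: spatial autocorrelation of edges,
subject-level global covariance factors, scanner/site effects, motion and
physiological noise, heavy-tailed score distributions. Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes,
with calibrated behaviour under its null — not that it will perform at any
particular level on clinical data.

## Validation protocols and the choices behind them

`connsel.protocols` fixes the standard experiments (also run by
`scripts/acceptance.py`):

- **Planted recovery** — 5-fold × 10 repeats on the default child-like
  cohort; recovery = fraction of the 15 planted edges in the stable set,
  false positives = stable non-planted edges.
- **Null calibration** — labels are freshly permuted for each of 10 repeats
  (5-fold each), accuracies and selection frequencies pooled over all 50
  loops. A single fixed permutation is *not* used: its realized "lucky"
  edges correlate with the permuted labels in every training fold, the
  rankers re-nominate them in every loop, and the frequency analysis would
  measure that one permutation's luck rather than the selector's
  false-stability rate. Averaging over permutations is the null the
  stability statistic is actually calibrated against.
- **Greedy/oracle equivalence** — 25 seeded strongly-separable instances
  (one feature tracking the labels at 12 within-class standard deviations,
  seven pure-noise features, n = 60); the forward-backward search must
  attain the exhaustive best-subset optimum of the same accuracy objective
  on every instance.
- **Selector benchmark** — 10 seeded replicates of the default planted
  study (5-fold each), ensemble selector vs the four baselines through the
  identical harness. Because all methods sit within one test subject of the
  ceiling under these conditions, the reported statistic is non-inferiority:
  the fraction of replicates in which no baseline is significantly more
  accurate (one-sided paired Wilcoxon, α = 0.05); mean paired differences
  and two-sided p-values are recorded alongside.
- **Transfer** — a model fit on the full child-like cohort applied unchanged
  to the adult-like cohort (and vice versa) under shared planted edges, and
  under a disjoint-planted variant where transfer should collapse to chance.
- **Association calibration** — the partial correlation is checked against
  an explicit residual-regression oracle to 1e−12 on a constructed 12-point
  dataset, and null correlation p-values against uniformity (KS, 1000
  simulations at n = 30).

## Known limitations

- The selector's stability statistic is calibrated against the generator's
  i.i.d.-noise null; correlated-noise nulls (realistic fMRI) will show
  higher false stability, as the single-permutation measurement above
  illustrates.
- The hinge objective can retain exactly collinear duplicates (a duplicated
  column halves its effective L2 penalty); the backward step removes
  duplicates under the accuracy objective but is not guaranteed to under
  hinge.
- Greedy search is not globally optimal on non-separable instances; the
  equivalence protocol certifies it only where the optimum is identifiable.
- Filter-baseline k and the FoBa cap (20) bound the dimensionality the
  package will report; cohorts whose signal is spread over many more edges
  than the cap will see truncated stable sets.
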