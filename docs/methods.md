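# Methods

## Problem setting

The package targets binary risk prediction on small, moderately imbalanced
clinical tables (hundreds of patients, tens of routine laboratory
features, minority fraction around 25–30%). The positive class is the
platinum-resistant group throughout; "sensitivity" always refers to
detecting resistance. Because single laboratory markers discriminate
weakly (univariable AUCs near 0.6), the method pools many weak base
classifiers and re-weights them per cross-validation fold.

## Pipeline and assumptions

**Outer evaluation.** Stratified 5-fold cross-validation. Every fitted
statistic — preprocessing parameters, selector scores, tuned
hyperparameters, SMOTE synthesis — is computed on the training split of a
fold only. An audit verifies after every fit that each synthetic sample's
parents are training-fold members and that validation folds keep their
original class composition.

**Preprocessing** (fit on train, replayed on validation):

1. *Capping*: values above a per-feature clinical upper reference limit
   are truncated to that limit. Limits are user-supplied configuration
   (no published reference table exists); the synthetic workflow emits
   stand-in caps at the sensitive class's 97.5th percentile. Upper limits
   only; no lower capping.
2. *Imputation*: chained equations — each incomplete feature is regressed
   on all others (ridge, penalty 1e-3, closed form), sweeps iterate until
   the largest imputed-cell change drops below 1e-3 of the feature's
   observed SD, at most 30 sweeps. Initial fill is the training mean.
   The ridge penalty stabilizes the solve on correlated panels; its bias
   at this magnitude is ~1e-4 relative, which the tests account for.
3. *Box–Cox*: per-feature maximum-likelihood λ after a positivity shift
   max(0, 1e-6 − min). Applied to all features by default (a config
   switch restricts nothing further); constant features get λ = 1.
   Validation values falling below the shifted training minimum are
   clamped to a tiny positive number before the power transform.
4. *Min-max scaling* to [0, 1] on training statistics; out-of-range
   validation values are clipped. Bounded inputs protect the
   distance-based learners. Constant columns map to 0.

The pipeline is fit per outer fold rather than once globally: fitting
globally would leak validation distributional information into the
transform. Per-fold fitting is the defensible default; the module API
makes the (leaky) global variant trivial to assemble for comparison.

**Oversampling.** Borderline-SMOTE, borderline-1 variant: a minority
point is a DANGER seed iff, among its m = 5 nearest neighbors (Euclidean,
on the scaled features, distance ties broken by row index), the majority
count m′ satisfies m/2 ≤ m′ < m. Pure-majority neighborhoods are noise
and never seed synthesis. Synthetic points are p + u·(q − p), u ~ U(0,1),
q drawn from p's k = 5 nearest minority neighbors; synthesis cycles over
the DANGER set until minority:majority reaches 1:1. m, k and the target
ratio are package defaults (the common defaults of the published
algorithm); they are exposed in the run configuration. If no DANGER
points exist the training split is returned unchanged with a warning.

**Selector grid.** Fourteen scoring methods behind one contract (score
every feature, higher = more relevant, take the top k = 10): ANOVA F,
pooled-variance |t|, Fisher score, reliefF (10 neighbors, all
instances), Laplacian score (heat-kernel 5-NN graph, negated), the
conditional-mutual-information family JMI / DISR / ICAP (greedy forward
selection on equal-frequency 5-bin discretized variables; the selection
order is mapped to descending rank scores), and a sparse-learning family:
least-squares and logistic-loss l2,1-regularized regressions (scored by
coefficient row norms), multi-cluster selection (spectral embedding +
LARS), nonnegative discriminative selection (alternating nonnegative
spectral indicator / l2,1 projection updates), an l2,1-regularized
orthogonal projection of the graph-Laplacian scatter, and the iterative
trace-ratio criterion. The sparse-learning methods standardize columns
internally: their row-norm scoring is only meaningful on a common scale.
Selection runs on the oversampled training view by default
(`select_before_oversample` switches to the pre-SMOTE view); both views
are training-only either way.

**Learner grid.** Twelve families — logistic regression; KNN and RBF-SVM;
decision tree, random forest, extremely randomized trees, balanced random
forest (each tree trained on a balanced bootstrap); AdaBoost, gradient
boosting, XGBoost, LightGBM, CatBoost (optional backend; the grid shrinks
with a logged warning when it is absent). Hyperparameters are tuned by
randomized search (default 20 draws; search spaces are small standard
ranges — tree depth 2–10, 50–300 estimators, log-uniform learning rates
and regularization strengths, k = 3–15 for KNN) with stratified internal
3-fold CV scored by G-mean of the 0.5-thresholded probabilities, then
refit on the full training split. G-mean is used for inner selection to
match the framework's screening metric. SVM probabilities come from Platt
sigmoid calibration on internal folds so all learners share the
probability contract. Class weights stay at learner defaults — imbalance
is already handled by oversampling — except the balanced random forest,
which is balanced by construction.

**Fusion.** Per fold, cells are ranked by validation G-mean (screened at
the fixed 0.5 threshold; ties by AUC, then lexicographic ids) and the top
10 kept. Combined score CS = 0.6·AUC + 0.4·G-mean; Softmax weights at
temperature T = 0.1 (computed with max-subtraction; as T→0 the weights
approach the argmax indicator, as T→∞ uniform). The fused probability is
the ω-weighted average, and the decision threshold is chosen per fold by
maximizing G-mean over candidate thresholds (midpoints of consecutive
distinct fused scores plus 0/1 guards; ties take the smallest). Threshold
optimization applies to the fused score only, not to individual cells,
whose screening stays at 0.5.

A deliberate fidelity point: by default the same validation fold is used
to rank cells, set weights, pick the threshold, *and* report performance
— the protocol dynamic-ensemble-selection frameworks typically follow,
but an optimistically biased one. The
`honest_selection` option instead carves a stratified 20% selection set
out of each training split for ranking/weighting/thresholding, leaving
the validation fold untouched.

**Prediction on new data.** The cross-validation produces five fold
ensembles; deployment scoring averages their fused scores with equal
weights and thresholds at the mean of the five per-fold thresholds. This
composition is the package's own choice — the protocol defines only
cross-validated behavior — and uses all trained state without refitting.
Supplying fold provenance instead scores each training patient by the
ensemble that held it out, reproducing the pooled validation scores.

**Importance.** Count of appearances in the 5×10 selected-feature sets,
normalized by the actual number of fused cells (50 at defaults), ties
broken by feature name. The "all cells" union variant is also exposed,
since the unique-feature count can be defined over either population.

**Evaluation.** Pooled confusion matrix = elementwise sum of fold
matrices; rank (Mann–Whitney, midrank-tie) AUC both per fold and on the
pooled scores — the two differ and both are reported; t-based 95% CIs
across folds, truncated to [0, 1]; DeLong placement-value test for paired
AUC comparison with a normal reference; per-feature univariable logistic
fits (statsmodels, Wald CIs, separation flagged per feature). Metrics
with empty denominators return flagged NaN rather than raising, so
subgroup tables never crash.

## Randomness and determinism

A single master seed drives everything. Sub-seeds are derived as
`SeedSequence([master, *stage_tags])`: tag 0 for fold assignment, (1,
fold) for oversampling, (2, fold, cell index) for per-cell tuning, (3,
fold) for the honest-selection split. Reruns with the same seed reproduce
fold assignments, synthetic samples, chosen hyperparameters and all
metrics exactly.

## The synthetic cohort generator

Emulates the structure of the clinical cohorts this framework targets: 322
patients (91 resistant / 231 sensitive, exact counts), 70 features in
five correlated blocks (clinical, complete blood count, liver/renal
panel, tumor markers, coagulation), latent Gaussian draws with
within-block correlation 0.5 and between-block 0.1, lognormal marginal
maps for the eight tumor markers plus the fibrin-degradation features
(FDP, D-dimer), and 1.62% completely-at-random missingness over feature
cells (the outcome is never missing). The resistant class receives
standardized latent mean shifts: Age +0.45, NL +0.35, GRAN +0.35,
GRAN# +0.30, FIB +0.30, FDP +0.30, LYM −0.30, WBC +0.25, UREA +0.25.
Directions follow the reported group differences; the magnitudes are free
calibration parameters chosen to put single-feature AUCs near 0.60,
the modest univariable regime typical of routine laboratory markers —
they are not estimates of the real cohort's effects. At this design the
one-sided two-sample t on NL has noncentrality 0.35/√(1/91 + 1/231) ≈
2.8, i.e., ≈88% power at α = 0.05, which the structural tests assert as
a Monte-Carlo floor.

What the generator does **not** emulate: missingness that depends on
clinical state (real laboratory panels are missing in blocks, not at
random), heavy-tailed measurement error, inter-laboratory unit drift,
treatment covariates, and survival time. Passing tests therefore
demonstrate that the machinery is correct and leakage-free under a known
signal, not that any real cohort's performance figures are reproduced —
hospital cohorts of this kind are privacy-restricted and no real data
ships with the package.

## Numerical choices and degenerate inputs

- Softmax computed with max-subtraction; weights sum to 1 within 1e-12.
- Threshold candidates are score midpoints, so optimality over all
  distinct classifications is exact (verified against a dense sweep).
- Tie-breaks are deterministic everywhere: feature index for score ties,
  AUC then ids for cell ranking, smallest threshold for G-mean ties, row
  index for neighbor-distance ties.
- Constant features: λ = 1 in Box–Cox, 0 after min-max, score 0 for
  variance-ratio selectors.
- Failed grid cells (learner errors, unavailable backends) are logged and
  excluded; ranking proceeds over the survivors, and fewer than 10
  survivors simply shrinks the ensemble with a warning.
- Grids smaller than the requested top-n renormalize the importance
  denominator to the actual cell count.

## Scaled-down defaults in the shipped tests

The test suite exercises full-size cohorts (322×70) on restricted 4×4
selector×learner grids with 5 randomized-search draws, and mid-size
(200×20) cohorts for the leakage probes. These sizes are the package's
chosen trade-off between coverage and turnaround; the full 168-cell grid
at 20 search draws runs the same code paths and is exercised in smaller
slices throughout the suite.

## Known limitations

- The default protocol's selection/weighting/evaluation share a fold (see
  above); use `honest_selection` for unbiased fold metrics.
- CatBoost support is optional; without the backend the grid is 154
  runnable cells out of the 168-cell roster.
- The sparse-learning selectors are compact native implementations of
  their published objectives (fixed iteration caps, multiplicative or
  reweighted updates); they match the selection behavior expected on
  well-separated signals but are not drop-in numerical replicas of any
  particular reference codebase.
- Reference ranges must be supplied by the user; the stand-in quantile
  caps are a synthetic-workflow convenience, not clinical values.
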