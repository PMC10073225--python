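# Methods

`braingut` implements a brain–gut machine-learning analysis that
discriminates obese (BMI > 30) from overweight (25 ≤ BMI < 30) adults from
two data blocks: nodal graph metrics of DTI-derived structural
connectomes, and fecal-metabolite abundances. Because the observational
study this design follows did not deposit subject-level data, the package
generates synthetic cohorts with planted, configurable group effects; the
properties under test are therefore recoverability and calibration of the
*procedure*, not any claim about real cohorts.

## Connectome model

A subject's connectome is a symmetric streamline-count matrix `c_ij` over
R parcellated regions (the demonstration setting uses R = 165, the size of
a Destrieux-style whole-brain parcellation) with region volumes `v_i`
(mm³). Connection weights volume-correct the counts:

    w_ij = c_ij / (v_i + v_j)

The divisor is the *sum* of the two region volumes. The prose convention
"divided by the individual volumes of the two interconnected regions" is
ambiguous between sum, mean and product; the sum is the prevailing
volume-correction for streamline counts and is the default, with `mean`
and `product` selectable (`volume_convention`). Note the three conventions
differ only by a global factor of 2 (mean) or a non-uniform rescaling
(product), and betweenness/eigenvector centralities are invariant to
global rescaling.

Four nodal metrics are computed on the weighted undirected graph, with
shortest paths taken under the inverse-weight edge distance
`d_ij = 1/w_ij` (a stronger connection is a shorter distance; `w_ij = 0`
means no edge):

* **strength** — `s_i = Σ_j w_ij`;
* **betweenness centrality** — fraction of shortest paths between other
  region pairs passing through region i, ties split fractionally,
  normalized by `(R−1)(R−2)/2` so values lie in [0, 1];
* **eigenvector centrality** — the Perron vector of the weight matrix,
  computed by power iteration to tolerance 1e−10 (bounded at 10⁴
  iterations), unit Euclidean norm, nonnegative orientation. Disconnected
  networks are refused with an error naming the components rather than
  silently scoring one component;
* **nodal average path length** — mean shortest-path distance from a
  region to every *reachable* other region; unreachable pairs are excluded
  and a region with no reachable partner is reported NaN (flagged, never
  coerced to zero). This metric is used throughout the results the design
  follows but is never defined in its methods; the mean-distance reading
  adopted here is a choice, recorded as such.

Flattened feature names follow the `<MetricTag>__<region>` convention
(`NodeBWCent__…`, `AvPathLength__…`, `Strength__…`, `EigCent__…`), sorted
by tag then region. The default selection is betweenness plus average path
length — the two families every reported discriminative brain feature
belongs to.

## Feature selection (SVM-RFE with voting)

Selection operates on a subjects × features block with covariates (age,
sex, diet) held apart from the selectable features.

1. **RFE ranking.** A linear-kernel SVM (C = 1 by default) is fit on the
   current feature set after z-scoring each feature on the training
   subjects; the `elimination_step` features with smallest |weight| are
   removed; repeat until the target count remains. One feature per
   iteration is the classical procedure and the default; larger steps are
   a speed/fidelity trade exposed in configuration. Standardization inside
   every fit is necessary because linear-SVM weights are scale-sensitive;
   eliminating on the *absolute* weight (not the signed weight) keeps
   strongly group-negative predictors, which signed elimination would
   discard first. Zero-variance features are dropped with a warning before
   fitting. Because elimination is deterministic and nested, the survivors
   at every candidate size k are obtained from a single elimination pass —
   mathematically identical to rerunning RFE per k, and what makes the
   search below tractable.
2. **Optimal subset size.** For every candidate k (an increasing grid; the
   full range 1..p for small p, else a ~15-point geometric grid densified
   near small k where the accuracy curve moves fastest), and for every
   leave-one-out split, features are eliminated to k on the n−1 training
   subjects only and the held-out subject is predicted from the k
   survivors. The k with the highest mean held-out accuracy wins, ties
   broken toward the smaller k. A `global` scope (rank once on all
   subjects) exists but is non-default: the split-wise refit is the
   faithful reading of a cross-validated RFE.
3. **Fold voting.** At the chosen k, RFE runs once per stratified fold
   (ten by default, seeded shuffle); each feature a fold selects gains one
   vote, so votes total `n_folds × k`. The final subset is the top k by
   votes; boundary ties are broken by the larger mean |SVM weight| across
   the folds that selected the feature, then by name.

## Final models and evaluation

Three linear families are trained on the selected features plus
covariates: linear-kernel SVM, ridge classifier (decision by the sign of
the linear score fit to ±1-coded labels; `alpha = 1/cost`), and
L2-penalized logistic regression. Age and sex enter every design; diet
enters designs containing metabolite features. Sex and diet are 0/1
indicators left unscaled; age and all features are z-scored, with the
training-set center/scale stored on the model for raw-scale application.

Evaluation is leave-one-out: for each subject the model (standardization
included) is refit on the remaining n−1 and the held-out subject scored;
the n decision scores give the confusion matrix (class 1 = obese =
positive), accuracy, per-class precision and recall (0/0 reported as NaN
with a flag), and an ROC curve (threshold sweep over unique scores,
trapezoidal area; SVM and ridge use the signed margin, logistic the
log-odds).

**Protocol caveat.** When the feature subset was selected using all
subjects, LOO evaluation of the final model inherits that selection and is
optimistically biased under the null — we measure roughly +3 to +5
accuracy points at the reduced problem sizes below. Every report carries a
`selection_inherited` note. The package also provides
`rfe.nested_loo_accuracy`, which re-runs elimination inside each split and
is the honest estimator; the permutation test (below) is the in-protocol
mechanism that exposes the bias.

## Combined model and permutation null

The combined feature set unions, per block, the features whose
standardized |weight| lies in the top `ceil(fraction × block size)` ranks
of the final brain and metabolite models (fraction 0.9 by default;
covariates never ranked; ties at the cut kept together and reported). The
printed sizes this design reproduces (83→76 brain, 57→50 metabolite) are
inconsistent with any single rounding rule — 0.9×83 = 74.7 and
0.9×57 = 51.3 — so `count_override` reproduces exact counts when needed
and the default remains the deterministic ceiling rule.

The permutation test shuffles labels uniformly, retrains the final model
and scores it with stratified ten-fold cross-validation (folds reseeded
per replicate), R = 199 replicates by default, and reports
`p = (1 + #{permuted ≥ observed}) / (R + 1)`. This generalizes the
single-shuffle check it descends from. The empirical p is uniform under
the null *only* when the evaluated design is label-independent; when
features were first selected on the real labels the p-value is
anticonservative under the null (the selection bias again), which is
exactly what makes the test informative about overfitting.

## Synthetic cohorts

The generator emulates the study conditions: 117 subjects (64 obese, 53
overweight), 165 regions, 987 metabolites (dimension defaults;
configurable). What it draws:

* **Connectomes** — one symmetric Poisson-rate template per cohort (edges
  present with probability `edge_density` = 0.35, Gamma(2, ·) rates with
  mean 40 streamlines); per subject, counts are Poisson draws from the
  template times a mild lognormal subject factor (σ = 0.10), volumes are
  region-level lognormal baselines (~2–10 cm³) times subject noise.
  The **brain effect** multiplies the expected count of every edge
  incident to an informative region by `brain_effect` in the obese group —
  injected in fiber-count space so the whole metric path is exercised.
* **Metabolites** — per-feature Gaussian log-abundance (feature means
  ~N(10, 2²), SDs uniform on [0.5, 1.5]); the **metabolite effect** shifts
  informative features' obese-group mean by `metabolite_effect`
  within-feature SDs on the log scale (a Cohen's d). The pipeline models
  log-abundances (standard metabolomics practice).
* **Covariates** — group-wise sex/diet Bernoulli and age Gaussian draws
  matching the study's clinical table (sex 19/53 vs 17/64 male, diet 12/53
  vs 29/64 American, ages ~31.5/33.2 ± ~10.5). `CovariateModel.null()`
  equalizes the groups; the zero-effect calibration uses it because the
  study-derived diet imbalance alone carries ~0.60-accuracy signal and
  "all effects null" must mean all of them.

A fixed seed reproduces a cohort bit-identically. What the generator does
*not* emulate: tractography error structure, metabolite correlation
blocks, batch effects, heavy tails, missingness. Passing tests therefore
show that the procedure recovers planted linear signal and is calibrated
under a clean null — not that it would perform identically on real data.

## Problem sizes and numerical choices

* Demonstration configuration (`PipelineConfig` defaults): 165 regions,
  200 metabolites, 8 informative regions at brain effect 1.25, 10
  informative metabolites at d = 0.8, automatic k grid. The effects were
  chosen once to yield clearly-above-chance but non-degenerate accuracies
  (roughly 0.85–0.99 across blocks); with the defaults the full run takes
  minutes on one CPU.
* Calibration suites run 25-cohort Monte-Carlo at 8 regions / 12
  metabolites with a fixed voted subset of 4, and the planted-recovery
  suite runs the stated conditions (10 informative among 500, d = 1.5,
  n = 117) with elimination step 5, which recovers the same median 9/10
  planted features as step 1 at a fifth of the cost.
* Chance level is the majority-class rate 64/117 ≈ 0.547; chance-level
  assertions use the 99% binomial band for one cohort's 117 LOO
  predictions, [0.428, 0.666]. Pooling predictions across cohorts would
  shrink the band below the procedure's intrinsic biases (inherited
  selection +0.03; honest classifiers on noise sit nearer 0.51 than the
  majority rate because they do not always vote majority), so the
  per-cohort band is the statistically defensible check.
* Power iteration tolerance 1e−10; RFE |weight| ties broken by column
  order (stable sort); vote ties as described; optimal-k ties toward
  smaller k; all fold splits stratified and seeded; every stage seeded
  from one pipeline seed, making reruns byte-identical.

## Known limitations

* The generator's independence assumptions (edges, metabolites) make
  selection easier than on correlated real data; recovery rates here are
  upper bounds.
* `optimal_k_search` is O(p²·n/step) SVM fits at full scale; the full
  1..p grid with leave-one-out at p ≈ 2000 is a cluster-scale computation.
  The geometric grid and configurable step preserve the procedure's
  definition at desk scale.
* Eigenvector centrality refuses disconnected networks by design; callers
  working with sparse cohorts should either raise `edge_density` or
  restrict to the giant component explicitly.
* The inherited-selection LOO estimate is the protocol being reimplemented,
  not a recommendation; use `nested_loo_accuracy` (or fully nested
  selection) for honest generalization estimates.
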