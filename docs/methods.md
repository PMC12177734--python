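# Methods

## Model and optimizer

`sgccapipe` fits sparse generalized canonical correlation analysis (SGCCA):
for J standardized views it maximizes the design-weighted sum of scheme-
transformed pairwise covariances between per-view component scores, subject
to a unit L2 ball and a per-view L1 budget `s_j = lambda_j * sqrt(p_j)`.
The optimizer is Gauss–Seidel block-coordinate ascent. Each block update
replaces `w_j` by the maximizer of a linear minorant of the criterion over
the feasible set; for the three schemes (horst `g(x)=x`, centroid `|x|`,
factorial `x^2`) the minorant at the current iterate is linear in `w_j`, so
every update is an exact ascent step and the recorded objective trace is
nondecreasing. The linear subproblem — maximize `<a, w>` over the
intersection of the L1 and L2 balls — is solved by soft-thresholding `a`
and L2-normalizing, with the threshold located by bisection to 1e-10 on the
resulting L1 norm; `lambda = 1` makes the L2 ball the binding set and
reduces the update to normalization.

Assumptions: complete data (participants missing any view are dropped
upstream; questionnaire skip rules are encoded as zeros beforehand),
columns standardized with training statistics, covariance — not
correlation — as the pairwise coupling (weights live on the unit L2 ball,
so the criterion is scale-free after standardization).

Initialization is deterministic: each view's leading right singular vector,
sign-fixed. When an L1 budget binds, the fit first converges unconstrained
and continues from that solution (continuation); cold starts at sparse
budgets are noticeably more prone to poor local optima. For a ladder of
sparsity levels, `lambda_objective_path` traces the path by warm-starting
each level from the previous solution, which (feasible start + monotone
ascent) guarantees the converged objective is nondecreasing in lambda —
a guarantee independent cold starts cannot give.

Successive components deflate each view by its own component score
(`X <- X - y (y'X)/(y'y)`), enforcing within-view score orthogonality on
the training data; projection of new data replays the same deflation using
the stored weights. A view whose deflated matrix falls below 1e-10 of its
original Frobenius norm is treated as exhausted: its later scores are exact
zeros rather than amplified rounding noise, and they contribute zero AVE.

Components are sign-indeterminate (per-view flips leave the centroid and
factorial criteria unchanged). For stable reporting, the clinical (anchor)
view is flipped so its largest-magnitude weight is positive and every other
view is flipped to covary positively with the anchor score. Under the horst
scheme per-view flips change the criterion, so only a global flip is
applied there.

## AVE

Inner AVE of a component is the design-weighted mean of squared
correlations between the views' scores — the cross-view coupling statistic
used for tuning and permutation testing. Outer AVE of a component for a
view is the mean squared correlation between the component score and the
view's *original* (non-deflated) variables; because own-block deflation
makes within-view scores orthogonal, per-component contributions are
disjoint and the variable-count-weighted cumulative outer AVE — the
"variance explained among all views" curve — is bounded by 1 and
nondecreasing. (Correlating against deflated matrices instead would let the
cumulative curve exceed 1 on rank-deficient data, losing its
percent-of-variance meaning.)

## Pipeline stages and their parameters

* **Residualization** — per-column OLS on [intercept, age (years), sex
  (0/1), site indicators], estimated on the training participants only and
  applied with those coefficients to everyone. All views, including the
  clinical one, are corrected identically.
* **Standardization** — training mean/SD per column, applied to test data.
* **Split** — simple random 70/30 (train size = floor of the fraction), no
  stratification.
* **Sparsity tuning** — grid of 10 equally spaced lambdas 0.1–1.0 (values
  below a view's `1/sqrt(p)` floor are clipped per view). Statistic: total
  inner AVE of a 1-component fit; null: participants permuted independently
  within each view (destroys cross-view covariance, preserves within-view
  structure), refit at the same lambda; `z = (obs - mean_null)/sd_null`;
  chosen lambda = argmax z, ties to the smaller value. Default 100–200
  permutations per grid point (configurable; the emulated design used
  1000).
* **Component count** — cumulative outer AVE at `k_max` components; chosen
  K is the last component whose marginal gain is at least `epsilon`
  (default 0.01), overridable in the config.
* **Stability selection** — `n_subsamples` (default 200; emulated design:
  10 000) half-samples drawn without replacement; a variable counts as
  selected when its weight is nonzero (|w| > 1e-12) in *any* component
  ("any-component" rather than per-component selection, because retention
  feeds one joint refit of all components); retained at frequency >= 0.9.
  Per-view opt-outs are available (`stability.skip_views`).
* **Final refit** — retained variables only, L1 disabled (lambda = 1). A
  view none of whose variables survives screening is dropped from the
  final unified model (it would contribute no stable signal to a joint
  refit); the run fails only if the clinical view empties or fewer than
  two views remain. A kept view with fewer retained variables than
  components deflates to zero partway: its later scores are exact zeros,
  contribute zero AVE, and are skipped as regression predictors.
* **Permutation significance** — B randomized models fitted to
  within-view-permuted training data (default 200; emulated design:
  10 000). Train context ranks the observed per-component training inner
  AVE among the randomized models' training inner AVEs; the test context
  projects the held-out data through the actual and the *same* randomized
  models and ranks test inner AVEs. `p = (1 + #{null >= obs})/(B + 1)`.
* **Score regression** — OLS of the clinical component score on the imaging
  component scores (intercept included); fit statistic `r = corr(observed,
  fitted)`; participant bootstrap (default 1000 draws) for CIs and
  two-sided p-values (normal approximation `estimate / bootstrap-SE`;
  percentile p available). Coefficient significance at P < .008 (about
  .05 / 7 predictors).
* **Structural coefficients** — Pearson correlation of each component
  score with its own view's residualized, standardized, non-deflated
  variables; bootstrap CI and p per coefficient; Benjamini–Hochberg within
  each (component, view) family at FDR .05. Clinical coefficients are
  also aggregated as section means (signed by default; absolute mode
  available — a signed mean of a balanced bipolar section is near zero by
  construction, which is informative in itself).

Bootstrap confidence intervals default to the **bias-corrected (BC)
percentile** interval. The plain percentile interval systematically
under-covers for the regression fit r: with seven predictors the sample r
is overfit-biased upward and resampling doubles the bias. In a calibration
experiment with known population R = 0.45 (n = 250, 500 draws, 100
replicates) plain percentile covered 88/100 while BC covered 95/100; plain
percentile remains available (`ci_method="percentile"`).

Every stochastic stage takes an explicit seed from the config (a config
with a missing seed is rejected); subsample/permutation streams are
pre-assigned from a `SeedSequence`, so results are identical for any
`n_jobs`. Two runs from one config are byte-identical.

## Synthetic data

The generator emulates the structure of a multimodal psychiatric-imaging
cohort: 8 views — one ordinal clinical view (60 items in 12 five-item
sections; the first item of each section is a gate whose zero forces the
rest of the section to zero, mimicking interview skip rules coded as
zeros) and seven continuous imaging views (24–34 variables each). All
views share `n_true_components` latent scores (exactly zero-mean,
orthonormal columns) through sparse loading matrices: per view and
component, a uniformly drawn support of `round(support_fraction * p)`
variables with loadings `±loading_scale` (supports may overlap across
components, as brain regions recur across dimensions). On top: i.i.d.
Gaussian noise (`noise_sd`) and additive linear confounds — age uniform
18–28 years, sex Bernoulli(0.5), site uniform over 3 levels — with
per-column random slopes scaled by a per-view amplitude (default 0.5).
Ordinal views discretize the continuous construction to {0, 1, 2} by
per-column tertiles before skip-rule zeroing.

Default effect size: `loading_scale = 0.4` against unit noise, i.e.
item–component correlations near 0.37 and cross-view canonical
correlations around 0.2–0.5 — the range typical of brain–behavior
covariation studies. Substantially stronger planted signal makes every
selection problem trivial and, more subtly, degenerates the permutation-z
sparsity tuning (see limitations).

What the generator does *not* emulate: spatial covariance among imaging
variables, questionnaire psychometrics (no item response model), item
difficulty structure, longitudinal correlation, scanner batch effects
beyond additive site shifts, or missingness beyond skip rules. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under clean multivariate-normal-plus-ordinal conditions — not that it
would recover structure in real cohort data with correlated noise and
model misspecification.

## Problem sizes

The test suite and the acceptance script run at desk scale: cohorts of
180–800 participants, views of 4–60 variables, 100–200 permutations and
subsamples, 50–1000 bootstrap draws, 10–100 replicates per statistical
check. These sizes put Monte-Carlo error well inside the asserted bands
(e.g. the exact binomial 95% band for a 5% rejection rate over 50
replicates) while keeping a full run to minutes on one CPU core. The
emulated design's production counts (10 000 subsamples and bootstraps,
1000 tuning permutations) are plain config values.

## Known limitations

* **Local optima.** Block-coordinate ascent certifies feasibility and
  monotone ascent, not global optimality. Continuation (from the
  unconstrained solution, and along lambda ladders) removes the failure
  modes we observed, but adversarial instances with competing near-optimal
  supports can still converge to a secondary optimum.
* **Tuning degeneracy under strong signal.** The permutation z divides by
  the null standard deviation, which shrinks as lambda decreases; when the
  planted signal is very strong the z curve becomes monotone toward the
  sparsest grid point regardless of the true support size. At realistic
  effect sizes the curve peaks at an interior lambda, but the argmax can
  still land one grid step too sparse for some data realizations, after
  which stability selection at a budget below the true support size
  splits selection frequencies across the support and can empty whole
  views (handled by the view-drop policy above). The observed inner AVE
  column in the tuning table makes this diagnosable.
* **Component-count inflation at sparse lambda.** With a binding L1 budget
  each extra component recruits fresh variables, so the cumulative
  outer-AVE curve can keep gaining more than `epsilon` past the true rank;
  the chosen K then hits `k_max` and the permutation test, not the AVE
  curve, separates real from noise components. The config exposes
  `components.override` for a manual choice.
* **Test-context permutation null reuses the training-permutation models**
  rather than refitting on permuted test data — this mirrors the emulated
  design (test data projected through actual and randomized models) and
  was verified to give nominal type-I error, but it tests the joint
  hypothesis "this fitted model generalizes", not view-independence of the
  test sample in isolation.
* Ridge-regularized (tau) RGCCA variants, kernel/tensor extensions and
  imputation are out of scope.
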