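# Methods

## The model

`boxcoxopt` treats the Box-Cox power transform as a *classification
preprocessing* step whose parameters are chosen for the downstream
classifier, not for normality.  The transform

    T(y; λ) = (y^λ − 1)/λ   for λ ≠ 0,      T(y; 0) = ln(y)

is monotone and defined for positive y only.  A matrix X ∈ ℝ^{n×p} is
transformed column-wise with one exponent per feature, Λ = [λ₁, …, λ_p].
Three parameterizations are distinguished:

* **spherical** — a single scalar λ shared by all columns;
* **diagonal** — each λⱼ chosen independently with the other coordinates
  held at 1 (i.e. untransformed);
* **full** — the joint vector Λ, realized here as iterative coordinate
  grid descent.

The optimization criterion is L = 1 − ACC, where ACC is the *in-sample*
(training-set) accuracy of the target classifier after transforming and
standardizing — deliberately no inner cross-validation.  The coordinate
search cannot reach the global in-sample optimum in general, and that
restraint appears to act as implicit regularization relative to the
exhaustive grid search.

## The pipeline

Fitting runs in a fixed stage order:

1. range-standardize each feature affinely to [1, 2] (positivity for the
   transform; the upper bound keeps large λ from exploding the feature);
2. optimize Λ against the classifier;
3. apply Box-Cox with the chosen Λ;
4. standardize to zero mean / unit variance (population divisor n);
5. train the classifier.

Prediction replays stages 1, 3, 4 with the *fitted* scaler states and the
stored Λ; nothing is refitted on test data.

Degenerate inputs: a test value far outside the training range can be mapped
to a non-positive number by the fitted range scaler, which would leave the
transform undefined.  The scaler therefore extrapolates affinely and floors
the result at 1e−6 — in-range data is untouched.  Constant training columns
map to the range midpoint 1.5 (any constant is equally uninformative inside
[1, 2]).  Zero-variance columns are centered but not scaled.  The
logarithmic branch triggers for |λ| < 1e−12.  Single-class training labels
make the criterion constant; the pipeline warns and falls back to Λ = ones
rather than erroring, so cross-validation on tiny strata cannot crash.

## Optimizers

* **grid_search_2d** — exhaustive search over the full candidate grid;
  O(gridsize^p), hence restricted to p = 2 and used as the low-dimensional
  reference.
* **spherical_search / diagonal_search** — scalar scan and per-axis scans.
  The diagonal strategy *assembles* the per-axis winners; the joint accuracy
  of the assembled vector is not guaranteed to beat the baseline, and the
  test suite constructs a criterion surface where it loses.
* **mle_lambda** — the classical profile log-likelihood maximizer
  LL(λ) = −(n/2)·ln var(T(y;λ)) + (λ−1)·Σ ln yᵢ, computed with
  `scipy.stats.boxcox_llf`, maximized by a 201-point grid pre-scan over
  [−5, 5] followed by bounded scalar refinement (the pre-scan guards against
  local optima; the likelihood names the criterion, not the numeric method).
  Used both as a baseline strategy and as the default start point of the
  iterative search.
* **iterative_search** — coordinate descent: per epoch, each direction is
  scanned over the candidate grid with the others held at the incumbent;
  the incumbent and best accuracy update only on *strict* improvement, so
  ties keep the earliest candidate in scan order and the best accuracy is
  non-decreasing by construction.  Cost is exactly epochs·p·gridsize
  criterion evaluations — linear in p.

### Refinements and their semantics

Three epoch-periodic refinements modify the plain coordinate search.  When
several fire on the same epoch they apply in the order finer → shuffle →
shift (grid state changes before path decisions; fixed and documented).

* **shift** (period `shift_epoch`): a fresh start point is drawn uniformly
  over the grid's bounding interval and becomes the trial base until a
  strict improvement clears shift mode.  Within an epoch the base carries
  the best-found coordinate of each scanned axis even when the global best
  was not beaten; if shift mode survives into the next epoch the evolved
  base is kept — re-scanning the identical start under a deterministic
  criterion would waste the epoch.
* **shuffle** (period `shuffle_epoch`): the direction order is permuted once
  with the seeded RNG and persists until the next shuffle epoch.
* **finer** (period `finer_epoch`): every candidate is multiplied by
  `finer_factor` (default 0.5) and the grid switches to *local* mode,
  attaching the candidates as offsets to the incumbent coordinate.
  Cardinality is preserved, so cost is unchanged while resolution doubles.

Named presets (gridsize, epochs, shift, shuffle, finer): Iterative grid
search 11/4/4/4/4, Shift 11/8/4/8/8, Shuffle 11/8/8/2/8, Finer 11/8/8/8/4,
Combined 1 11/16/8/2/4, Combined 2 21/16/8/2/4.  In the first preset all
three periods coincide with the final epoch; with strict-improvement
bookkeeping a final-epoch trigger can only improve the returned incumbent.

## Evaluation protocols

Two deliberately different paths exist:

* `evaluate_cv` — the honest estimate: repeated stratified k-fold CV
  (defaults 10 folds × 5 repetitions, repetition r seeded with
  base_seed + r) where scalers and Λ are fitted inside each training fold.
* `grid_exploration` — the exploratory heatmap: the full
  (pre-range-standardized) matrix is transformed at a fixed (λ₁, λ₂)
  *before* splitting; each fold then standard-scales on its training part,
  trains and tests.  Because the transform at fixed Λ is element-wise, the
  only cross-fold leak is the global range standardization.  The cell at
  Λ = [1, 1] equals the no-transform baseline: λ = 1 is a pure unit shift,
  which the subsequent standardization removes exactly.

`annotate_optima` marks on the heatmap the full optimum (global argmax,
row-major first on ties), the spherical optimum (best diagonal cell) and the
diagonal optimum (argmax of the λ₂ = 1 column combined with the argmax of
the λ₁ = 1 row; axis ties are resolved by evaluating each tied combination's
joint cell and keeping the best, remaining ties by scan order).  F1 uses the
lexicographically larger label as the positive class (a macro switch is
provided); multi-class inputs always use macro averaging.

## Synthetic data

The four generator families mirror the standard scikit-learn toy problems:
concentric Gaussian quantile shells, two interleaving half circles,
isotropic Gaussian blobs, and a linearly-mixed two-informative-feature
problem.  Defaults — n = 1000, half-circle noise 0, blob spread 1.5, class
separation 1.0, seed 42 — give visually well-formed 2-D problems and stable
CV estimates; all are configurable.  Generators are deterministic per seed
and class-balanced to within one sample.  What they do *not* emulate:
feature correlation structure of real measurements, heavy-tailed or
discrete features, label noise and class imbalance — so passing tests show
that the machinery behaves as specified on clean geometry, not that a given
real dataset will gain accuracy.

## Problem sizes and numerical choices

The test suite scales its simulations to desk size as the package's own
choice: oracle-equivalence checks use 30-sample fixtures with 5×5 grids;
the heatmap-consistency check uses the half circles at n = 500 with the full
11×11 grid and 10×5 CV; the replicated full-vs-baseline comparison uses 10
regenerated linearly-mixed datasets at n = 300 with 5-fold × 2-repetition CV
on a 6-point λ grid {−5, −3, −1, 1, 3, 5} per axis (the grid contains 1, so
the baseline cell is always present).  MLE recovery is asserted on
lognormal data (σ = 0.25, n = 2000) over 20 seeded replicates with an
18-of-20 pass rule.

Numerical conventions collected in one place: log-branch tolerance 1e−12;
positivity floor 1e−6; standardization divisor n; strict-improvement ("first
wins") tie-breaking in every search; heatmap rows are λ₁ and columns λ₂,
stored with explicit axis vectors.

## Known limitations

* The in-sample criterion can overfit aggressively for high-capacity
  classifiers; the honest estimate is always `evaluate_cv`.
* `grid_search_2d` is exponential in p and intentionally limited to p = 2.
* The diagonal strategy can assemble a jointly poor Λ — by design, as a
  comparison point.
* No shift estimation for non-positive data beyond the range scaler; no
  Yeo-Johnson family; no probability calibration or multi-label targets.
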