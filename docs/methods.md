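# Methods

## The model chain

The package treats post-stroke motor prognosis as a two-layer linear
problem. First, each patient's spatial pattern of white-matter disconnection
is compressed: the 372-region vector of average disconnection probabilities
is regressed (OLS with intercept) on a fixed 372 × 46 component basis, and
the unstandardised coefficients — the *component scores* — become the
patient's feature vector. Per-patient adjusted R²,
`1 − (1 − R²)(n − 1)/(n − p − 1)` with `n = 372`, `p = 46`, reports how much
of the pattern the basis captures. Second, a motor outcome (one latent
score per body side, obtained by oblique-rotation PCA of a 16-test
battery) is predicted from the 46 scores by one of six linear families,
evaluated out of sample under repeated resampling.

Assumptions inherited from this design: region averaging is unweighted
(every voxel of a structure counts equally); the per-patient regression
treats regions as exchangeable observations; outcome models are linear in
the component scores with i.i.d. errors; and the left/right outcome scores
are analysed per side × timepoint cell, never jointly.

## Synthetic studies and what they emulate

Real inputs of this kind (lesion masks, normative-tractography disconnection
maps, a clinical motor battery) are not publicly available, so the
generator produces studies with the same statistical skeleton and a fully
recorded ground truth.

* **Basis** — i.i.d. normal loadings smoothed along the region index by a
  moving average; `smoothness` controls adjacent-region autocorrelation
  (the index stands in for spatial adjacency; there is no real geometry).
* **Disconnection patterns** — each patient mixes `n_active` components
  with signed, magnitude-sorted `|Normal|` weights; the noiseless mixture
  is mapped affinely onto [0.02, 0.98], Gaussian voxel-level noise is
  added, and values are clipped to [0, 1]. The affine squash keeps the
  region vector exactly linear in the (rescaled) weights, so the recorded
  `mixing_weights` are recovered *exactly* by the downstream regression
  when noise is zero. A logistic squash is available
  (`squash="logistic"`) for bounded-but-nonlinear data; it sacrifices this
  identity and is off by default. The marginal distribution of real
  disconnection values is not known to us; the affine map is a neutral
  stand-in, not a claim about that distribution.
* **Outcomes** — per timepoint, a latent factor per side is
  `scores · w + ε` with `k_active` nonzero weights per cell (disjoint
  left/right supports). The noise is demeaned, projected orthogonal to the
  signal, and rescaled exactly, so the generating signal fraction of latent
  variance is exactly `1/(1 + outcome_noise_sd²)` — with the default
  `outcome_noise_sd = 0.5`, exactly 0.8. The right-side latent is the
  `ρ`-mix of the standardized sides, which imposes the configured
  left/right correlation (default 0.5, a moderate bilateral covariance);
  consequently, for `ρ ≠ 0` the *effective* right-side weight vector
  recorded in the truth has up to `2·k_active` nonzeros. Raw test scores
  are monotone affine maps of their side's latent factor plus test noise in
  latent-SD units; the ARAT total is rounded and clamped to [0, 57].
* **Voxel studies** — contiguous equal-size parcels on a grid, constant
  fill per parcel, so region averaging inverts the construction exactly;
  no anatomically realistic lesion shapes.

Defaults mirror the study scale: 62 patients, 372 regions, 46 components,
sparse mixing with 5 active components per patient, voxel noise SD 0.02.
Every generator is a pure function of (parameters, master seed); child
seeds derive from fixed offsets (`strokepred._utils.SEED_OFFSETS`).

What passing tests on these studies show: the estimators, selection rules,
tuning loop and summaries do what they claim, with exact parameter
recovery in the noiseless limit and calibrated nulls. What they do not
show: performance on real disconnection maps, whose spatial statistics,
missingness and measurement error the generator does not attempt to model.

## Numerical and protocol choices

* **Standardization** — every family z-scores predictors and centers the
  response with training-fold statistics only; penalties are therefore
  comparable across components and selection is invariant to affine
  rescaling of raw predictors.
* **LOOCV on a fixed design** — the tuner standardizes the training set
  once and leaves one patient out of that fixed matrix. This choice makes
  the classical OLS identity `e_i/(1 − h_ii)` hold exactly (it is the test
  oracle) and sidesteps re-standardization ambiguity inside folds. Ridge
  folds are solved by rank-one Gram downdates plus one eigendecomposition
  per fold (algebraically identical to refitting); stepwise folds compute
  the greedy selection path once per fold, since the path does not depend
  on the predictor cap; lasso folds are warm-started along the descending
  penalty path.
* **Ridge** — `(XᵀX + λ₂I)⁻¹Xᵀy`, intercept unpenalized; grid
  `λ₂ ∈ 10^linspace(−4, 4, 60)`.
* **Lasso** — objective `(1/2n)‖y − Xβ‖² + λ₁‖β‖₁`; cyclic coordinate
  descent (numba-jitted) with soft-thresholding, tol `1e-7` on the largest
  coefficient change, `max_iter` 10 000 sweeps. Between chunks of sweeps an
  active-set Newton step solves the KKT stationarity system for the current
  sign pattern and is accepted only when the signs verify and no inactive
  gradient exceeds `λ₁` — an exact accelerator that rescues the
  near-interpolation corner (`p = 46` close to fold size 49 at small
  penalties) where plain coordinate descent crawls. Grid
  `λ₁ ∈ λ_max·10^linspace(−4, 0, 60)` with `λ_max = max|Xᵀy|/n`.
* **Selection rules** — hierarchical elimination follows component index
  order with nested-model F-tests at α = 0.05, repeating full passes until
  the selection stabilizes (a single forward pass can miss a weak
  predictor masked by stronger ones not yet admitted; iteration makes the
  noiseless case exact). Stepwise uses coefficient t-test p-values,
  α = 0.05, ties to the lower index, and the max-predictor cap 1..46 as
  its tuned hyperparameter. A numerically perfect fit (RSS at machine
  zero) counts a nonzero coefficient as maximally significant and a zero
  one as maximally insignificant.
* **Splits** — `|train| = round(f·n)`: 0.80 → 50/12 and 0.78 → 48/14 on 62
  patients. Repetition `r` uses seed `base_seed + r`.
* **Accuracy** — squared Pearson correlation between predictions and test
  observations (affine-invariant by construction; a documented consequence
  is that uniform shrinkage does not change it). The `1 − SSE/SST`
  definition is computed alongside and stored in every result. Constant
  predictions (e.g. an empty lasso model predicting the training mean)
  score 0 by convention; constant test outcomes are recorded as missing,
  not dropped.
* **Mode** — Gaussian KDE with Silverman bandwidth on 512 grid points over
  [min, max], argmax; histogram fallback available. Below 10 repetitions
  the median is reported instead.
* **Behavioral PCA** — correlation-matrix PCA, Kaiser-normalized varimax by
  pairwise Jacobi rotations (the closed-form pair angle also converges in
  the degenerate equal-eigenvalue case), promax power 4, factor scores by
  the regression method. Variance explained is the unrotated top-2
  eigenvalue share. Factors are assigned to sides by structure loadings
  and signed so the side's grip-strength test loads positively; the PCA is
  fitted per timepoint (pooled fitting available behind a flag — which of
  the two the original lineage used is not documented). The 9-hole peg
  test enters as pegs/second, i.e. already higher-is-better.

## Design decisions that were genuinely open

* The behavioral literature this battery imitates says only "oblique
  rotation"; promax (power 4) is that lineage's standard and is the
  default, recorded as configurable.
* The hierarchical families have no hyperparameter and use the 78/22 split
  without LOOCV; tuned families use 80/20 with LOOCV inside the training
  set (folds of size `n_train − 1`).
* Optional covariate columns (age, total lesion load) can be appended as
  ordinary predictors; off by default.
* The lasso "retained" set for overlap summaries is defined as components
  selected in at least half of the repetitions.

## Known limitations

* **The p ≈ n estimation floor.** With 46 coefficients estimated from 50
  training patients, per-coefficient estimation noise `σ²/n` accumulates to
  the same order as the signal: at generating R² = 0.8 the population test
  correlation² is capped near 0.5–0.65 whatever the penalty, because ridge
  shrinkage in a near-orthogonal design scales signal and estimation noise
  alike and a correlation metric is blind to uniform shrinkage. The
  repeated-split R² distribution at this scale is therefore broad (often
  bimodal, with a pile of near-zero splits), and its KDE mode is both
  downward-shifted and unstable across replicate studies. The compact
  well-powered configuration (8 components, 62 patients) recovers the
  generating R² to within 0.02 — the machinery is exact; the full-scale
  gap is information-theoretic, not an implementation artifact. Top-3
  importance recovery is robust at both scales.
* Sparse patient mixing (5 active of 46 components) leaves each predictor
  column with only a handful of informative entries, further limiting
  estimability at the clinical scale. A second consequence: the latent
  outcome is heavy-tailed (most patients' mixing support misses the outcome
  support entirely), and *greedy forward* selection can stall below the
  true active set even with zero noise — two active components acting as
  mutual suppressors are never admitted one-at-a-time, leave-one-out RMSE
  then genuinely favors a small predictor cap, and out-of-sample R² on an
  unlucky test set can collapse. Backward elimination is immune in the
  noiseless case (the saturated fit has exact zeros on inactive
  components). The noiseless identity therefore holds unconditionally for
  the chain (score recovery, adjusted R²) and for backward / penalized
  families, but for forward selection only on configurations where the
  greedy path can reach the active set.
* The generator's battery has no missing assessments, no floor/ceiling
  pile-ups (beyond ARAT clamping), and no practice effects across
  timepoints.
* Lesion-load baselines use toy rectangular parcels and thresholded
  probability volumes as lesion stand-ins, adequate for exercising the
  arithmetic, not for anatomical claims.
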