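# Methods

## The structural causal model

The simulator draws, for each patient, the chain

    C  →  (V_O, M_O, V_T)  →  D_plan  →  D_del  →  Y  ←  C

* **Confounder.** C ~ Normal(0, 1). Unit variance is forced by the outcome
  model: with the (C/2) interaction below, the per-patient effect
  θ_ij + (C/2)ξ_ij must have variance ξ_ij²/4, and mean zero makes the
  population ATE equal θ exactly.
* **Plan parameters.** V_T = v_T·exp(0.3·C + ε), V_O = v_O·exp(−0.3·C + ε),
  M_O = softplus(1 + 0.5·C + ε), each ε ~ Normal(0, 0.1) (variance 0.1)
  independently. These are strictly positive, non-linear in C, and carry
  enough C-signal that confounding is material (|corr(C, V·)| ≳ 0.3). The
  base scales v_T, v_O default to 0.22 and 0.15 of min(Nx, Ny): the two
  grid sizes are the same anatomy at two resolutions, so fall-offs scale
  with the grid while the uncertainty magnitudes (which are in absolute
  dose/pixel units) do not.
* **Planned dose.** A Gaussian tumor peak of height `dose_max` (width V_T)
  plus a wide low-amplitude halo (amplitude 0.25·dose_max, width 3·V_T —
  the entrance/exit dose bath of a rotational delivery), multiplied by an
  organ-ray suppression factor 1 − exp(−M_O)·exp(−d_R²/2V_O²), where d_R
  is the perpendicular distance to the horizontal line of pixels through
  the fixed OAR. Larger M_O permits more dose on the ray; larger V_O
  widens the sparing trough. The halo matters statistically, not just
  cosmetically: without it, pixels far from every tumor position have
  vanishing dose variance across patients and the voxel-wise slope
  cov/var explodes numerically, swamping every comparison.
* **Tumor placement.** Uniform over the grid outside a Chebyshev radius 2
  around the OAR.
* **Delivery uncertainties**, applied in the order: rigid shift of the
  planned field by continuous (L_x, L_y) ~ Normal(0, σ²_L) with bilinear
  interpolation and edge-clamped boundary; then an additive
  Gaussian-process field with RBF kernel k(x,x′) = exp(−‖x−x′‖²/2σ²_GP)
  (unit marginal variance, scaled by M_GP); then i.i.d. per-pixel white
  noise of variance σ²_UD. Negative delivered doses are recorded, not
  clipped — the estimators are linear and clipping would distort the
  causal model. An alternative reading of σ²_GP as an output variance
  (fixed unit length-scale) is selectable via `gp_sigma2_role`.
* **Ground truth.** θ is a Gaussian bump A_θ·exp(−d²/2s²) truncated to a
  disk centered on the organ ray two pixels off the OAR; ξ is the same
  bump with amplitude A_ξ. Defaults (10×10): disk radius 3, width 2,
  A_θ = 12, A_ξ = 0.1 — 28 non-zero pixels out of 100.
* **Outcome.** Y = 5C + U_Y + Σ_ij [D_ij θ_ij + (C/2) D_ij ξ_ij] with
  U_Y ~ Normal(0, σ²_UY), σ²_UY = 1 by default. The direct C coefficient
  is fixed at 5.

Everything is a pure function of (config, seed); cohorts regenerate
bitwise-identically.

### Calibration of the defaults

The absolute scales (A_θ, A_ξ, dose_max, halo) were set once so that the
voxel-wise comparators exhibit their characteristic failure scale —
MSE_tot near 10⁶ at 10×10, n_obs = 500 — while the data remain a
plausible dose/outcome model, and then frozen; all evaluation below uses
these frozen defaults. A_ξ is kept small relative to A_θ because the
interaction term acts, from the estimators' viewpoint, as dose-scaled
outcome noise; its absolute scale is otherwise a free choice of the
simulation design.

## Estimators

* **Voxel-wise regression** (planned or delivered dose): per pixel, the
  univariate OLS slope of Y on D_ij with intercept and no covariates —
  the field's standard analysis, and deliberately so: any adjustment
  would blur the causal/non-causal contrast the comparison is built to
  show. Pixels with dose variance below `var_tol` (10⁻¹²) are flagged
  degenerate and given slope 0.
* **Back-door adjustment.** The ATE of D_ij on Y is identified by
  adjusting for all other dose pixels plus either C (variant a) or
  {V_O, M_O, V_T} (variant b, the default — robust to direct
  plan-parameter effects on the outcome). The full design is therefore
  [all Nx·Ny dose pixels | V_O, M_O, V_T].
* **Causal regression without sparsity**: one OLS on that design. It is
  declared *non-converged* — no pseudo-inverse fallback — when the
  intercept-augmented design is rank-deficient or p ≥ n. At 25×25
  (p = 628) it therefore fails for every tested cohort size, which is the
  intended behavior of the comparison, not an error state to be patched.
* **Causal Adaptive Lasso (CAL)**: an adaptive lasso on the same design.
  Stage 1 fits a ridge pilot over the penalized (dose) columns,
  λ_ridge chosen by 10-fold CV minimizing mean squared prediction error
  on a 100-point log grid; adaptive weights are w_j = 1/|β*_j|^γ with
  γ = 1. Stage 2 solves the weighted lasso, λ chosen the same way
  (mean-CV-error rule, not 1-SE). {V_O, M_O, V_T} carry weight exactly 0
  and are always in the model.
* **Pixel-wise CAL**: Nx·Ny separate adaptive-lasso fits; fit (i, j)
  additionally forces in the D_ij column, so the target coefficient is
  never shrunk away.

### Numerical choices

* **Forced-in columns** are handled exactly by projection
  (Frisch–Waugh–Lovell): y and the penalized columns are residualized on
  [1 | forced block], the weighted lasso is solved on residuals, and the
  forced block is recovered by least squares given the penalized fit.
  This is the exact joint minimizer of the weighted objective with zero
  weights on the forced block.
* **Weighted penalty by rescaling**: penalized column j is scaled by
  1/w_j, a standard lasso is solved (scikit-learn's coordinate descent),
  and coefficients are back-scaled. The test suite checks this against an
  independent hand-written coordinate descent on the weighted objective.
* **Standardization**: the ridge pilot runs on unit-variance columns and
  is back-transformed, so the weights live on the original scale; the
  lasso stage applies the weights via rescaling with *no* second
  standardization — standardizing again would undo the adaptive weights.
* **Penalty grids**: 100 log-spaced points down to 10⁻⁴ of the maximum.
  For the lasso the maximum is the smallest penalty zeroing every
  penalized coefficient (max_j |X̃_jᵀ y|/n); a ridge penalty has no such
  zeroing point, so its grid top is set to the total sum of squares of
  the standardized design (n·p), which over-shrinks by construction and
  brackets the useful range from above.
* **Near-zero pilots**: |β*_j| < 10⁻⁸ would overflow 1/|β*|; such columns
  are excluded from the lasso (the infinite-weight limit) and reported
  with coefficient 0.
* **CV folds** are drawn from a dedicated seed (ridge and lasso stages use
  independent shuffles derived from it), making every fit deterministic
  given (cohort, seed).
* **Ridge CV cost**: one SVD per fold, then the whole λ path via filter
  factors — 10 SVDs total regardless of grid size.

## Monte Carlo evaluation

For a setting and method, `monte_carlo` runs n_sim independent
simulate→fit cycles with per-replicate seeds derived from
(master seed, setting hash, replicate index) via `SeedSequence`, then
forms the bias array B = mean_k θ̂_k − θ, per-pixel MSE
(mean_k (θ̂_k − θ)²), and MSE_tot (its sum). Non-converged replicates are
excluded and counted; a setting with zero converged replicates yields an
invalid summary rather than numbers. `run_grid` sweeps settings × methods
into a long-format table; `parameter_grid` enumerates the full factorial
(3·4⁴ = 768 settings per grid size), and `uncertainty_subset` provides
the desk-scale 12-setting subset: each of the four uncertainty
parameters swept over {3·10⁻¹², 3·10⁻¹, 3} with the other three at
3·10⁻², covering every tabulated value of every parameter.

Problem sizes used by the shipped acceptance checks: 20 replicates per
setting at 10×10 and 10 replicates at 25×25 (three settings: the 3·10⁻²
baseline, σ²_UD = 3, and σ²_L = 3); defaults for exploratory use are 100
and 25 replicates respectively.

## What the simulation does and does not show

The generator reproduces the features that break voxel-wise analysis —
plan personalization (confounding), near-collinearity of neighboring
pixels, sparse spatial response, realistic delivery noise — with a
linear outcome and a single composite delivered dose per patient. It does
not model 3D anatomy, organ/tumor shape variation, segmentation-driven
confounding, fractionation, or non-linear dose response, so passing
results say nothing about those regimes; they show that *given* the
assumed causal structure, back-door adjustment plus oracle-property
sparsity recovers per-pixel effects that unadjusted regression cannot.

## Known limitations

* **Weak identifiability under near-deterministic delivery.** When the
  dosimetric white noise is essentially off (σ²_UD = 3·10⁻¹²) and the
  other uncertainties are small, the delivered dose lies close to a
  5-parameter manifold (tumor position plus three plan parameters), and
  the outcome retains irreducible noise (U_Y plus the confounder's
  residual 5·C given the plan parameters, s.d. ≈ 2.2 under the default
  SCM constants). In that regime the ~28 collinear signal coefficients
  cannot be jointly estimated to small total error by *any* estimator of
  this class: ordinary least squares given the exact true support — the
  oracle — already incurs total squared error of a few hundred on such
  cohorts, and CAL tracks that floor (while still beating the voxel-wise
  comparators by three to four orders of magnitude, and keeping the null
  region exactly zero). With any appreciable delivery noise the floor
  drops by orders of magnitude.
* The organ ray is a single axis-aligned line; real OAR geometry is
  richer.
* Hyperparameter selection uses the mean-CV-error rule throughout;
  the 1-SE rule would give sparser, more biased fits and is not exposed.
* `bias_map_report` heatmap rendering needs matplotlib (optional
  extra); array dumps are plain `.npy` and never require it.
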