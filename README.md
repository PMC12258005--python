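# caldose

Causal effect estimation for high-dimensional, spatial, multi-collinear
treatments, demonstrated on simulated radiotherapy outcome data.

## The problem

Voxel-based analysis — regressing a complication outcome on the radiation
dose at each voxel, one univariate regression per voxel — is the de-facto
method for mapping spatial dose–response in radiotherapy cohorts. It has a
structural flaw: treatment plans are personalized. A patient covariate
C (say, concurrent chemotherapy dose) shapes the plan through clinical
parameters (tumor fall-off V_T, organ-ray fall-off V_O, organ-ray dose
magnitude M_O) *and* affects the outcome directly, confounding every
voxel-level dose–outcome association. On top of that, dose at neighboring
voxels is almost perfectly collinear, so unadjusted per-voxel slopes soak
up the effect of the entire dose distribution.

`caldose` implements, end to end:

1. **A structural causal model simulator** of 2D planned and delivered
   dose distributions (10×10 or 25×25 pixel grids by default). Plans put
   a Gaussian dose peak on a randomly placed tumor while suppressing dose
   along a fixed organ ray; delivery adds a rigid setup shift
   (L ~ N(0, σ²_L) per axis), a spatially correlated Gaussian-process
   motion field (RBF kernel, magnitude M_GP, kernel parameter σ²_GP), and
   per-pixel white dosimetric noise (σ²_UD). The outcome is linear:

   Y = 5·C + U_Y + Σ_ij [ D_ij·θ_ij + (C/2)·D_ij·ξ_ij ],

   with sparse ground-truth effect (θ) and interaction (ξ) arrays, so the
   per-pixel average treatment effect (ATE) is exactly θ.

2. **Five per-pixel ATE estimators**: voxel-wise OLS on planned and on
   delivered dose (the field's standard), an unregularized back-door
   regression on all dose pixels plus {V_O, M_O, V_T}, the **Causal
   Adaptive Lasso (CAL)** — an adaptive lasso (weights w_j = 1/|β*_j|^γ
   from a cross-validated ridge pilot, γ = 1, 10-fold CV for both
   penalties) on the same back-door adjustment set with the plan
   parameters forced in — and a pixel-wise CAL that runs one adaptive
   lasso per pixel with that pixel's dose column also forced in.

3. **A Monte Carlo evaluation harness** computing the bias array
   B_ij = mean_k θ̂_ijk − θ_ij, per-pixel MSE, and the global metric
   MSE_tot = Σ_ij MSE_ij over grids of uncertainty settings.

Everything is written in scikit-learn style (`fit`, fitted attributes
with trailing underscores, `get_params`/`set_params`), so the estimators
compose with sklearn tooling; module-level functions (`fit_cal`,
`fit_pixelwise`, ...) wrap the classes for cohort-level use.

## Worked example

```python
import numpy as np
from caldose import SimulationConfig, simulate_cohort, fit_cal, fit_pixelwise

cfg = SimulationConfig(seed=1)            # 10x10, n_obs=500, moderate noise
cohort = simulate_cohort(cfg)
theta = cohort.estimands.theta            # ground-truth ATE array

cal = fit_cal(cohort, random_state=0)
pw = fit_pixelwise(cohort, "planned")

print("CAL   sq-err:", round(((cal.theta_hat - theta) ** 2).sum(), 1))
print("voxel sq-err:", round(((pw.theta_hat - theta) ** 2).sum(), 1))
zero = theta == 0
print("null pixels set exactly to 0:", round((cal.theta_hat[zero] == 0).mean(), 2))
```

prints

```
CAL   sq-err: 69.7
voxel sq-err: 811428.7
null pixels set exactly to 0: 1.0
```

i.e. on one confounded cohort the causal sparse estimator's total squared
error is roughly four orders of magnitude below the voxel-wise baseline,
and it sets every truly null pixel exactly to zero — the adaptive
lasso's oracle-style selection at work.

The same pipeline is scriptable from the shell:

```bash
caldose simulate --seed 1 --out runs/cohort
caldose estimate --cohort runs/cohort --methods cal,pixelwise_planned --out runs/est
caldose evaluate --n-sim 20 --seed 1 --out runs/eval   # 12-setting sweep
```

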