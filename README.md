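# mmsgl — multimodal sparse-group-lasso + TV regression

`mmsgl` finds brain (or other tissue) regions whose voxel-wise measurements
are *jointly* associated with a continuous per-subject outcome across two
co-registered imaging modalities — the motivating case being R2* and
quantitative-susceptibility MRI maps, both sensitive to iron, regressed on
age over a deep-gray-matter mask. It is aimed at neuroimaging researchers
with small cohorts (n of order 100) and very high voxel counts (p ≫ n) who
need support estimates that are sparse, spatially compact, and stable
across modalities and training sets.

## The estimator

With standardized per-modality design matrices `X₁, X₂ ∈ ℝⁿˣᵖ` and outcome
`y ∈ ℝⁿ`, the coefficient fields solve

```
min  ‖y − X₁β₁ − X₂β₂‖²
     + λ₁(‖β₁‖₁ + ‖β₂‖₁)                 lasso — voxel selection
     + λ₂(‖∇β₁‖₁ + ‖∇β₂‖₁)               anisotropic TV — compact regions
     + λ₃ Σⱼ √(β₁ⱼ² + β₂ⱼ²)              group — cross-modality overlap
```

where `∇` stacks masked forward differences along the three axes. The
group term encourages, without forcing, the two modalities to select the
same voxels ("joint support" = voxels nonzero in both). Two baselines share
the machinery: **JS** (joint sparse, `λ₃ = 0`) and **IS** (independent
per-modality lasso+TV fits, predictions averaged).

The problem is solved by ADMM: the L1/TV terms split onto an auxiliary
variable with a closed-form soft-threshold update; the remaining smooth +
group subproblem is minimized by FISTA with voxel-wise block
soft-thresholding; iteration stops on primal/dual residuals plus a
subproblem stationarity check. Hyperparameters are tuned on a
`(λ, r₁,₂, r₃)` grid (the three weights always sum to `λ`) by BIC.
See `docs/methods.md` for the model, solver, tuning, and generator details.

## Worked example

Simulate a two-modality cohort with four correlated signal blocks per
modality, tune the sparse-group-lasso estimator by BIC, and score it
against the known truth:

```python
from mmsgl import (SimulationConfig, SolverSettings, generate_truth,
                   generate_dataset, standardize, grid_search, default_grid,
                   predict, dice, r_squared)

cfg = SimulationConfig(
    shape=(16, 16, 4), block_extent=(4, 4, 2),
    mode2_xy_choices=(3, 4, 5), mode2_z_choices=(2,),
    rho_spatial=0.5, eta_mode=0.2, n_train=100, n_test=200,
)
truth = generate_truth(cfg, seed=7)
X1, X2, y = generate_dataset(truth, cfg, cfg.n_train, seed=8)
X1_test, X2_test, y_test = generate_dataset(truth, cfg, cfg.n_test, seed=9)

design = standardize([X1, X2], y, space=truth.space, scale_y=True)
fit, scores = grid_search(
    "sgl", design, default_grid("sgl", n_lambda=10),
    SolverSettings(max_iter=300), criterion="bic_fixed",
    penalty_scale=cfg.n_train, sigma2=cfg.noise_sd**2,
)

y_hat = predict(fit, design, [X1_test, X2_test])
print(f"selected lambda : {scores.lam[scores.score.idxmin()]:.4f}")
print(f"voxels selected : {fit.full_support.size} of {2 * truth.p}")
print(f"test R^2        : {r_squared(y_test, y_hat):.3f}")
print(f"full-support Dice vs truth : {dice(fit.full_support, truth.full_support):.3f}")
print(f"joint-support Dice vs truth: {dice(fit.joint_support, truth.joint_support):.3f}")
```

Output:

```
selected lambda : 0.0498
voxels selected : 407 of 2048
test R^2        : 0.962
full-support Dice vs truth : 0.829
joint-support Dice vs truth: 0.811
```

The tuned model keeps 407 of 2048 voxel coefficients, explains 96% of the
held-out outcome variance, and its estimated support overlaps the true
signal blocks with Dice ≈ 0.83 (0.81 for the region selected in *both*
modalities — the joint support the group penalty is designed to recover).

## Real-data workflow

Volumes are NIfTI, cohorts are delimited tables (one volume path per
modality per subject), and the `mmsgl` command drives the standard steps,
each from a small YAML config:

```sh
mmsgl simulate sim.yaml     # synthetic cohort -> NIfTI + cohort.csv (+ truth)
mmsgl fit      fit.yaml     # one model at fixed penalties -> coefficients,
                            #   labeled support map (0/1/2/3 = none/m1/m2/joint)
mmsgl tune     tune.yaml    # BIC grid search -> score table + best fit
mmsgl cv       cv.yaml      # k-fold CV (per-fold tuning, support stability)
mmsgl evaluate ev.yaml      # score a saved fit on an independent cohort
```

Every run writes a manifest (config hash, seed, versions); identical
configs and seeds reproduce outputs bit for bit.

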