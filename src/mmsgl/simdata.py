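"""Synthetic two-modality imaging data with block-structured supports.

The generator emulates a small-sample multimodal imaging study.  Each
modality is a 32x32x8 volume; the true signal of modality 1 lives on four
disjoint 8x8x4 blocks placed in the four (x, y) quadrants (z-centered), with
effect sizes 0.1/0.2/0.3/0.4.  Modality-2 blocks are co-centered with the
modality-1 blocks but their extents are drawn uniformly from
{6..10} x {6..10} x {4, 5}, so the supports overlap partially rather than
coincide.  Background voxels are i.i.d. standard normal.  Within a block,
voxel pairs are correlated as ``rho ** d0`` where ``d0`` is the number of
differing lattice coordinates (L0 distance); pairs in corresponding blocks
of the two modes carry an extra factor ``eta``.  The response is

    y = 0.01 + X1 beta1 + X2 beta2 + eps,   eps ~ N(0, I).

Two named settings: low correlation (rho=0.5, eta=0.2) and high correlation
(rho=0.8, eta=0.5); training size 100, test size 500.

``run_study1`` measures average recovery over independently drawn truths;
``run_study2`` measures stability of the estimated supports across datasets
drawn from one fixed truth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import evaluation, models, tuning
from .admm import SolverSettings
from .operators import VoxelSpace, build_voxel_space

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_truth",
    "generate_dataset",
    "run_study1",
    "run_study2",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, correlation, and sample-size parameters of the generator."""

    shape: tuple = (32, 32, 8)
    block_extent: tuple = (8, 8, 4)
    mode2_xy_choices: tuple = (6, 7, 8, 9, 10)
    mode2_z_choices: tuple = (4, 5)
    effect_sizes: tuple = (0.1, 0.2, 0.3, 0.4)
    rho_spatial: float = 0.5
    eta_mode: float = 0.2
    n_train: int = 100
    n_test: int = 500
    intercept: float = 0.01
    noise_sd: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.rho_spatial < 1.0:
            raise ValueError("rho_spatial must lie in [0, 1)")
        if not 0.0 <= self.eta_mode < 1.0:
            raise ValueError("eta_mode must lie in [0, 1)")
        if len(self.effect_sizes) != 4:
            raise ValueError("exactly four blocks (one effect size each)")

    @staticmethod
    def low_correlation(**kw) -> "SimulationConfig":
        return SimulationConfig(rho_spatial=0.5, eta_mode=0.2, **kw)

    @staticmethod
    def high_correlation(**kw) -> "SimulationConfig":
        return SimulationConfig(rho_spatial=0.8, eta_mode=0.5, **kw)

    def scaled(self, factor: int = 2, n_test: int | None = None) -> "SimulationConfig":
        """Proportionally smaller volume/blocks for quick desk-scale runs."""
        f = int(factor)
        return replace(
            self,
            shape=tuple(max(1, s // f) for s in self.shape),
            block_extent=tuple(max(1, b // f) for b in self.block_extent),
            mode2_xy_choices=tuple(sorted({max(1, c // f) for c in self.mode2_xy_choices})),
            mode2_z_choices=tuple(sorted({max(1, c // f) for c in self.mode2_z_choices})),
            n_test=n_test if n_test is not None else self.n_test,
        )


@dataclass
class Block:
    origin: tuple
    extent: tuple
    effect: float

    def slices(self):
        return tuple(slice(o, o + e) for o, e in zip(self.origin, self.extent))

    @property
    def center2(self):
        # doubled center coordinates (integer even for even extents)
        return tuple(2 * o + e for o, e in zip(self.origin, self.extent))


@dataclass
class SyntheticTruth:
    """Ground-truth geometry and coefficient fields for one simulation."""

    space: VoxelSpace
    blocks: list  # per mode: list of 4 Block
    beta_list: list  # per mode: p-vector

    @property
    def p(self) -> int:
        return self.space.p

    def support(self, modality: int) -> np.ndarray:
        return np.flatnonzero(self.beta_list[modality] != 0.0)

    @property
    def joint_support(self) -> np.ndarray:
        return np.intersect1d(self.support(0), self.support(1), assume_unique=True)

    @property
    def full_support(self) -> np.ndarray:
        p = self.p
        return np.concatenate([self.support(k) + k * p for k in range(len(self.beta_list))])


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _block_centers(shape, nz_center):
    nx, ny, _ = shape
    lo_x, hi_x = nx // 4, 3 * nx // 4
    lo_y, hi_y = ny // 4, 3 * ny // 4
    # fixed order: bottom, left, right, top (effect 0.1, 0.2, 0.3, 0.4)
    return [(lo_x, lo_y, nz_center), (lo_x, hi_y, nz_center),
            (hi_x, lo_y, nz_center), (hi_x, hi_y, nz_center)]


def _place(center, extent, shape):
    origin = tuple(c - e // 2 for c, e in zip(center, extent))
    for o, e, s in zip(origin, extent, shape):
        if o < 0 or o + e > s:
            raise ValueError(
                f"block extent {extent} at center {center} does not fit in {shape}"
            )
    return origin


def generate_truth(config: SimulationConfig, seed=0) -> SyntheticTruth:
    """Draw a ground truth: block geometry and the true coefficient fields."""
    rng = _rng(seed)
    shape = config.shape
    nz_center = shape[2] // 2
    centers = _block_centers(shape, nz_center)

    blocks1, blocks2 = [], []
    for center, effect in zip(centers, config.effect_sizes):
        e1 = config.block_extent
        blocks1.append(Block(_place(center, e1, shape), e1, effect))
        e2 = (
            int(rng.choice(config.mode2_xy_choices)),
            int(rng.choice(config.mode2_xy_choices)),
            int(rng.choice(config.mode2_z_choices)),
        )
        blocks2.append(Block(_place(center, e2, shape), e2, effect))

    for blist in (blocks1, blocks2):
        for a, b in itertools.combinations(blist, 2):
            if all(
                a.origin[d] < b.origin[d] + b.extent[d]
                and b.origin[d] < a.origin[d] + a.extent[d]
                for d in range(3)
            ):
                raise ValueError("overlapping blocks: volume too small for the extents")

    space = build_voxel_space(shape, np.ones(shape, dtype=bool))
    beta_list = []
    for blist in (blocks1, blocks2):
        vol = np.zeros(shape)
        for blk in blist:
            vol[blk.slices()] = blk.effect
        beta_list.append(space.from_volume(vol))
    return SyntheticTruth(space=space, blocks=[blocks1, blocks2], beta_list=beta_list)


def _block_voxels(space, blk):
    idx = np.zeros(space.shape, dtype=bool)
    idx[blk.slices()] = True
    return np.flatnonzero(space.from_volume(idx.astype(np.int8)) > 0)


def _l0_dist(c_a, c_b):
    return sum((c_a[:, None, d] != c_b[None, :, d]).astype(np.int8) for d in range(3))


def _pair_correlation(coords1, coords2, rho, eta):
    m1 = coords1.shape[0]
    R = np.empty((m1 + coords2.shape[0],) * 2)
    R[:m1, :m1] = rho ** _l0_dist(coords1, coords1)
    R[m1:, m1:] = rho ** _l0_dist(coords2, coords2)
    cross = eta * rho ** _l0_dist(coords1, coords2)
    R[:m1, m1:] = cross
    R[m1:, :m1] = cross.T
    return R


def _safe_cholesky(R):
    try:
        return np.linalg.cholesky(R), 0.0
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        adj = float(max(0.0, 1e-8 - w.min()))
        w = np.maximum(w, 1e-8)
        warnings.warn(
            f"block covariance repaired to nearest PD (max eigenvalue adjustment {adj:.3g})",
            RuntimeWarning,
        )
        return np.linalg.cholesky((V * w) @ V.T), adj


def generate_dataset(truth: SyntheticTruth, config: SimulationConfig, n: int, seed=0):
    """Draw ``n`` subjects: two design matrices and the linear response.

    Background voxels are i.i.d. N(0, 1).  Each of the four block pairs
    (modality-1 block plus the corresponding modality-2 block) is drawn
    jointly from the Cholesky factor of its target correlation matrix, so
    every voxel keeps unit marginal variance.
    """
    rng = _rng(seed)
    space = truth.space
    p = space.p
    X = [rng.standard_normal((n, p)) for _ in truth.beta_list]
    coords_all = space.coords()
    for blk1, blk2 in zip(*truth.blocks):
        idx1 = _block_voxels(space, blk1)
        idx2 = _block_voxels(space, blk2)
        R = _pair_correlation(
            coords_all[idx1], coords_all[idx2], config.rho_spatial, config.eta_mode
        )
        L, _ = _safe_cholesky(R)
        Z = rng.standard_normal((n, R.shape[0])) @ L.T
        X[0][:, idx1] = Z[:, : idx1.size]
        X[1][:, idx2] = Z[:, idx1.size:]
    y = (
        config.intercept
        + sum(Xk @ bk for Xk, bk in zip(X, truth.beta_list))
        + config.noise_sd * rng.standard_normal(n)
    )
    return X[0], X[1], y


# ---------------------------------------------------------------------------
# Simulation studies
# ---------------------------------------------------------------------------

#: solver controls used for the study fits (support accuracy at study scale
#: is tolerance-limited well before max_iter on these problems)
STUDY_SETTINGS = SolverSettings(max_iter=300, inner_max_iter=20, inner_tol=1e-5)


def _study_grids(model_set, n_lambda, grids=None):
    out = {m: tuning.default_grid(m, n_lambda=n_lambda) for m in model_set}
    if grids:
        out.update(grids)
    return out


def _study_design(X1, X2, y, space):
    # fit on the SD-scaled response with penalties scaled by n (the MSE form
    # of the objective): the default lambda grid then spans the full range
    # from dense to empty fits
    return models.standardize([X1, X2], y, space=space, scale_y=True)


def _evaluate_fit(fit, design, truth, test):
    X1_te, X2_te, y_te = test
    yhat_te = models.predict(fit, design, [X1_te, X2_te])
    return dict(
        train_mae=evaluation.mae(design.y, models.predict(fit, design)),
        test_mae=evaluation.mae(y_te, yhat_te),
        test_r2=evaluation.r_squared(y_te, yhat_te),
        dice_full=evaluation.dice(fit.full_support, truth.full_support),
        dice_joint=evaluation.dice(fit.joint_support, truth.joint_support),
    )


def _summarize(per_run: pd.DataFrame, extra_cols=()) -> pd.DataFrame:
    cols = ["train_mae", "test_mae", "test_r2", "dice_full", "dice_joint", *extra_cols]
    rows = []
    for model, grp in per_run.groupby("model", sort=False):
        row = {"model": model, "n_runs": len(grp)}
        for c in cols:
            if c in grp:
                row[f"{c}_mean"] = grp[c].mean()
                row[f"{c}_sd"] = grp[c].std(ddof=1) if len(grp) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_study1(
    config: SimulationConfig,
    n_sims: int = 10,
    model_set=("is", "js", "sgl"),
    n_lambda: int = 10,
    grids: dict | None = None,
    settings: SolverSettings | None = None,
    seed: int = 0,
    criterion: str = "bic_fixed",
):
    """Average recovery over ``n_sims`` independently drawn ground truths.

    For each simulation a fresh truth, training set (``n_train``), and test
    set (``n_test``) are drawn; each model in ``model_set`` is tuned by the
    information criterion over its default grid and scored.  Returns
    ``(summary, per_run)``: per-model means/SDs and the per-simulation rows.
    """
    settings = settings or STUDY_SETTINGS
    grids = _study_grids(model_set, n_lambda, grids)
    ss = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(ss.spawn(n_sims)):
        rng = np.random.default_rng(child)
        truth = generate_truth(config, rng)
        X1, X2, y = generate_dataset(truth, config, config.n_train, rng)
        test = generate_dataset(truth, config, config.n_test, rng)
        design = _study_design(X1, X2, y, truth.space)
        for model in model_set:
            fit, _ = tuning.grid_search(
                model, design, grids[model], settings, criterion,
                penalty_scale=config.n_train, sigma2=config.noise_sd**2,
            )
            rows.append(dict(sim=i, model=model, **_evaluate_fit(fit, design, truth, test)))
    per_run = pd.DataFrame(rows)
    return _summarize(per_run), per_run


def run_study2(
    config: SimulationConfig,
    n_datasets: int = 5,
    model_set=("is", "js", "sgl"),
    n_lambda: int = 10,
    grids: dict | None = None,
    settings: SolverSettings | None = None,
    seed: int = 0,
    criterion: str = "bic_fixed",
):
    """Support stability across datasets drawn from one fixed ground truth.

    One truth is drawn; ``n_datasets`` independent training/test sets are
    generated from it.  In addition to the study-1 metrics, the pairwise
    Dice of the estimated supports over all C(n_datasets, 2) pairs is
    reported per model.  Returns ``(summary, per_run)``.
    """
    settings = settings or STUDY_SETTINGS
    grids = _study_grids(model_set, n_lambda, grids)
    ss = np.random.SeedSequence(seed)
    truth_rng, *data_children = ss.spawn(n_datasets + 1)
    truth = generate_truth(config, np.random.default_rng(truth_rng))
    rows = []
    supports = {m: {"full": [], "joint": []} for m in model_set}
    for i, child in enumerate(data_children):
        rng = np.random.default_rng(child)
        X1, X2, y = generate_dataset(truth, config, config.n_train, rng)
        test = generate_dataset(truth, config, config.n_test, rng)
        design = _study_design(X1, X2, y, truth.space)
        for model in model_set:
            fit, _ = tuning.grid_search(
                model, design, grids[model], settings, criterion,
                penalty_scale=config.n_train, sigma2=config.noise_sd**2,
            )
            rows.append(dict(dataset=i, model=model, **_evaluate_fit(fit, design, truth, test)))
            supports[model]["full"].append(fit.full_support)
            supports[model]["joint"].append(fit.joint_support)
    per_run = pd.DataFrame(rows)
    summary = _summarize(per_run)
    for model in model_set:
        mf, sf = evaluation.pairwise_dice(supports[model]["full"])
        mj, sj = evaluation.pairwise_dice(supports[model]["joint"])
        sel = summary.model == model
        summary.loc[sel, "pairwise_dice_full_mean"] = mf
        summary.loc[sel, "pairwise_dice_full_sd"] = sf
        summary.loc[sel, "pairwise_dice_joint_mean"] = mj
        summary.loc[sel, "pairwise_dice_joint_sd"] = sj
    return summary, per_run
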