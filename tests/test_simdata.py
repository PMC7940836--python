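"""Synthetic-data generator geometry, correlation structure, and studies."""

import numpy as np
import pytest

import mmsgl as M
from mmsgl import simdata
from mmsgl.simdata import SimulationConfig


@pytest.fixture(scope="module")
def lc_truth():
    cfg = SimulationConfig.low_correlation()
    return cfg, simdata.generate_truth(cfg, 0)


class TestTruthGeometry:
    def test_mode1_support_size(self, lc_truth):
        _, truth = lc_truth
        # four disjoint 8x8x4 blocks
        assert truth.support(0).size == 4 * 8 * 8 * 4 == 1024

    def test_mode2_extents_within_choices(self):
        cfg = SimulationConfig.low_correlation()
        for seed in range(5):
            truth = simdata.generate_truth(cfg, seed)
            for blk in truth.blocks[1]:
                assert blk.extent[0] in cfg.mode2_xy_choices
                assert blk.extent[1] in cfg.mode2_xy_choices
                assert blk.extent[2] in cfg.mode2_z_choices

    def test_cocentered_containment_joint_size(self):
        # a 6x6x4 mode-2 block co-centered in an 8x8x4 mode-1 block is fully
        # contained, so each block contributes 6*6*4 = 144 joint voxels
        cfg = SimulationConfig(mode2_xy_choices=(6,), mode2_z_choices=(4,))
        truth = simdata.generate_truth(cfg, 0)
        assert truth.joint_support.size == 4 * 144

    def test_effects_assigned_in_fixed_order(self, lc_truth):
        _, truth = lc_truth
        for blist in truth.blocks:
            assert [b.effect for b in blist] == [0.1, 0.2, 0.3, 0.4]

    def test_blocks_disjoint(self, lc_truth):
        _, truth = lc_truth
        for k in range(2):
            sizes = sum(np.prod(b.extent) for b in truth.blocks[k])
            assert truth.support(k).size == sizes  # no double counting

    def test_infeasible_extent_rejected(self):
        cfg = SimulationConfig(shape=(8, 8, 8), block_extent=(8, 8, 4))
        with pytest.raises(ValueError):
            simdata.generate_truth(cfg, 0)

    def test_total_feature_count(self, lc_truth):
        cfg, truth = lc_truth
        X1, X2, y = simdata.generate_dataset(truth, cfg, 3, 0)
        assert X1.shape[1] + X2.shape[1] == 16384


class TestDatasetStatistics:
    SMALL = SimulationConfig(
        shape=(16, 16, 4), block_extent=(4, 4, 2),
        mode2_xy_choices=(4,), mode2_z_choices=(2,),
        rho_spatial=0.5, eta_mode=0.2,
    )

    def test_reproducible_given_seed(self):
        truth = simdata.generate_truth(self.SMALL, 1)
        a = simdata.generate_dataset(truth, self.SMALL, 10, 42)
        b = simdata.generate_dataset(truth, self.SMALL, 10, 42)
        for x, z in zip(a, b):
            np.testing.assert_array_equal(x, z)

    def test_independence_limit(self):
        cfg = SimulationConfig(
            shape=(16, 16, 4), block_extent=(4, 4, 2),
            mode2_xy_choices=(4,), mode2_z_choices=(2,),
            rho_spatial=0.0, eta_mode=0.0,
        )
        truth = simdata.generate_truth(cfg, 1)
        X1, X2, _ = simdata.generate_dataset(truth, cfg, 4000, 7)
        idx = truth.support(0)[:20]
        C = np.corrcoef(X1[:, idx].T)
        off = C[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.08  # ~5 sigma at n=4000

    def test_adjacent_in_block_correlation(self):
        truth = simdata.generate_truth(self.SMALL, 1)
        X1, _, _ = simdata.generate_dataset(truth, self.SMALL, 4000, 3)
        vols = truth.space.to_volume(np.arange(truth.p).astype(float)).astype(int)
        blk = truth.blocks[0][2]
        sl = blk.slices()
        cols = vols[sl]
        # x-adjacent pairs within the block
        rs = []
        for (a, b) in zip(cols[:-1].ravel(), cols[1:].ravel()):
            rs.append(np.corrcoef(X1[:, a], X1[:, b])[0, 1])
        assert np.mean(rs) == pytest.approx(self.SMALL.rho_spatial, abs=0.05)

    def test_correlation_decays_with_l0_distance(self):
        truth = simdata.generate_truth(self.SMALL, 1)
        X1, _, _ = simdata.generate_dataset(truth, self.SMALL, 6000, 9)
        blk = truth.blocks[0][3]
        vols = truth.space.to_volume(np.arange(truth.p).astype(float)).astype(int)
        o = blk.origin
        base = vols[o[0], o[1], o[2]]
        d1 = vols[o[0] + 1, o[1], o[2]]
        d2 = vols[o[0] + 1, o[1] + 1, o[2]]
        d3 = vols[o[0] + 1, o[1] + 1, o[2] + 1]
        cors = [np.corrcoef(X1[:, base], X1[:, j])[0, 1] for j in (d1, d2, d3)]
        assert cors[0] > cors[1] > cors[2] > 0

    def test_cross_mode_correlation_scaled_by_eta(self):
        truth = simdata.generate_truth(self.SMALL, 1)
        X1, X2, _ = simdata.generate_dataset(truth, self.SMALL, 6000, 5)
        # same lattice location in corresponding blocks: correlation ~ eta
        b1, b2 = truth.blocks[0][1], truth.blocks[1][1]
        vols = truth.space.to_volume(np.arange(truth.p).astype(float)).astype(int)
        shared = vols[b2.slices()]  # mode-2 block is contained in mode-1's here
        rs = [
            np.corrcoef(X1[:, j], X2[:, j])[0, 1] for j in shared.ravel()[:30]
        ]
        assert np.mean(rs) == pytest.approx(self.SMALL.eta_mode, abs=0.05)

    def test_response_mean_and_form(self):
        truth = simdata.generate_truth(self.SMALL, 1)
        X1, X2, y = simdata.generate_dataset(truth, self.SMALL, 20000, 11)
        # signal columns have zero mean, so E[y] is the intercept
        se = y.std(ddof=1) / np.sqrt(len(y))
        assert abs(y.mean() - 0.01) < 3 * se
        # and y is exactly linear in the data up to N(0,1) noise
        resid = y - 0.01 - X1 @ truth.beta_list[0] - X2 @ truth.beta_list[1]
        assert resid.std(ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_nonpd_matrix_repaired_with_warning(self):
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        with pytest.warns(RuntimeWarning, match="repaired"):
            L, adj = simdata._safe_cholesky(R)
        assert adj > 0
        w = np.linalg.eigvalsh(L @ L.T)
        assert w.min() >= 0


class TestStudies:
    TINY = SimulationConfig(
        shape=(8, 8, 4), block_extent=(2, 2, 2),
        mode2_xy_choices=(2,), mode2_z_choices=(2,),
        effect_sizes=(1.0, 2.0, 3.0, 4.0),
        rho_spatial=0.3, eta_mode=0.2, n_train=60, n_test=60,
    )

    def test_study1_shape_and_singleton_model(self):
        summary, per = simdata.run_study1(
            self.TINY, n_sims=2, model_set=("sgl",), n_lambda=4, seed=3,
            settings=M.SolverSettings(max_iter=200),
        )
        assert list(summary.model) == ["sgl"]
        assert len(per) == 2
        assert {"test_r2_mean", "dice_full_sd", "train_mae_mean"} <= set(summary.columns)

    def test_study1_single_sim_has_no_sd(self):
        summary, _ = simdata.run_study1(
            self.TINY, n_sims=1, model_set=("sgl",), n_lambda=3, seed=3,
            settings=M.SolverSettings(max_iter=200),
        )
        assert np.isnan(summary.test_r2_sd.iloc[0])

    def test_study2_pairwise_columns_and_counts(self):
        summary, per = simdata.run_study2(
            self.TINY, n_datasets=2, model_set=("sgl",), n_lambda=3, seed=4,
            settings=M.SolverSettings(max_iter=200),
        )
        assert len(per) == 2
        # a single pair: mean defined, SD reported as 0
        assert 0.0 <= summary.pairwise_dice_full_mean.iloc[0] <= 1.0
        assert summary.pairwise_dice_full_sd.iloc[0] == 0.0
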