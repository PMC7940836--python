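import numpy as np
import pytest

import mmsgl as M


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def line_space():
    """12-voxel 1D chain (TV acts along a single axis)."""
    shape = (12, 1, 1)
    return M.build_voxel_space(shape, np.ones(shape, bool))


@pytest.fixture
def grid_space():
    """Small true-3D lattice (4 x 3 x 2 = 24 voxels, all in-mask)."""
    shape = (4, 3, 2)
    return M.build_voxel_space(shape, np.ones(shape, bool))


def make_problem(space, n=20, n_signal=3, noise=0.1, seed=0):
    """Two-modality regression problem with a few strong coefficients."""
    rng = np.random.default_rng(seed)
    p = space.p
    X1 = rng.standard_normal((n, p))
    X2 = rng.standard_normal((n, p))
    beta = np.zeros(2 * p)
    idx = rng.choice(2 * p, size=n_signal, replace=False)
    beta[idx] = rng.choice([-2.0, 1.5, 2.5], size=n_signal)
    y = np.hstack([X1, X2]) @ beta + noise * rng.standard_normal(n)
    return X1, X2, y, beta


@pytest.fixture
def small_problem(line_space):
    X1, X2, y, beta = make_problem(line_space, n=20, seed=3)
    return line_space, X1, X2, y, beta


#: settings tight enough that solver error is negligible in oracle checks
TIGHT = M.SolverSettings(tol_scale=1e-6, max_iter=4000)
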