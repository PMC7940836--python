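"""Voxel lattices, masked finite-difference operators, and proximal primitives.

The coefficient field of each imaging modality lives on a 3D voxel lattice
restricted to a binary mask.  This module builds

* :class:`VoxelSpace` — the bijection between in-mask voxel coordinates and
  flat feature indices ``0..p-1`` (row-major / C order over ``(x, y, z)``;
  this flattening order is part of the public file contract),
* the sparse forward-difference gradient operator ``D`` (anisotropic total
  variation acts through ``||D beta||_1``),
* the stacked constraint operator ``A`` used by the ADMM splitting, with its
  penalty-weight vector ``Lambda``,
* the scalar and block soft-thresholding operators (proximal maps of the
  L1 norm and of the voxel-wise Euclidean group norm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "VoxelSpace",
    "OperatorBundle",
    "build_voxel_space",
    "build_gradient_operator",
    "build_operator_bundle",
    "soft_threshold",
    "block_soft_threshold",
]


@dataclass(frozen=True)
class VoxelSpace:
    """An in-mask voxel lattice with a fixed coordinate/index bijection.

    Attributes
    ----------
    shape : tuple of int
        Volume dimensions ``(nx, ny, nz)``.
    mask : ndarray of bool
        Boolean volume of that shape; ``p`` = number of True entries.
    flat_index : ndarray of int
        ``p`` flat (C-order) positions of the in-mask voxels, sorted.
    inverse : ndarray of int
        Full-volume C-order array mapping a voxel's flat position to its
        in-mask index, or -1 outside the mask.
    """

    shape: tuple[int, int, int]
    mask: np.ndarray
    flat_index: np.ndarray = field(repr=False)
    inverse: np.ndarray = field(repr=False)

    @property
    def p(self) -> int:
        return int(self.flat_index.size)

    def coords(self) -> np.ndarray:
        """Integer (p, 3) array of in-mask voxel coordinates, index order."""
        return np.stack(np.unravel_index(self.flat_index, self.shape), axis=1)

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a p-vector back onto the full 3D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.p:
            raise ValueError(f"expected length-{self.p} vector, got {values.shape}")
        vol = np.full(self.shape, fill, dtype=values.dtype)
        vol.flat[self.flat_index] = values
        return vol

    def from_volume(self, volume: np.ndarray) -> np.ndarray:
        """Extract the in-mask voxels of a volume as a p-vector."""
        volume = np.asarray(volume)
        if volume.shape != self.shape:
            raise ValueError(f"volume shape {volume.shape} != space shape {self.shape}")
        return volume.reshape(-1)[self.flat_index]


def build_voxel_space(shape, mask) -> VoxelSpace:
    """Create a :class:`VoxelSpace` from a shape triple and boolean mask."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be a triple (nx, ny, nz)")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match {shape}")
    if not mask.any():
        raise ValueError("mask is empty: at least one voxel must be selected")
    flat_index = np.flatnonzero(mask.reshape(-1))
    inverse = np.full(int(np.prod(shape)), -1, dtype=np.int64)
    inverse[flat_index] = np.arange(flat_index.size)
    return VoxelSpace(shape=shape, mask=mask, flat_index=flat_index, inverse=inverse)


def build_gradient_operator(space: VoxelSpace) -> sp.csr_matrix:
    """Masked forward-difference gradient ``D``: p-vectors -> 3p-vectors.

    Rows are stacked axis-major: rows ``[0, p)`` are x-differences, ``[p, 2p)``
    y, ``[2p, 3p)`` z.  The row for voxel ``v`` along an axis is
    ``beta[v + e_axis] - beta[v]`` when both voxels are in-mask; otherwise the
    row is identically zero (implicit Neumann boundary), so ``D`` annihilates
    constant in-mask fields exactly.
    """
    p = space.p
    coords = space.coords()
    nx, ny, nz = space.shape
    rows, cols, vals = [], [], []
    for axis in range(3):
        nbr = coords.copy()
        nbr[:, axis] += 1
        in_bounds = nbr[:, axis] < space.shape[axis]
        nbr_flat = np.ravel_multi_index(
            (nbr[in_bounds, 0], nbr[in_bounds, 1], nbr[in_bounds, 2]), space.shape
        )
        nbr_idx = space.inverse[nbr_flat]
        ok = nbr_idx >= 0
        v_idx = np.arange(p)[in_bounds][ok]
        n_idx = nbr_idx[ok]
        base = axis * p
        rows.append(base + v_idx)
        cols.append(n_idx)
        vals.append(np.ones(v_idx.size))
        rows.append(base + v_idx)
        cols.append(v_idx)
        vals.append(-np.ones(v_idx.size))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(3 * p, p))


@dataclass
class OperatorBundle:
    """Operators shared by all ADMM fits on a given voxel space.

    ``A`` stacks, block-diagonally per modality, the identity over the
    gradient: for ``m`` modalities it maps ``m*p``-vectors to ``4*m*p``-vectors
    with per-modality blocks ``[I_p; D]``.  ``lambda_weights`` builds the
    matching weight vector (lasso weight on identity rows, TV weight on
    gradient rows).
    """

    space: VoxelSpace
    D: sp.csr_matrix
    A: sp.csr_matrix
    n_modalities: int
    # largest eigenvalue of A^T A, cached for FISTA step sizes
    _AtA_norm: float | None = None

    @property
    def p(self) -> int:
        return self.space.p

    def lambda_weights(self, lambda1: float, lambda2: float) -> np.ndarray:
        if lambda1 < 0 or lambda2 < 0:
            raise ValueError("penalty weights must be nonnegative")
        p = self.p
        block = np.concatenate([np.full(p, lambda1), np.full(3 * p, lambda2)])
        return np.tile(block, self.n_modalities)

    def AtA_norm(self) -> float:
        if self._AtA_norm is None:
            AtA = (self.A.T @ self.A).tocsr()
            # power iteration; AtA is symmetric PSD
            rng = np.random.default_rng(0)
            v = rng.standard_normal(AtA.shape[0])
            v /= np.linalg.norm(v)
            lam = 0.0
            for _ in range(100):
                w = AtA @ v
                lam_new = float(np.linalg.norm(w))
                v = w / lam_new
                if abs(lam_new - lam) <= 1e-10 * max(lam_new, 1.0):
                    lam = lam_new
                    break
                lam = lam_new
            self._AtA_norm = lam * 1.01  # slack so 1/L is a safe step
        return self._AtA_norm


def build_operator_bundle(space: VoxelSpace, n_modalities: int = 2) -> OperatorBundle:
    """Build ``D`` and the stacked constraint operator ``A`` for a space."""
    if n_modalities < 1:
        raise ValueError("need at least one modality")
    D = build_gradient_operator(space)
    block = sp.vstack([sp.identity(space.p, format="csr"), D], format="csr")
    A = sp.block_diag([block] * n_modalities, format="csr")
    return OperatorBundle(space=space, D=D, A=A, n_modalities=n_modalities)


def soft_threshold(x, t):
    """Soft-thresholding ``S_t(x) = sgn(x) * max(|x| - t, 0)``.

    ``t`` may be a scalar or an array broadcastable against ``x``; all entries
    must be nonnegative.  This is the proximal operator of ``t * |.|``.
    """
    t = np.asarray(t)
    if np.any(t < 0):
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x)
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def block_soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    """Block (group) soft-thresholding ``v * max(1 - t/||v||_2, 0)``.

    Proximal operator of ``t * ||.||_2``; returns the zero vector when
    ``||v||_2 <= t``.  On 1-vectors it reduces to :func:`soft_threshold`.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    v = np.asarray(v, dtype=float)
    nrm = np.linalg.norm(v)
    if nrm <= t:
        return np.zeros_like(v)
    return v * (1.0 - t / nrm)


def block_soft_threshold_rows(V: np.ndarray, t: float) -> np.ndarray:
    """Row-wise group soft-thresholding of a (p, m) array of coefficient
    groups; each row is shrunk toward zero by ``t`` in Euclidean norm."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    if t == 0:
        return V
    nrm = np.linalg.norm(V, axis=1)
    scale = np.zeros_like(nrm)
    nz = nrm > t
    scale[nz] = 1.0 - t / nrm[nz]
    return V * scale[:, None]
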