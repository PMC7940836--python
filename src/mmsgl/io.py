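"""File I/O: NIfTI volumes, cohort tables, support maps, fit containers.

Volumes are NIfTI (.nii/.nii.gz) read through nibabel; cohort tables and
reports are delimited text.  The mapping between volumes and flat feature
vectors uses the :class:`~mmsgl.operators.VoxelSpace` flattening order
(C order over (x, y, z)); affine/header metadata of the mask is carried
through to outputs unchanged but plays no role in computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .admm import FitResult
from .models import ISFit
from .operators import VoxelSpace, build_voxel_space

__all__ = [
    "load_mask",
    "load_cohort",
    "export_support_map",
    "save_fit",
    "load_fit",
    "write_dataset",
]


def load_mask(mask_path) -> tuple[VoxelSpace, nib.Nifti1Image]:
    """Read a binary mask volume and build the voxel space over it."""
    img = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be a 3D volume, got shape {data.shape}")
    space = build_voxel_space(data.shape, data > 0)
    return space, img


def load_cohort(table_path, mask_path, response_col: str = "response"):
    """Read a cohort table and assemble per-modality design matrices.

    The delimited table needs a subject-id column, a continuous response
    column, and one volume-path column per modality (every column whose name
    ends in ``_path``, in table order).  Relative volume paths are resolved
    against the table's directory.  Returns ``(raw_X_list, y, space, table)``.
    """
    table_path = Path(table_path)
    # converters route parsing through Python's float(), which round-trips
    # repr-printed values exactly
    table = pd.read_csv(
        table_path, sep=None, engine="python", converters={response_col: float}
    )
    if response_col not in table.columns:
        raise ValueError(f"table has no {response_col!r} column")
    path_cols = [c for c in table.columns if c.endswith("_path")]
    if not path_cols:
        raise ValueError("table has no modality columns (names ending in '_path')")
    y = table[response_col].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        bad = table.loc[~np.isfinite(y)].index.tolist()
        raise ValueError(f"non-finite responses for table rows {bad}")

    space, _ = load_mask(mask_path)
    X_list = []
    for col in path_cols:
        rows = []
        for _, rec in table.iterrows():
            vol_path = Path(rec[col])
            if not vol_path.is_absolute():
                vol_path = table_path.parent / vol_path
            if not vol_path.exists():
                raise FileNotFoundError(f"subject {rec.iloc[0]!r}: missing volume {vol_path}")
            vol = np.asanyarray(nib.load(str(vol_path)).dataobj)
            if vol.shape != space.shape:
                raise ValueError(
                    f"subject {rec.iloc[0]!r}: volume shape {vol.shape} != mask {space.shape}"
                )
            row = space.from_volume(vol.astype(float))
            if not np.all(np.isfinite(row)):
                raise ValueError(f"subject {rec.iloc[0]!r}: non-finite voxels in {vol_path}")
            rows.append(row)
        X_list.append(np.vstack(rows))
    return X_list, y, space, table


def export_support_map(fit, space: VoxelSpace, out_path, like: nib.Nifti1Image | None = None):
    """Write a labeled support volume: 0 none, 1 modality-1 only, 2
    modality-2 only, 3 joint (selected in both)."""
    labels = np.zeros(space.p, dtype=np.int16)
    s1 = fit.support(0)
    s2 = fit.support(1) if fit.n_modalities > 1 else np.array([], dtype=int)
    labels[s1] += 1
    labels[s2] += 2
    vol = space.to_volume(labels)
    affine = like.affine if like is not None else np.eye(4)
    img = nib.Nifti1Image(vol.astype(np.int16), affine)
    nib.save(img, str(out_path))
    return vol


def _fit_to_frame(betas) -> pd.DataFrame:
    frames = []
    for k, b in enumerate(betas):
        idx = np.flatnonzero(b)
        frames.append(pd.DataFrame({"modality": k, "voxel": idx, "beta": b[idx]}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def save_fit(fit, out_dir, p: int | None = None):
    """Persist a fit as JSON metadata plus a sparse coefficient table.

    Coefficients are stored as ``repr``-precision decimal text (lossless for
    float64); only nonzero entries are written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    is_pair = isinstance(fit, ISFit)
    betas = fit.betas
    meta = {
        "kind": "is" if is_pair else "fit",
        "p": int(betas[0].size),
        "n_modalities": len(betas),
        "intercept": float(fit.intercept),
        "converged": bool(fit.converged),
    }
    if not is_pair:
        meta["n_iter"] = int(fit.n_iter)
    (out_dir / "fit.json").write_text(json.dumps(meta, indent=1))
    table = _fit_to_frame(betas)
    table.to_csv(out_dir / "coefficients.tsv", sep="\t", index=False,
                 float_format=None)
    return out_dir


def load_fit(in_dir) -> FitResult:
    """Load a persisted fit (as a plain :class:`FitResult`; the IS pair is
    reconstituted as one result holding both modality fields)."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "fit.json").read_text())
    p, m = meta["p"], meta["n_modalities"]
    betas = [np.zeros(p) for _ in range(m)]
    table = pd.read_csv(in_dir / "coefficients.tsv", sep="\t")
    for _, row in table.iterrows():
        betas[int(row.modality)][int(row.voxel)] = row.beta
    return FitResult(
        betas=betas,
        intercept=meta["intercept"],
        n_iter=int(meta.get("n_iter", 0)),
        converged=meta["converged"],
        objective_trace=np.array([]),
        r_primal=np.nan,
        r_dual=np.nan,
    )


def write_dataset(out_dir, space: VoxelSpace, X_list, y, truth=None, prefix: str = "mode"):
    """Write a simulated cohort as NIfTI stacks plus a cohort table.

    Each modality becomes one 4D volume (subjects along the 4th axis) plus
    per-subject 3D volumes referenced by the cohort table, so the ``fit`` /
    ``tune`` command path can be exercised end-to-end on synthetic data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(
        nib.Nifti1Image(space.mask.astype(np.int16), affine), out_dir / "mask.nii.gz"
    )
    n = len(y)
    records = []
    for i in range(n):
        rec = {"subject_id": f"s{i:04d}", "response": float(y[i])}
        for k, X in enumerate(X_list):
            vol = space.to_volume(X[i])
            name = f"{prefix}{k + 1}_s{i:04d}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), out_dir / name)
            rec[f"{prefix}{k + 1}_path"] = name
        records.append(rec)
    pd.DataFrame(records).to_csv(out_dir / "cohort.csv", index=False)
    if truth is not None:
        info = {
            "p": truth.p,
            "support": [truth.support(k).tolist() for k in range(len(truth.beta_list))],
            "joint_support": truth.joint_support.tolist(),
            "effects": [
                [blk.effect for blk in blist] for blist in truth.blocks
            ],
        }
        (out_dir / "truth.json").write_text(json.dumps(info))
    return out_dir
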