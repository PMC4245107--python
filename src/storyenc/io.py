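"""Reading and writing fMRI data and accuracy maps.

Two interchangeable on-disk representations of a subject's run are
supported: a NIfTI 4D volume plus a binary mask (coordinates derived from
the NIfTI affine under the voxel-centre RAS+ mm convention), and a plain
matrix TSV with a ``*.coords.tsv`` sidecar so that desk-scale analyses never
need volumetric files.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

from .data import SubjectData
from .searchlight import SearchlightResult

__all__ = ["read_fmri", "write_fmri", "write_map", "read_map_table"]


def _coords_sidecar(path: str) -> str:
    base = str(path)
    if base.endswith(".tsv"):
        base = base[: -len(".tsv")]
    return base + ".coords.tsv"


def read_fmri(path, mask_path=None, voxel_size: float | None = None,
              subject_id: str | None = None) -> SubjectData:
    """Load one subject's run from NIfTI (+mask) or matrix TSV (+sidecar).

    For NIfTI, voxels inside the mask are returned in C order of their
    ``(i, j, k)`` indices with coordinates ``affine @ (i, j, k, 1)``.
    """
    path = str(path)
    sid = subject_id or os.path.basename(path).split(".")[0]
    if path.endswith((".nii", ".nii.gz")):
        img = nib.load(path)
        affine = img.affine
        if affine is None or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError(f"{path}: missing or singular affine")
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path}: expected a 4D volume, got {data.ndim}D")
        if mask_path is None:
            raise ValueError("a mask NIfTI is required alongside a 4D volume")
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {data.shape[:3]}"
            )
        ijk = np.argwhere(mask)  # C order
        fmri = data[mask].T      # (T, V) in the same C order
        coords = apply_affine(affine, ijk)
        vs = voxel_size or float(np.abs(affine[0, 0]))
        return SubjectData(sid, fmri, coords, vs)
    # matrix + coordinate sidecar
    fmri = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    coords = pd.read_csv(_coords_sidecar(path), sep="\t")[["x", "y", "z"]] \
        .to_numpy(dtype=float)
    return SubjectData(sid, fmri, coords, voxel_size or 3.0)


def _grid_affine(coords: np.ndarray, voxel_size: float) -> tuple[np.ndarray, np.ndarray, tuple]:
    origin = coords.min(axis=0)
    ijk = np.round((coords - origin) / voxel_size).astype(int)
    if not np.allclose(origin + ijk * voxel_size, coords, atol=1e-6):
        raise ValueError("coordinates do not lie on a regular grid; cannot "
                         "rasterize to NIfTI")
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = origin
    shape = tuple(ijk.max(axis=0) + 1)
    return affine, ijk, shape


def write_fmri(subject: SubjectData, path) -> None:
    """Write a subject as NIfTI 4D + ``*_mask.nii.gz``, or as matrix TSV +
    coordinate sidecar, depending on the extension."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        affine, ijk, shape = _grid_affine(subject.coords, subject.voxel_size)
        vol = np.zeros(shape + (subject.n_trs,))
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2], :] = subject.fmri.T
        mask = np.zeros(shape, dtype=np.uint8)
        mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = 1
        nib.save(nib.Nifti1Image(vol, affine), path)
        mask_path = path.replace(".nii.gz", "").replace(".nii", "") + "_mask.nii.gz"
        nib.save(nib.Nifti1Image(mask, affine), mask_path)
    else:
        pd.DataFrame(subject.fmri,
                     columns=[f"v{j}" for j in range(subject.n_voxels)]) \
            .to_csv(path, sep="\t", index=False)
        pd.DataFrame(subject.coords, columns=["x", "y", "z"]) \
            .to_csv(_coords_sidecar(path), sep="\t", index=False)


def write_map(result: SearchlightResult, outdir, voxel_size: float = 3.0,
              affine: np.ndarray | None = None) -> dict[str, str]:
    """Write a searchlight map as NIfTI volumes plus a per-centre TSV.

    Emits ``<set>_accuracy.nii.gz``, and — when significance has been
    attached — ``<set>_qvalue.nii.gz`` and ``<set>_significant.nii.gz``.
    Missing centres carry NaN.  Files for different feature sets are
    independent of one another.
    """
    os.makedirs(outdir, exist_ok=True)
    centres = result.centres
    if affine is None:
        affine, ijk, shape = _grid_affine(centres, voxel_size)
    else:
        inv = np.linalg.inv(affine)
        ijk = np.round(apply_affine(inv, centres)).astype(int)
        shape = tuple(ijk.max(axis=0) + 1)
        if np.any(ijk < 0):
            bad = centres[np.argmax(np.any(ijk < 0, axis=1))]
            raise ValueError(f"centre {bad} falls outside the template grid")
    written = {}

    def _vol(values, name, dtype=float):
        vol = np.full(shape, np.nan if dtype is float else 0, dtype=dtype)
        vol[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = values
        fn = os.path.join(str(outdir), f"{result.feature_set}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64
                                            if dtype is float else np.uint8),
                                 affine), fn)
        written[name] = fn

    _vol(result.table["accuracy"].to_numpy(), "accuracy")
    if "q" in result.table:
        _vol(result.table["q"].to_numpy(), "qvalue")
        _vol(result.table["significant"].to_numpy().astype(np.uint8),
             "significant", dtype=np.uint8)
    tsv = os.path.join(str(outdir), f"{result.feature_set}_map.tsv")
    result.table.to_csv(tsv, sep="\t", index=False)
    written["table"] = tsv
    return written


def read_map_table(path) -> pd.DataFrame:
    """Read back the per-centre TSV written by :func:`write_map`."""
    return pd.read_csv(path, sep="\t")
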