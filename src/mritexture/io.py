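"""NIfTI and voxel-list I/O for synthetic and real-data modes.

Synthetic volumes use a plain diagonal affine built from the voxel spacing
(index * spacing world coordinates).  For real data the NIfTI affine is
honoured only to recover the voxel spacing; the pipeline itself works in
voxel space.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import SubjectRecord
from .voi import voxel_list_from_mask, write_voxel_list

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_cohort",
    "grid_from_voxel_list",
]


def save_nifti(
    data: np.ndarray, spacing: Sequence[float], path: str | Path
) -> None:
    """Write a 3D array as NIfTI-1 with a diagonal spacing affine."""
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI, returning the array and its voxel spacing in mm."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def save_cohort(
    records: Sequence[SubjectRecord], out_dir: str | Path,
    voxel_lists: bool = False,
) -> pd.DataFrame:
    """Write cohort volumes and lesion masks as NIfTI plus a manifest CSV.

    One volume file per subject x contrast, one 0/1 mask file per lesion.
    With ``voxel_lists=True`` each lesion VOI is additionally exported in
    the plain-text per-voxel dialect.  Returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        spec = rec.spec
        spacing = next(iter(rec.volumes.values())).spacing
        vox_mm3 = float(np.prod(spacing))
        mask_paths = []
        for k, mask in enumerate(rec.lesion_masks):
            mp = out / f"{spec.subject_id}_lesion{k}.nii.gz"
            save_nifti(mask.astype(np.uint8), spacing, mp)
            mask_paths.append(mp)
        for contrast, vol in rec.volumes.items():
            vp = out / f"{spec.subject_id}_{contrast}.nii.gz"
            save_nifti(vol.voxels, vol.spacing, vp)
            for k, (mask, mp) in enumerate(zip(rec.lesion_masks, mask_paths)):
                if voxel_lists:
                    lp = out / f"{spec.subject_id}_{contrast}_lesion{k}.txt"
                    coords, vals = voxel_list_from_mask(vol.voxels, mask)
                    write_voxel_list(lp, coords, vals)
                rows.append(
                    {
                        "subject_id": spec.subject_id,
                        "group": spec.disease_group,
                        "contrast": contrast,
                        "lesion_id": k,
                        "volume_path": str(vp),
                        "mask_path": str(mp),
                        "lesion_volume_mm3": float(mask.sum()) * vox_mm3,
                        "seed": spec.seed,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "cohort_manifest.csv", index=False)
    return manifest


def grid_from_voxel_list(
    coords: np.ndarray, intensities: np.ndarray,
    grid_shape: Sequence[int] | None = None,
    fill_value: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild a (volume, mask) pair from a per-voxel list.

    Unlisted voxels get ``fill_value``; they lie outside the mask, so they
    never enter feature computation.
    """
    coords = np.asarray(coords, dtype=int)
    if grid_shape is None:
        grid_shape = tuple(coords.max(axis=0) + 1)
    vol = np.full(tuple(grid_shape), float(fill_value))
    mask = np.zeros(tuple(grid_shape), dtype=bool)
    vol[tuple(coords.T)] = intensities
    mask[tuple(coords.T)] = True
    return vol, mask
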