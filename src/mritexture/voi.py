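"""Volume-of-interest construction and validation.

Two segmentation styles are supported: axis-aligned 3D elliptical VOIs placed
inside the lesion core, and "manual-like" VOIs obtained by dilating the true
lesion mask by a small margin so that mixed boundary voxels are included, as
a hand-drawn contour would.  Controls are mirrored to the co-lateral
hemisphere across the midsagittal plane, and a minimum-volume rule (default
1 cm^3) filters out VOIs too small for texture analysis.

Voxel membership is decided by the voxel center; world coordinates are
``index * spacing`` (0-based indices, no origin offset in synthetic mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation

logger = logging.getLogger(__name__)

__all__ = [
    "VOIMask",
    "ellipsoid_voi",
    "manual_like_voi",
    "mirror_voi",
    "filter_min_volume",
    "read_voxel_list",
    "write_voxel_list",
]


@dataclass
class VOIMask:
    """A boolean voxel mask aligned to an image grid.

    role is ``"pathological"`` or ``"control"``; style is ``"elliptical"``
    or ``"manual"``.
    """

    mask: np.ndarray
    role: str = "pathological"
    style: str = "elliptical"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.role not in ("pathological", "control"):
            raise ValueError(f"invalid role {self.role!r}")
        if self.style not in ("elliptical", "manual"):
            raise ValueError(f"invalid style {self.style!r}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not self.mask.any():
            raise ValueError("VOI mask must contain at least one voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing))


def ellipsoid_voi(
    center: Sequence[float],
    semi_axes: Sequence[float],
    grid_shape: Sequence[int],
    spacing: Sequence[float],
    role: str = "pathological",
    label: str = "",
) -> VOIMask:
    """Rasterize an axis-aligned ellipsoid given in mm coordinates.

    A voxel belongs to the VOI iff its center (x_k = index_k * spacing_k)
    satisfies sum(((x_k - c_k) / a_k)^2) <= 1.  The ellipsoid must lie fully
    inside the physical extent of the grid.
    """
    center = tuple(float(c) for c in center)
    semi_axes = tuple(float(a) for a in semi_axes)
    if any(a <= 0 for a in semi_axes):
        raise ValueError("semi_axes must be strictly positive")
    extent = [(n - 1) * s for n, s in zip(grid_shape, spacing)]
    for ax, (c, a) in enumerate(zip(center, semi_axes)):
        if c - a < 0 or c + a > extent[ax]:
            raise ValueError(
                f"ellipsoid exceeds grid bounds on axis {ax}: "
                f"[{c - a:.2f}, {c + a:.2f}] outside [0, {extent[ax]:.2f}]"
            )
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    q = np.zeros(tuple(grid_shape), dtype=np.float64)
    for g, c, a, s in zip(grids, center, semi_axes, spacing):
        q = q + ((g * s - c) / a) ** 2
    return VOIMask(q <= 1.0, role=role, style="elliptical",
                   spacing=tuple(spacing), label=label)


def _ball_structure(margin_mm: float, spacing: Sequence[float]) -> np.ndarray:
    """Structuring element: voxel offsets within margin_mm (Euclidean, mm)."""
    half = [int(np.floor(margin_mm / s + 1e-9)) for s in spacing]
    offs = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    d2 = sum((o * s) ** 2 for o, s in zip(offs, spacing))
    return d2 <= margin_mm**2 + 1e-9


def manual_like_voi(lesion_mask: VOIMask, margin_mm: float = 2.0) -> VOIMask:
    """Emulate a hand-drawn VOI by dilating the true lesion mask.

    The dilation uses a ball of radius ``margin_mm`` in physical units, so
    boundary voxels with mixed tissue content become part of the VOI.  A
    dilation that would escape the grid is truncated with a logged warning.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    if margin_mm == 0:
        return replace(lesion_mask, style="manual")
    structure = _ball_structure(margin_mm, lesion_mask.spacing)
    dilated = binary_dilation(lesion_mask.mask, structure=structure)
    # detect truncation: dilating the same mask on a padded grid
    half = [(s - 1) // 2 for s in structure.shape]
    padded = np.pad(lesion_mask.mask, [(h, h) for h in half])
    full = binary_dilation(padded, structure=structure)
    if int(full.sum()) != int(dilated.sum()):
        logger.warning(
            "manual-like VOI %r truncated at the grid boundary",
            lesion_mask.label,
        )
    return VOIMask(dilated, role=lesion_mask.role, style="manual",
                   spacing=lesion_mask.spacing, label=lesion_mask.label)


def mirror_voi(mask: VOIMask, midsagittal_index: float) -> VOIMask:
    """Reflect a VOI across the plane x = midsagittal_index (voxel units).

    The mirrored mask is the co-lateral control: every true voxel at index x
    maps to round(2 * m - x).  Voxel count is preserved; reflections landing
    outside the grid raise.
    """
    idx = np.argwhere(mask.mask)
    new_x = np.rint(2.0 * midsagittal_index - idx[:, 0]).astype(int)
    if new_x.min() < 0 or new_x.max() >= mask.mask.shape[0]:
        raise ValueError(
            "mirrored VOI falls outside the grid "
            f"(x range {new_x.min()}..{new_x.max()})"
        )
    out = np.zeros_like(mask.mask)
    out[new_x, idx[:, 1], idx[:, 2]] = True
    if int(out.sum()) != len(idx):
        raise ValueError("reflection collapsed voxels; check midsagittal_index")
    return VOIMask(out, role="control", style=mask.style,
                   spacing=mask.spacing, label=mask.label)


def filter_min_volume(
    masks: Sequence[VOIMask], min_cm3: float = 1.0
) -> list[VOIMask]:
    """Keep only VOIs with physical volume >= min_cm3 (order preserved)."""
    threshold_mm3 = min_cm3 * 1000.0
    return [m for m in masks if m.volume_mm3 >= threshold_mm3]


def read_voxel_list(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a plain-text per-voxel list ("x y z intensity" per line).

    Lines starting with ``#`` are ignored.  Coordinates are 0-based integer
    voxel indices; intensities must be positive decimals.  Returns an
    (n, 3) int coordinate array and an (n,) float intensity array.
    """
    coords: list[tuple[int, int, int]] = []
    intensities: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 fields, got {len(parts)}"
                )
            try:
                x, y, z = (int(p) for p in parts[:3])
                val = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if x < 0 or y < 0 or z < 0:
                raise ValueError(f"{path}:{lineno}: negative voxel index")
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive intensity")
            coords.append((x, y, z))
            intensities.append(val)
    return (
        np.asarray(coords, dtype=int).reshape(-1, 3),
        np.asarray(intensities, dtype=float),
    )


def write_voxel_list(
    path: str | Path, coords: np.ndarray, intensities: np.ndarray
) -> None:
    """Write the plain-text per-voxel dialect (LF endings, '.' decimals)."""
    coords = np.asarray(coords, dtype=int)
    intensities = np.asarray(intensities, dtype=float)
    if coords.shape[0] != intensities.shape[0]:
        raise ValueError("coords and intensities must have equal length")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for (x, y, z), v in zip(coords, intensities):
            fh.write(f"{x} {y} {z} {float(v)!r}\n")


def voxel_list_from_mask(
    volume: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (coords, intensities) of the masked voxels in C order."""
    coords = np.argwhere(np.asarray(mask, dtype=bool))
    vals = np.asarray(volume, dtype=float)[tuple(coords.T)]
    return coords, vals
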