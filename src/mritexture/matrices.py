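"""Grey-level texture matrices (GLCM, GLRLM, GLSZM) on masked 3D grids.

All three matrices are built from a :class:`~mritexture.discretization.DiscretizedVOI`
that carries a boolean mask and integer grey levels >= 1.  Conventions are
pinned for reproducibility:

* GLCM: ordered neighbor pairs at Chebyshev distance 1 along the 13 unique
  3D directions, both orderings counted (symmetric matrix), all directions
  merged into one matrix, then normalised to probabilities.
* GLRLM: maximal same-level runs along each of the 13 directions, truncated
  at the mask boundary, counts summed over directions.
* GLSZM: connected components of equal level under 26-connectivity.

The grey-level axis runs 1..Ng with Ng the maximum observed level;
unobserved intermediate levels are kept as empty rows because the
intensity-weighted features use the level *value*, which is what separates
absolute from relative binning.  2D grids are accepted for testing (4 unique
directions, 8-connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretization import DiscretizedVOI

__all__ = [
    "DIRECTIONS_3D",
    "DIRECTIONS_2D",
    "GreyLevelCooccurrenceMatrix",
    "GreyLevelRunLengthMatrix",
    "GreyLevelSizeZoneMatrix",
    "build_glcm",
    "build_glrlm",
    "build_glszm",
]


def _unique_directions(ndim: int) -> tuple[tuple[int, ...], ...]:
    """Half of the (3^ndim - 1) neighbor offsets: first nonzero positive."""
    dirs = []
    for off in np.ndindex(*(3,) * ndim):
        d = tuple(o - 1 for o in off)
        if all(v == 0 for v in d):
            continue
        first = next(v for v in d if v != 0)
        if first > 0:
            dirs.append(d)
    return tuple(dirs)


DIRECTIONS_3D = _unique_directions(3)   # 13 directions
DIRECTIONS_2D = _unique_directions(2)   # 4 directions


@dataclass
class GreyLevelCooccurrenceMatrix:
    """Symmetric, direction-merged co-occurrence probabilities (levels 1..Ng)."""

    probabilities: np.ndarray
    n_pairs: int
    distance: int = 1
    direction_policy: str = "merged-symmetric"

    @property
    def n_levels(self) -> int:
        return self.probabilities.shape[0]


@dataclass
class GreyLevelRunLengthMatrix:
    """Run counts by (level 1..Ng, run length 1..Rmax), merged directions."""

    counts: np.ndarray
    n_voxels: int
    n_directions: int
    direction_policy: str = "merged"

    @property
    def n_runs(self) -> float:
        return float(self.counts.sum())


@dataclass
class GreyLevelSizeZoneMatrix:
    """Zone counts by (level 1..Ng, zone size 1..Smax), 26-connectivity."""

    counts: np.ndarray
    n_voxels: int
    connectivity: int = 26

    @property
    def n_zones(self) -> float:
        return float(self.counts.sum())


def _crop_to_mask(voi: DiscretizedVOI) -> tuple[np.ndarray, np.ndarray]:
    """Level grid and mask cropped to the mask bounding box."""
    grid = voi.level_grid()
    mask = voi.mask
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    return grid[sl], mask[sl]


def _offset_slices(shape, direction):
    """Source/destination slice tuples for a voxel offset."""
    src, dst = [], []
    for n, d in zip(shape, direction):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def build_glcm(
    voi: DiscretizedVOI,
    distance: int = 1,
    directions: tuple[tuple[int, ...], ...] | None = None,
) -> GreyLevelCooccurrenceMatrix:
    """Merged symmetric co-occurrence matrix of a discretized VOI.

    Pairs with either voxel outside the mask are skipped.  Raises on a VOI
    with no neighbor pairs (e.g. a single voxel).
    """
    grid, mask = _crop_to_mask(voi)
    if directions is None:
        directions = DIRECTIONS_3D if grid.ndim == 3 else _unique_directions(grid.ndim)
    ng = int(grid.max())
    counts = np.zeros((ng, ng), dtype=np.float64)
    for d in directions:
        off = tuple(distance * int(c) for c in d)
        src, dst = _offset_slices(grid.shape, off)
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = grid[src][valid] - 1
        b = grid[dst][valid] - 1
        flat = np.bincount(a * ng + b, minlength=ng * ng)
        counts += flat.reshape(ng, ng)
    counts = counts + counts.T  # count both orderings of each pair
    total = counts.sum()
    if total == 0:
        raise ValueError("degenerate GLCM: VOI has no neighboring voxel pairs")
    return GreyLevelCooccurrenceMatrix(
        probabilities=counts / total, n_pairs=int(total), distance=distance
    )


def build_glrlm(
    voi: DiscretizedVOI,
    directions: tuple[tuple[int, ...], ...] | None = None,
) -> GreyLevelRunLengthMatrix:
    """Merged run-length matrix over the 13 unique directions.

    A run is a maximal sequence of equal-level masked voxels along one
    direction; each masked voxel belongs to exactly one run per direction,
    so sum(length * count) = n_directions * n_voxels.
    """
    grid, mask = _crop_to_mask(voi)
    if directions is None:
        directions = DIRECTIONS_3D if grid.ndim == 3 else _unique_directions(grid.ndim)
    n_vox = int(mask.sum())
    ng = int(grid.max())
    rmax = 1
    per_dir: list[tuple[np.ndarray, np.ndarray]] = []
    for d in directions:
        src, dst = _offset_slices(grid.shape, d)
        # continues[v] = True if voxel v has a same-level masked predecessor
        continues = np.zeros(grid.shape, dtype=bool)
        continues[dst] = mask[dst] & mask[src] & (grid[dst] == grid[src])
        # ends[v] = True if voxel v has no same-level masked successor
        ends = mask.copy()
        ends[src] &= ~(mask[src] & mask[dst] & (grid[src] == grid[dst]))
        # position within the run, propagated from each run start
        pos = np.where(mask & ~continues, 1, 0).astype(np.int64)
        while True:
            known_pred = np.zeros(grid.shape, dtype=np.int64)
            known_pred[dst] = pos[src]
            upd = continues & (pos == 0) & (known_pred > 0)
            if not upd.any():
                break
            pos[upd] = known_pred[upd] + 1
        run_levels = grid[ends]
        run_lengths = pos[ends]
        per_dir.append((run_levels, run_lengths))
        if run_lengths.size:
            rmax = max(rmax, int(run_lengths.max()))
    counts = np.zeros((ng, rmax), dtype=np.float64)
    for levels, lengths in per_dir:
        flat = np.bincount((levels - 1) * rmax + (lengths - 1), minlength=ng * rmax)
        counts += flat.reshape(ng, rmax)
    return GreyLevelRunLengthMatrix(
        counts=counts, n_voxels=n_vox, n_directions=len(directions)
    )


def build_glszm(voi: DiscretizedVOI) -> GreyLevelSizeZoneMatrix:
    """Size-zone matrix: 26-connected (8 in 2D) equal-level components."""
    grid, mask = _crop_to_mask(voi)
    n_vox = int(mask.sum())
    ng = int(grid.max())
    structure = np.ones((3,) * grid.ndim, dtype=bool)
    zones: dict[tuple[int, int], float] = {}
    smax = 1
    for g in np.unique(grid[mask]):
        labeled, n_comp = ndimage.label(mask & (grid == g), structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones[(int(g), int(s))] = zones.get((int(g), int(s)), 0.0) + 1.0
            smax = max(smax, int(s))
    counts = np.zeros((ng, smax), dtype=np.float64)
    for (g, s), c in zones.items():
        counts[g - 1, s - 1] = c
    connectivity = 3**grid.ndim - 1
    return GreyLevelSizeZoneMatrix(
        counts=counts, n_voxels=n_vox, connectivity=connectivity
    )
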