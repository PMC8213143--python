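"""Grey-level discretization schemes for texture analysis.

Three schemes map continuous voxel intensities I(i) inside a VOI to integer
grey levels before any texture matrix is built:

* **LAR** (lesion absolute resampling, fixed bin size anchored at the VOI
  minimum)::

      I_LAR(i) = floor(I(i)/B) - floor(I_min/B) + 1

* **AR** (absolute resampling, fixed bin size anchored at absolute zero)::

      I_AR(i) = ceil(I(i)/B) - 1

  which requires strictly positive intensities so levels stay >= 0.

* **LRR** (lesion relative resampling, fixed bin number)::

      I_LRR(i) = 1                                      if I(i) = I_min
               = ceil(D * (I(i)-I_min) / (I_max-I_min)) otherwise

  mapping the VOI range onto {1..D}.

For the fixed-bin-size schemes (LAR, AR) intensities are first winsorized to
the 10th–90th percentile of the VOI by default; LRR uses the raw VOI range
(clipping for LRR can be enabled explicitly).  The parameter grids swept in
binning-sensitivity studies are B in {1, 5, 10, ..., 100} and D in
{8, 16, ..., 1024}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DiscretizationScheme",
    "ClipStats",
    "DiscretizedVOI",
    "percentile_clip",
    "discretize_lar",
    "discretize_ar",
    "discretize_lrr",
    "discretize",
    "default_grids",
]


@dataclass(frozen=True)
class DiscretizationScheme:
    """One discretization setting: method plus its single parameter.

    Exactly the parameter matching the method must be set: ``bin_width`` (B)
    for LAR/AR, ``bin_count`` (D) for LRR.  ``clip_percentiles`` gives the
    winsorization bounds; ``None`` disables clipping.  By default clipping
    applies to the fixed-bin-size schemes only.
    """

    method: str
    bin_width: float | None = None
    bin_count: int | None = None
    clip_percentiles: tuple[float, float] | None = field(
        default=(10.0, 90.0)
    )

    def __post_init__(self) -> None:
        if self.method not in ("LAR", "AR", "LRR"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method in ("LAR", "AR"):
            if self.bin_width is None or self.bin_width <= 0:
                raise ValueError(f"{self.method} requires bin_width > 0")
            if self.bin_count is not None:
                raise ValueError(f"{self.method} does not take bin_count")
        else:
            if self.bin_count is None or self.bin_count < 2:
                raise ValueError("LRR requires bin_count >= 2")
            if self.bin_width is not None:
                raise ValueError("LRR does not take bin_width")
        if self.clip_percentiles is not None:
            lo, hi = self.clip_percentiles
            if not (0 <= lo < hi <= 100):
                raise ValueError("clip percentiles must satisfy 0<=lo<hi<=100")

    @classmethod
    def lar(cls, bin_width: float,
            clip: tuple[float, float] | None = (10.0, 90.0)):
        return cls("LAR", bin_width=bin_width, clip_percentiles=clip)

    @classmethod
    def ar(cls, bin_width: float,
           clip: tuple[float, float] | None = (10.0, 90.0)):
        return cls("AR", bin_width=bin_width, clip_percentiles=clip)

    @classmethod
    def lrr(cls, bin_count: int,
            clip: tuple[float, float] | None = None):
        return cls("LRR", bin_count=bin_count, clip_percentiles=clip)

    @property
    def param(self) -> float:
        """The scheme's swept parameter (B or D)."""
        return self.bin_width if self.method in ("LAR", "AR") else self.bin_count

    @property
    def clips(self) -> bool:
        return self.clip_percentiles is not None

    def tag(self) -> str:
        p = self.param
        p_str = f"{p:g}"
        return f"{self.method}_{p_str}"


@dataclass(frozen=True)
class ClipStats:
    """Winsorization bookkeeping for one VOI."""

    p_lo: float
    p_hi: float
    n_clipped_low: int
    n_clipped_high: int

    def __post_init__(self) -> None:
        if self.p_lo > self.p_hi:
            raise ValueError("p_lo must be <= p_hi")


@dataclass
class DiscretizedVOI:
    """Integer grey levels on the masked voxels of a VOI.

    ``levels`` follows the voxel order of ``np.argwhere(mask)`` (C order)
    when a mask is attached, or the input order for bare intensity arrays.
    ``i_min``/``i_max`` are the post-clipping intensity extremes.  For AR the
    raw equation can produce level 0; ``grey_levels`` applies the +1 shift
    used at matrix-construction time so grey levels always start at >= 1
    while preserving all level differences.
    """

    levels: np.ndarray
    i_min: float
    i_max: float
    scheme: DiscretizationScheme
    mask: np.ndarray | None = None
    spacing: tuple[float, float, float] | None = None
    clip_stats: ClipStats | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if not np.issubdtype(self.levels.dtype, np.integer):
            raise TypeError("levels must be integers")

    @property
    def n_levels_observed(self) -> int:
        return int(np.unique(self.levels).size)

    @property
    def grey_levels(self) -> np.ndarray:
        """Levels as used for matrix construction (>= 1)."""
        if self.scheme.method == "AR":
            return self.levels + 1
        return self.levels

    def level_grid(self) -> np.ndarray:
        """3D integer grid with grey levels inside the mask and 0 outside."""
        if self.mask is None:
            raise ValueError("this DiscretizedVOI carries no mask")
        grid = np.zeros(self.mask.shape, dtype=np.int64)
        grid[self.mask] = self.grey_levels
        return grid


def percentile_clip(
    intensities: np.ndarray, lo: float = 10.0, hi: float = 90.0
) -> tuple[np.ndarray, ClipStats]:
    """Winsorize intensities to their [lo, hi] percentile range.

    Percentiles use the linear-interpolation definition.  Values outside the
    bounds are set to the bounds; the voxel count is unchanged, so the VOI
    lattice keeps all its voxels.
    """
    x = np.asarray(intensities, dtype=np.float64)
    if x.size == 0:
        raise ValueError("cannot clip an empty intensity array")
    if not (0 <= lo < hi <= 100):
        raise ValueError("percentiles must satisfy 0 <= lo < hi <= 100")
    p_lo, p_hi = np.percentile(x, [lo, hi])
    n_low = int(np.count_nonzero(x < p_lo))
    n_high = int(np.count_nonzero(x > p_hi))
    return np.clip(x, p_lo, p_hi), ClipStats(float(p_lo), float(p_hi), n_low, n_high)


def discretize_lar(
    intensities: np.ndarray, B: float, i_min: float | None = None
) -> DiscretizedVOI:
    """Fixed bin size anchored at the VOI minimum; minimum level is 1."""
    if B <= 0:
        raise ValueError("bin width B must be > 0")
    x = np.asarray(intensities, dtype=np.float64)
    if i_min is None:
        i_min = float(x.min())
    levels = (np.floor(x / B) - math.floor(i_min / B) + 1).astype(np.int64)
    return DiscretizedVOI(
        levels=levels,
        i_min=float(i_min),
        i_max=float(x.max()),
        scheme=DiscretizationScheme.lar(B),
        degenerate=bool(np.all(x == x.flat[0])),
    )


def discretize_ar(intensities: np.ndarray, B: float) -> DiscretizedVOI:
    """Fixed bin size anchored at absolute intensity zero.

    Levels are independent of the VOI minimum, so a given intensity always
    falls in the same bin regardless of the lesion it belongs to.
    """
    if B <= 0:
        raise ValueError("bin width B must be > 0")
    x = np.asarray(intensities, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("AR discretization requires strictly positive intensities")
    levels = (np.ceil(x / B) - 1).astype(np.int64)
    return DiscretizedVOI(
        levels=levels,
        i_min=float(x.min()),
        i_max=float(x.max()),
        scheme=DiscretizationScheme.ar(B),
        degenerate=bool(np.all(x == x.flat[0])),
    )


def discretize_lrr(intensities: np.ndarray, D: int) -> DiscretizedVOI:
    """Fixed bin number: VOI intensity range mapped onto {1..D}.

    The minimum maps to 1, the maximum to D.  A constant VOI is degenerate
    and maps everywhere to 1.
    """
    if D < 2:
        raise ValueError("bin count D must be >= 2")
    x = np.asarray(intensities, dtype=np.float64)
    i_min, i_max = float(x.min()), float(x.max())
    if i_max == i_min:
        levels = np.ones(x.shape, dtype=np.int64)
        degenerate = True
    else:
        scaled = np.ceil(D * (x - i_min) / (i_max - i_min))
        levels = np.where(x == i_min, 1, scaled).astype(np.int64)
        np.clip(levels, 1, D, out=levels)  # guard float roundoff at the top bin
        degenerate = False
    return DiscretizedVOI(
        levels=levels,
        i_min=i_min,
        i_max=i_max,
        scheme=DiscretizationScheme.lrr(D),
        degenerate=degenerate,
    )


def discretize(
    volume: np.ndarray,
    mask: np.ndarray,
    scheme: DiscretizationScheme,
    spacing: Sequence[float] | None = None,
) -> DiscretizedVOI:
    """Apply a scheme to the masked voxels of a volume (clip, then bin)."""
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} != mask shape {mask.shape}"
        )
    intensities = volume[mask]
    if intensities.size == 0:
        raise ValueError("mask selects no voxels")
    clip_stats = None
    if scheme.clips:
        lo, hi = scheme.clip_percentiles
        intensities, clip_stats = percentile_clip(intensities, lo, hi)
    if scheme.method == "LAR":
        dv = discretize_lar(intensities, scheme.bin_width)
    elif scheme.method == "AR":
        dv = discretize_ar(intensities, scheme.bin_width)
    else:
        dv = discretize_lrr(intensities, scheme.bin_count)
    dv.scheme = scheme
    dv.mask = mask
    dv.spacing = tuple(spacing) if spacing is not None else None
    dv.clip_stats = clip_stats
    return dv


def default_grids() -> tuple[tuple[float, ...], tuple[int, ...]]:
    """The swept parameter grids: 21 bin widths and 8 bin counts."""
    b_grid = (1.0,) + tuple(float(b) for b in range(5, 101, 5))
    d_grid = tuple(8 * 2**k for k in range(8))
    return b_grid, d_grid
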