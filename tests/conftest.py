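import numpy as np
import pytest

from mritexture.discretization import DiscretizationScheme, DiscretizedVOI


def dv_from_grid(grid, method_scheme=None):
    """Wrap an integer level grid (0 = outside mask) as a DiscretizedVOI."""
    grid = np.asarray(grid, dtype=np.int64)
    mask = grid > 0
    scheme = method_scheme or DiscretizationScheme.lrr(max(int(grid.max()), 2))
    return DiscretizedVOI(
        levels=grid[mask], i_min=1.0, i_max=float(grid.max()),
        scheme=scheme, mask=mask,
    )


def random_level_grid(rng, max_side=4, max_level=4, ndim=3):
    """Random small masked level grid for oracle comparisons."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(ndim))
    grid = rng.integers(0, max_level + 1, size=shape)
    # ensure at least one neighbouring masked pair for GLCM validity
    if (grid > 0).sum() < 2:
        grid.flat[0] = 1
        grid.flat[1] = 1
    if not _has_pair(grid):
        grid[..., :2] = np.maximum(grid[..., :2], 1)
    return grid


def _has_pair(grid):
    mask = grid > 0
    for ax in range(grid.ndim):
        a = np.take(mask, range(grid.shape[ax] - 1), axis=ax)
        b = np.take(mask, range(1, grid.shape[ax]), axis=ax)
        if (a & b).any():
            return True
    return False


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
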