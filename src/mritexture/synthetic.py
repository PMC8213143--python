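"""Synthetic brain-lesion phantom cohorts.

The generator emulates the statistical structure a lesion-texture analysis
relies on, not MR physics: each subject is a 3D scalar volume per contrast
(T1-like and T2-like) consisting of a stationary correlated Gaussian random
field background, one or more ellipsoidal lesions whose interior field has a
different mean / spread / correlation length, and a global Gaussian blur that
mimics partial-volume mixing at the lesion boundary.  Lesion geometry is
shared between the contrasts of one subject, as for co-registered scans, and
every lesion is placed so that its mirror image across the midsagittal plane
(the co-lateral control position) also fits inside the grid.

Three disease groups are emulated (ischemic stroke IS, multiple sclerosis MS,
tumor TU) with default sizes 22 / 22 / 27.  Groups differ only in lesion
count, size range and per-contrast lesion texture presets; no clinical
realism beyond that is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ._seeds import derive_seed, label_hash

__all__ = [
    "TextureParams",
    "SubjectSpec",
    "CohortDesign",
    "ImageVolume",
    "SubjectRecord",
    "GROUP_PRESETS",
    "generate_subject_volume",
    "generate_subject",
    "generate_cohort",
]

#: Floor applied to generated intensities.  Keeping voxel values strictly
#: positive guarantees that absolute-resampling discretization
#: (``ceil(I/B) - 1``) yields grey levels >= 0.
INTENSITY_FLOOR = 1.0


@dataclass(frozen=True)
class TextureParams:
    """Second-order description of a stationary textured region.

    Parameters
    ----------
    mean_intensity : float
        Target mean in arbitrary MR units, > 0.
    intensity_sd : float
        Target standard deviation, >= 0 (0 gives a constant region).
    correlation_length : float
        Spatial correlation length in mm (Gaussian kernel width used to
        correlate the white-noise field); 0 means white noise.
    boundary_blur_sigma : float
        Gaussian sigma in mm of the partial-volume blur applied to the
        composed volume; 0 disables blurring.
    """

    mean_intensity: float
    intensity_sd: float = 0.0
    correlation_length: float = 0.0
    boundary_blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_intensity <= 0:
            raise ValueError("mean_intensity must be > 0")
        if self.intensity_sd < 0:
            raise ValueError("intensity_sd must be >= 0")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        if self.boundary_blur_sigma < 0:
            raise ValueError("boundary_blur_sigma must be >= 0")


@dataclass(frozen=True)
class SubjectSpec:
    """Full recipe for one synthetic subject.

    ``lesion_radii`` holds one (rx, ry, rz) semi-axis triple in mm per
    lesion; ``lesion_centers`` the matching centers in mm (index * spacing
    coordinates).  ``lesion_params`` maps each contrast label to the
    TextureParams of the lesion interior for that contrast.
    """

    subject_id: str
    disease_group: str
    n_lesions: int
    lesion_radii: tuple[tuple[float, float, float], ...]
    lesion_centers: tuple[tuple[float, float, float], ...]
    background_params: TextureParams
    lesion_params: Mapping[str, TextureParams]
    seed: int

    def __post_init__(self) -> None:
        if self.disease_group not in ("IS", "MS", "TU"):
            raise ValueError(f"unknown disease_group {self.disease_group!r}")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if len(self.lesion_radii) != self.n_lesions:
            raise ValueError("lesion_radii must have one entry per lesion")
        if len(self.lesion_centers) != self.n_lesions:
            raise ValueError("lesion_centers must have one entry per lesion")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort-level design: group sizes, grid geometry and the master seed."""

    n_is: int = 22
    n_ms: int = 22
    n_tu: int = 27
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    master_seed: int = 0
    contrasts: tuple[str, ...] = ("T1", "T2")

    def __post_init__(self) -> None:
        if min(self.n_is, self.n_ms, self.n_tu) < 1:
            raise ValueError("all group counts must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 4 voxels")

    @property
    def n_subjects(self) -> int:
        return self.n_is + self.n_ms + self.n_tu


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    contrast_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if not np.all(self.voxels > 0):
            raise ValueError("all intensities must be strictly positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SubjectRecord:
    """One generated subject: its spec, per-contrast volumes, lesion masks."""

    spec: SubjectSpec
    volumes: dict[str, ImageVolume]
    lesion_masks: list[np.ndarray]


# Per-group presets: lesion multiplicity, semi-axis range (mm) and the
# contrast-dependent lesion interiors.  Background is shared.  Intensities
# sit on an arbitrary-unit scale typical of unnormalised 1.5 T brain MR
# (hundreds to ~1500), so the fixed-bin-size grid B = 1..100 spans fine to
# coarse binning relative to the VOI intensity spread, as in clinical data.
# Stroke is T1-hypo / T2-hyper, MS plaques mildly T2-hyper, enhancing tumors
# T1-hyper; lesion fields are rougher (larger sd) than normal parenchyma.
BACKGROUND_PRESET = TextureParams(
    mean_intensity=600.0, intensity_sd=60.0, correlation_length=1.5,
    boundary_blur_sigma=0.5,
)

GROUP_PRESETS: dict[str, dict] = {
    "IS": {
        "n_lesions": (1, 3),
        "radii_mm": (7.0, 10.0),
        "lesion_params": {
            "T1": TextureParams(420.0, 85.0, 2.5, 0.5),
            "T2": TextureParams(900.0, 110.0, 2.5, 0.5),
        },
    },
    "MS": {
        "n_lesions": (1, 3),
        "radii_mm": (7.0, 9.0),
        "lesion_params": {
            "T1": TextureParams(510.0, 70.0, 2.0, 0.5),
            "T2": TextureParams(840.0, 90.0, 2.0, 0.5),
        },
    },
    "TU": {
        "n_lesions": (1, 1),
        "radii_mm": (8.0, 13.0),
        "lesion_params": {
            "T1": TextureParams(1080.0, 150.0, 3.0, 0.5),
            "T2": TextureParams(960.0, 180.0, 3.0, 0.5),
        },
    },
}

#: Range of the per-subject multiplicative intensity gain.  MR intensities
#: are arbitrary units that vary between acquisitions; sampling a gain per
#: subject reproduces that between-subject scale variability (no
#: normalization is applied anywhere downstream, deliberately).
SUBJECT_GAIN_RANGE = (0.8, 1.2)


def _correlated_field(
    shape: Sequence[int],
    spacing: Sequence[float],
    params: TextureParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary Gaussian random field with the requested mean/sd.

    White noise is convolved with an isotropic (in mm) Gaussian kernel of
    width ``correlation_length`` and then standardised empirically, so the
    sample mean and sd over the generated block match the targets exactly.
    """
    noise = rng.standard_normal(tuple(shape))
    if params.correlation_length > 0:
        sigma_vox = [params.correlation_length / s for s in spacing]
        fieldv = gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    else:
        fieldv = noise
    sd = fieldv.std()
    if sd > 0 and params.intensity_sd > 0:
        fieldv = (fieldv - fieldv.mean()) / sd * params.intensity_sd
    else:
        fieldv = np.zeros_like(fieldv)
    return params.mean_intensity + fieldv


def ellipsoid_mask(
    center_mm: Sequence[float],
    semi_axes_mm: Sequence[float],
    grid_shape: Sequence[int],
    spacing: Sequence[float],
) -> np.ndarray:
    """Boolean mask of voxel centers inside an axis-aligned ellipsoid."""
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    q = np.zeros(tuple(grid_shape), dtype=np.float64)
    for g, c, a, s in zip(grids, center_mm, semi_axes_mm, spacing):
        q = q + ((g * s - c) / a) ** 2
    return q <= 1.0


def _validate_placement(
    spec: SubjectSpec,
    grid_shape: Sequence[int],
    spacing: Sequence[float],
) -> None:
    extent = [(n - 1) * s for n, s in zip(grid_shape, spacing)]
    mid = extent[0] / 2.0
    for k, (c, r) in enumerate(zip(spec.lesion_centers, spec.lesion_radii)):
        for ax in range(3):
            if c[ax] - r[ax] < 0 or c[ax] + r[ax] > extent[ax]:
                raise ValueError(
                    f"lesion {k} of subject {spec.subject_id} extends outside "
                    f"the grid on axis {ax}"
                )
        # mirrored control: reflect x across the midsagittal plane
        cx = 2 * mid - c[0]
        if cx - r[0] < 0 or cx + r[0] > extent[0]:
            raise ValueError(
                f"mirrored control of lesion {k} of subject "
                f"{spec.subject_id} extends outside the grid"
            )


def generate_subject_volume(
    spec: SubjectSpec,
    contrast_label: str,
    grid_shape: Sequence[int],
    spacing: Sequence[float],
) -> tuple[ImageVolume, list[np.ndarray]]:
    """Render one subject's volume for one contrast.

    Returns the volume and the list of per-lesion boolean masks.  The lesion
    geometry depends only on the spec, so the two contrasts of one subject
    share identical masks; the noise realisation depends on the contrast.
    Identical inputs give bit-identical outputs.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be strictly positive")
    if contrast_label not in spec.lesion_params:
        raise KeyError(
            f"no lesion TextureParams for contrast {contrast_label!r}"
        )
    _validate_placement(spec, grid_shape, spacing)

    chash = label_hash(contrast_label)
    bg_rng = np.random.default_rng(derive_seed(spec.seed, chash, 0))
    vol = _correlated_field(grid_shape, spacing, spec.background_params, bg_rng)

    lesion_par = spec.lesion_params[contrast_label]
    masks: list[np.ndarray] = []
    blur_mm = max(
        spec.background_params.boundary_blur_sigma,
        lesion_par.boundary_blur_sigma,
    )
    for k, (c, r) in enumerate(zip(spec.lesion_centers, spec.lesion_radii)):
        mask = ellipsoid_mask(c, r, grid_shape, spacing)
        les_rng = np.random.default_rng(derive_seed(spec.seed, chash, k + 1))
        lesion_field = _correlated_field(grid_shape, spacing, lesion_par, les_rng)
        vol[mask] = lesion_field[mask]
        masks.append(mask)

    if blur_mm > 0:
        sigma_vox = [blur_mm / s for s in spacing]
        vol = gaussian_filter(vol, sigma=sigma_vox, mode="reflect")

    vol = np.maximum(vol, INTENSITY_FLOOR)
    return ImageVolume(vol, tuple(spacing), contrast_label), masks


def _sample_subject_spec(
    subject_id: str,
    group: str,
    design: CohortDesign,
    seed: int,
    presets: Mapping[str, dict],
    max_tries: int = 10000,
) -> SubjectSpec:
    """Draw lesion count, sizes and non-overlapping placements for a subject.

    Lesions live in the low-x half of the grid with a safety margin so the
    mirrored control position in the other hemisphere is always inside the
    grid, and neither lesions nor their mirrors overlap each other.
    """
    preset = presets[group]
    rng = np.random.default_rng(derive_seed(seed, 0x9E37, 0))
    lo, hi = preset["n_lesions"]
    n_lesions = int(rng.integers(lo, hi + 1))
    rlo, rhi = preset["radii_mm"]

    # per-subject acquisition gain: scales all means/sds of this subject
    g_lo, g_hi = preset.get("gain_range", SUBJECT_GAIN_RANGE)
    gain = float(rng.uniform(g_lo, g_hi))

    def _scaled(p: TextureParams) -> TextureParams:
        return TextureParams(
            p.mean_intensity * gain, p.intensity_sd * gain,
            p.correlation_length, p.boundary_blur_sigma,
        )

    background = _scaled(BACKGROUND_PRESET)
    lesion_params = {
        contrast: _scaled(p) for contrast, p in preset["lesion_params"].items()
    }

    extent = [(n - 1) * s for n, s in zip(design.grid_shape, design.spacing)]
    mid = extent[0] / 2.0
    margin = 1.0  # mm of clearance from grid edges and the midline

    centers: list[tuple[float, float, float]] = []
    radii: list[tuple[float, float, float]] = []
    tries = 0
    while len(centers) < n_lesions:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_lesions} non-overlapping lesions for "
                f"{subject_id}; enlarge the grid or reduce radii"
            )
        if tries % 1000 == 0:
            centers.clear()  # restart a stuck partial placement
            radii.clear()
        r = tuple(float(rng.uniform(rlo, rhi)) for _ in range(3))
        # center x confined to the low-x hemisphere
        x_lo, x_hi = r[0] + margin, mid - r[0] - margin
        if x_hi <= x_lo:
            continue
        cx = float(rng.uniform(x_lo, x_hi))
        cyz = [
            float(rng.uniform(r[ax] + margin, extent[ax] - r[ax] - margin))
            for ax in (1, 2)
        ]
        c = (cx, cyz[0], cyz[1])
        # reject overlap with existing lesions and all mirrored controls
        ok = True
        candidates = centers + [(2 * mid - cc[0], cc[1], cc[2]) for cc in centers]
        cand_r = radii + radii
        # 5 mm clearance so dilated manual VOIs and mirrored controls of
        # distinct lesions never touch each other
        for cc, rr in zip(candidates, cand_r):
            d = np.linalg.norm(np.subtract(c, cc))
            if d < max(r) + max(rr) + 5.0:
                ok = False
                break
        if ok:
            centers.append(c)
            radii.append(r)

    return SubjectSpec(
        subject_id=subject_id,
        disease_group=group,
        n_lesions=n_lesions,
        lesion_radii=tuple(radii),
        lesion_centers=tuple(centers),
        background_params=background,
        lesion_params=lesion_params,
        seed=seed,
    )


def generate_subject(
    subject_id: str,
    group: str,
    design: CohortDesign,
    seed: int,
    presets: Mapping[str, dict] | None = None,
) -> SubjectRecord:
    """Generate one subject (spec + one volume per contrast)."""
    presets = GROUP_PRESETS if presets is None else presets
    spec = _sample_subject_spec(subject_id, group, design, seed, presets)
    volumes: dict[str, ImageVolume] = {}
    masks: list[np.ndarray] | None = None
    for contrast in design.contrasts:
        vol, m = generate_subject_volume(
            spec, contrast, design.grid_shape, design.spacing
        )
        volumes[contrast] = vol
        masks = m
    assert masks is not None
    return SubjectRecord(spec=spec, volumes=volumes, lesion_masks=masks)


def generate_cohort(
    design: CohortDesign,
    presets: Mapping[str, dict] | None = None,
) -> list[SubjectRecord]:
    """Generate the full cohort deterministically from the design.

    Subject seeds are derived independently from the master seed, the group
    label and the within-group index, so adding or removing a subject (or
    resizing one group) leaves the realisations of all other subjects
    unchanged.
    """
    records: list[SubjectRecord] = []
    for group, n in (("IS", design.n_is), ("MS", design.n_ms),
                     ("TU", design.n_tu)):
        for i in range(n):
            seed = derive_seed(design.master_seed, label_hash(group), i + 1)
            sid = f"{group}{i:03d}"
            records.append(generate_subject(sid, group, design, seed, presets))
    return records
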