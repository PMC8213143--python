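"""Reusable cohort-level experiments on synthetic phantoms.

These drive the calibration and qualitative-pattern checks of the analysis:

* type-I error of the rank-sum screening on a *null* cohort (pathological
  and control VOIs drawn from statistically identical texture);
* stability of each texture index across the bin-number grid (coefficient
  of variation), which separates binning-robust indices such as GLCM
  Correlation and NormInvDiff from binning-driven ones such as JEntropy;
* monotone response of entropy-type indices to the binning parameters;
* a discrimination study on a cohort with genuine lesion/background texture
  differences, comparing significant-feature counts between discretization
  methods and segmentation styles, and volume-correlation maps.

Problem sizes default to desk-scale settings chosen so each experiment runs
in seconds to a couple of minutes on one core.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .discretization import DiscretizationScheme, default_grids
from .features import extract_features
from .pipeline import StudyConfig, build_voi_records, extract_feature_table, compute_statistics
from .stats import HIGH_CORRELATION_R2
from .synthetic import (
    BACKGROUND_PRESET,
    CohortDesign,
    GROUP_PRESETS,
    generate_cohort,
)
from ._seeds import derive_seed

__all__ = [
    "null_presets",
    "type1_error_null_cohort",
    "spearman_volume_null",
    "binning_stability",
    "binning_monotonicity",
    "discrimination_study",
    "binomial_bounds",
]

#: Compact grid that still holds a lesion and its mirrored control.
SMALL_GRID = (48, 32, 32)


def null_presets() -> dict:
    """Group presets whose lesions are statistically identical to background.

    Under these presets the pathological/control comparison has no true
    effect, so the rank-sum screening should reject at its nominal rate.
    Lesion geometry and the per-subject intensity gain are held fixed (one
    9 mm spherical lesion, gain 1): texture-index values depend on VOI size
    and on the acquisition gain, so letting either vary would give the two
    VOIs of one subject a shared covariate, correlating the arms and making
    the unpaired test conservative rather than nominal.
    """
    null_lesion = {
        "T1": BACKGROUND_PRESET,
        "T2": BACKGROUND_PRESET,
    }
    return {
        group: {
            **preset, "lesion_params": null_lesion,
            "n_lesions": (1, 1), "radii_mm": (9.0, 9.0),
            "gain_range": (1.0, 1.0),
        }
        for group, preset in GROUP_PRESETS.items()
    }


def binomial_bounds(p0: float, n: int, z: float = 2.5758) -> tuple[float, float]:
    """Two-sided normal-approximation binomial bounds (99% for default z)."""
    half = z * math.sqrt(p0 * (1 - p0) / n)
    return p0 - half, p0 + half


def type1_error_null_cohort(
    master_seed: int = 0,
    n_seeds: int = 240,
    n_subjects: int = 12,
    scheme: DiscretizationScheme | None = None,
) -> dict:
    """Fraction of significant rank-sum tests on null cohorts.

    Each replicate draws a fresh cohort of ``n_subjects`` single-lesion
    subjects whose lesion interiors share the background TextureParams,
    extracts texture indices from elliptical pathological and mirrored
    control VOIs, and rank-sum-tests one feature between the two arms at
    alpha = 0.05, rotating through the 40-feature roster across
    replicates.  One test per independent cohort keeps the pooled tests
    independent, which is what the binomial reference bounds assume; the
    40 indices of a single cohort comparison are strongly correlated and
    would make pooled counts overdispersed.

    The elliptical VOIs are shrunk 2 mm inside the nominal lesion so
    neither arm samples the partial-volume boundary shell, whose mixing
    statistics differ slightly between the lesion side (two independent
    fields) and the control side (one continuous field).
    """
    from .features import ALL_FEATURES
    from .stats import ranksum_disease_vs_control

    scheme = scheme or DiscretizationScheme.ar(5.0)
    presets = null_presets()
    n_sig = 0
    n_tests = 0
    for rep in range(n_seeds):
        design = CohortDesign(
            n_is=1, n_ms=1, n_tu=n_subjects,
            grid_shape=SMALL_GRID, contrasts=("T1",),
            master_seed=derive_seed(master_seed, rep) % (2**31),
        )
        cohort = generate_cohort(design, presets=presets)
        config = StudyConfig(design=design, b_grid=(), d_grid=(),
                             elliptical_shrink_mm=2.0)
        vois = [
            v for v in build_voi_records(cohort, config)
            if v.segmentation == "elliptical" and v.group == "TU"
        ]
        table = extract_feature_table(vois, [scheme])
        feature = ALL_FEATURES[rep % len(ALL_FEATURES)]
        sub = table[table["feature"] == feature]
        x = sub.loc[sub["role"] == "pathological", "value"].to_numpy()
        y = sub.loc[sub["role"] == "control", "value"].to_numpy()
        rec = ranksum_disease_vs_control(x, y, feature=feature)
        n_tests += 1
        n_sig += int((not rec.degenerate) and rec.value < 0.05)
    return {
        "n_tests": n_tests,
        "n_significant": n_sig,
        "fraction": n_sig / n_tests if n_tests else float("nan"),
        "alpha": 0.05,
    }


def _fixed_voi(master_seed: int, rep: int = 0, group: str = "TU"):
    """One deterministic textured lesion VOI (volume, mask)."""
    design = CohortDesign(
        n_is=1, n_ms=1, n_tu=1, grid_shape=SMALL_GRID, contrasts=("T1",),
        master_seed=derive_seed(master_seed, 0xF1, rep) % (2**31),
    )
    presets = {
        g: {**p, "n_lesions": (1, 1), "radii_mm": (8.0, 10.0)}
        for g, p in GROUP_PRESETS.items()
    }
    cohort = generate_cohort(design, presets=presets)
    rec = next(r for r in cohort if r.spec.disease_group == group)
    return rec.volumes["T1"].voxels, rec.lesion_masks[0]


def binning_stability(
    master_seed: int = 0,
    d_grid: tuple[int, ...] | None = None,
) -> pd.Series:
    """Coefficient of variation of each feature across the bin-number grid.

    On one fixed synthetic VOI, every feature is computed under LRR at each
    D in the grid; the CoV (std over |mean|) across the grid quantifies how
    strongly the index depends on the binning parameter.
    """
    d_grid = d_grid or default_grids()[1]
    vol, mask = _fixed_voi(master_seed)
    rows = []
    for d in d_grid:
        rows.append(extract_features(vol, mask, DiscretizationScheme.lrr(int(d))))
    df = pd.DataFrame(rows)
    mean = df.mean()
    cov = df.std(ddof=1) / mean.abs().where(mean.abs() > 0, np.nan)
    return cov


def binning_monotonicity(
    master_seed: int = 0,
    n_seeds: int = 48,
    feature: str = "glcm_JEntropy",
    b_grid: tuple[float, ...] | None = None,
    d_grid: tuple[int, ...] | None = None,
) -> dict:
    """Seed-averaged response of an entropy-type index to the binning grids.

    Replicates rotate through the three disease-group presets, and the
    generator's per-subject gain varies the intensity location of every
    lesion, so the average over replicates marginalises the alignment of
    the absolute bin grid with any one lesion's intensity range (for a
    single fixed intensity location the fixed-bin-size response at coarse
    B is alignment-dependent rather than monotone).  Returns the
    per-parameter averages and whether they are monotone (non-decreasing
    in D under LRR, non-increasing in B under AR).
    """
    b_grid = b_grid or default_grids()[0]
    d_grid = d_grid or default_grids()[1]
    by_d = np.zeros(len(d_grid))
    by_b = np.zeros(len(b_grid))
    groups = ("IS", "MS", "TU")
    for rep in range(n_seeds):
        vol, mask = _fixed_voi(master_seed, rep, group=groups[rep % 3])
        for k, d in enumerate(d_grid):
            by_d[k] += extract_features(
                vol, mask, DiscretizationScheme.lrr(int(d))
            )[feature]
        for k, b in enumerate(b_grid):
            by_b[k] += extract_features(
                vol, mask, DiscretizationScheme.ar(float(b))
            )[feature]
    by_d /= n_seeds
    by_b /= n_seeds
    return {
        "d_grid": tuple(d_grid),
        "mean_by_d": by_d,
        "b_grid": tuple(b_grid),
        "mean_by_b": by_b,
        "nondecreasing_in_d": bool(np.all(np.diff(by_d) >= 0)),
        "nonincreasing_in_b": bool(np.all(np.diff(by_b) <= 0)),
    }


def spearman_volume_null(
    master_seed: int = 0,
    n_seeds: int = 28,
    n_subjects: int = 16,
    scheme: DiscretizationScheme | None = None,
) -> dict:
    """Pooled Spearman feature-volume p-values when texture is volume-free.

    Cohorts of single-lesion subjects whose lesion texture parameters are
    independent of lesion size by construction; for every co-occurrence
    (GLCM) index and both contrasts the p-value of the Spearman
    feature-vs-volume correlation under fixed-bin-size (AR) discretization
    is pooled.  Under this null the pooled distribution should be close to
    uniform.  Only the GLCM family is used: run-length and size-zone
    indices that aggregate raw run/zone counts are intrinsically
    sample-size dependent, so they correlate with VOI volume by
    construction — the very bias the volume-correlation analysis is there
    to expose — and have no uniformity null to satisfy.

    Returns the pooled p-values and their Kolmogorov distance to uniform.
    """
    from scipy import stats as sps

    scheme = scheme or DiscretizationScheme.ar(50.0)
    presets = {
        g: {**p, "n_lesions": (1, 1), "radii_mm": (7.0, 10.0)}
        for g, p in GROUP_PRESETS.items()
    }
    pvals: list[float] = []
    for rep in range(n_seeds):
        design = CohortDesign(
            n_is=1, n_ms=1, n_tu=n_subjects, grid_shape=SMALL_GRID,
            master_seed=derive_seed(master_seed, 0x5EA, rep) % (2**31),
        )
        cohort = generate_cohort(design, presets=presets)
        config = StudyConfig(design=design, b_grid=(), d_grid=())
        vois = [
            v for v in build_voi_records(cohort, config)
            if v.segmentation == "elliptical" and v.group == "TU"
            and v.role == "pathological"
        ]
        table = extract_feature_table(vois, [scheme])
        glcm_rows = table[table["feature"].str.startswith("glcm_")]
        for (feat, contrast), sub in glcm_rows.groupby(["feature", "contrast"]):
            pvals.append(float(sps.spearmanr(
                sub["value"], sub["lesion_volume_mm3"]
            ).pvalue))
    arr = np.asarray(pvals)
    ks = float(sps.ks_1samp(arr, sps.uniform.cdf).statistic)
    return {"pvalues": arr, "ks_distance": ks, "n_tests": arr.size}


def discrimination_study(
    master_seed: int = 0,
    n_per_group: int = 8,
    bin_width: float = 50.0,
    bin_count: int = 64,
) -> dict:
    """Headline-setting comparison on a cohort with real texture contrast.

    Runs the full pipeline at B = bin_width (AR) and D = bin_count (LRR) on
    a cohort whose lesions genuinely differ from background, then tabulates
    significant rank-sum counts per (method, segmentation) and the number
    of high volume-correlation cells (R^2 > 0.5) per method.
    """
    design = CohortDesign(
        n_is=n_per_group, n_ms=n_per_group, n_tu=n_per_group,
        master_seed=derive_seed(master_seed, 0xD15C) % (2**31),
    )
    cohort = generate_cohort(design)
    config = StudyConfig(design=design, b_grid=(bin_width,),
                         d_grid=(bin_count,))
    vois = build_voi_records(cohort, config)
    table = extract_feature_table(vois, config.schemes())
    records, summary, r2_tables = compute_statistics(table, alpha=0.05)

    sig = {
        (row["method"], row["segmentation"]): int(row["n_significant"])
        for _, row in summary.iterrows()
    }
    tests = {
        (row["method"], row["segmentation"]): int(row["n_tests"])
        for _, row in summary.iterrows()
    }
    high_corr = {}
    for tag, tbl in r2_tables.items():
        high_corr[tag] = int((tbl > HIGH_CORRELATION_R2).sum().sum())
    return {
        "n_significant": sig,
        "n_tests": tests,
        "n_high_correlation": high_corr,
        "summary": summary,
        "r2_tables": r2_tables,
    }
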