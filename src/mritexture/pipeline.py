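"""End-to-end study orchestration.

``run_study`` executes the whole experiment from one config: synthesize the
cohort, construct pathological and mirrored-control VOIs in both
segmentation styles, sweep the discretization grids, extract all 40 texture
indices per VOI, and run the statistical comparison stage (Spearman
feature-volume correlations, rank-sum pathological-vs-control screening,
significance counts, R^2 maps).  Identical config and seed give
byte-identical CSV outputs.

The default grids are a desk-scale subset (B in {10, 50, 100}, D in
{8, 64, 256}, 6 subjects per group); ``StudyConfig.full_scale()`` selects
the complete 21 + 8 grid sweep and the 22/22/27 cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .discretization import DiscretizationScheme, default_grids
from .features import extract_features
from .io import load_nifti, save_cohort
from .stats import (
    StatRecord,
    correlation_matrix_table,
    count_significant,
    ranksum_disease_vs_control,
    spearman_feature_volume,
)
from .synthetic import CohortDesign, SubjectRecord, generate_cohort
from .voi import (
    VOIMask,
    ellipsoid_voi,
    filter_min_volume,
    manual_like_voi,
    mirror_voi,
    read_voxel_list,
)
from .io import grid_from_voxel_list

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "VOIRecord", "run_study", "build_voi_records",
           "extract_feature_table", "compute_statistics", "real_data_ingest"]


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run."""

    design: CohortDesign = field(
        default_factory=lambda: CohortDesign(n_is=6, n_ms=6, n_tu=6)
    )
    b_grid: tuple[float, ...] = (10.0, 50.0, 100.0)
    d_grid: tuple[int, ...] = (8, 64, 256)
    include_lar: bool = False
    clip: tuple[float, float] | None = (10.0, 90.0)
    manual_margin_mm: float = 2.0
    elliptical_shrink_mm: float | None = None  # None: use the blur width
    min_voi_cm3: float = 1.0
    alpha: float = 0.05
    out_dir: str = "study_out"

    @classmethod
    def full_scale(cls, master_seed: int = 0, out_dir: str = "study_out"):
        """The complete design: 22/22/27 subjects and the full B/D grids."""
        b_grid, d_grid = default_grids()
        return cls(
            design=CohortDesign(master_seed=master_seed),
            b_grid=b_grid, d_grid=d_grid, out_dir=out_dir,
        )

    def schemes(self) -> list[DiscretizationScheme]:
        out = [DiscretizationScheme.ar(b, clip=self.clip) for b in self.b_grid]
        if self.include_lar:
            out += [DiscretizationScheme.lar(b, clip=self.clip) for b in self.b_grid]
        out += [DiscretizationScheme.lrr(int(d)) for d in self.d_grid]
        return out

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        design = data.pop("design", {})
        design = CohortDesign(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in design.items()
            }
        )
        kwargs = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(design=design, **kwargs)


@dataclass
class VOIRecord:
    """One VOI ready for feature extraction, with its design-cell keys."""

    subject_id: str
    group: str
    contrast: str
    segmentation: str
    role: str
    lesion_id: int
    volume: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * float(np.prod(self.spacing))


def build_voi_records(
    records: Sequence[SubjectRecord], config: StudyConfig
) -> list[VOIRecord]:
    """Construct the 4 VOIs (2 styles x 2 roles) per lesion and contrast.

    Elliptical VOIs are placed at the lesion center with semi-axes shrunk by
    the partial-volume blur width so they sample the lesion core; manual-like
    VOIs dilate the true lesion mask outward by ``manual_margin_mm``.  Both
    are mirrored across the midsagittal plane to give co-lateral controls.
    A (lesion, style) pair is kept only if the pathological VOI meets the
    minimum-volume rule; its control is kept or dropped with it.
    """
    out: list[VOIRecord] = []
    for rec in records:
        spec = rec.spec
        spacing = next(iter(rec.volumes.values())).spacing
        grid_shape = next(iter(rec.volumes.values())).shape
        mid_index = (grid_shape[0] - 1) / 2.0
        blur = max(
            spec.background_params.boundary_blur_sigma,
            max(p.boundary_blur_sigma for p in spec.lesion_params.values()),
        )
        shrink = (
            config.elliptical_shrink_mm
            if config.elliptical_shrink_mm is not None
            else blur
        )
        for k, lesion_mask in enumerate(rec.lesion_masks):
            center = spec.lesion_centers[k]
            radii = tuple(max(r - shrink, 1.0) for r in spec.lesion_radii[k])
            label = f"{spec.subject_id}_l{k}"
            styled: dict[str, VOIMask] = {}
            try:
                styled["elliptical"] = ellipsoid_voi(
                    center, radii, grid_shape, spacing, label=label
                )
            except ValueError as exc:
                logger.warning("skipping elliptical VOI %s: %s", label, exc)
            true_voi = VOIMask(
                lesion_mask, role="pathological", style="elliptical",
                spacing=spacing, label=label,
            )
            styled["manual"] = manual_like_voi(true_voi, config.manual_margin_mm)
            for style, voi in styled.items():
                if not filter_min_volume([voi], config.min_voi_cm3):
                    logger.info(
                        "dropping %s %s VOI below %.1f cm^3",
                        label, style, config.min_voi_cm3,
                    )
                    continue
                try:
                    control = mirror_voi(voi, mid_index)
                except ValueError as exc:
                    logger.warning("skipping control for %s: %s", label, exc)
                    continue
                for contrast, vol in rec.volumes.items():
                    for mask_obj in (voi, control):
                        out.append(
                            VOIRecord(
                                subject_id=spec.subject_id,
                                group=spec.disease_group,
                                contrast=contrast,
                                segmentation=style,
                                role=mask_obj.role,
                                lesion_id=k,
                                volume=vol.voxels,
                                mask=mask_obj.mask,
                                spacing=spacing,
                            )
                        )
    return out


def extract_feature_table(
    voi_records: Sequence[VOIRecord],
    schemes: Sequence[DiscretizationScheme],
    distance: int = 1,
) -> pd.DataFrame:
    """Long-format feature table over every VOI x scheme combination.

    Columns: subject_id, group, contrast, segmentation, role, lesion_id,
    lesion_volume_mm3, method, param, feature, value.  VOIs for which a
    scheme degenerates are excluded with a logged reason.
    """
    rows = []
    for vr in voi_records:
        for scheme in schemes:
            try:
                feats = extract_features(
                    vr.volume, vr.mask, scheme, spacing=vr.spacing,
                    distance=distance,
                )
            except ValueError as exc:
                logger.warning(
                    "excluding %s/%s lesion %d (%s %s, %s): %s",
                    vr.subject_id, vr.contrast, vr.lesion_id,
                    vr.segmentation, vr.role, scheme.tag(), exc,
                )
                continue
            base = {
                "subject_id": vr.subject_id,
                "group": vr.group,
                "contrast": vr.contrast,
                "segmentation": vr.segmentation,
                "role": vr.role,
                "lesion_id": vr.lesion_id,
                "lesion_volume_mm3": vr.volume_mm3,
                "method": scheme.method,
                "param": float(scheme.param),
            }
            for feature, value in feats.items():
                rows.append({**base, "feature": feature, "value": value})
    return pd.DataFrame(rows)


def compute_statistics(
    features: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """The statistical comparison stage on a long feature table.

    Returns (stat_records, significance_summary, r2_tables) where
    r2_tables maps "<method>_<param>_<segmentation>" to a wide feature x
    (group-role x contrast) R^2 map.
    """
    stat_records: list[StatRecord] = []
    cell_keys = ["method", "param", "segmentation"]
    for (method, param, seg), cell in features.groupby(cell_keys, sort=True):
        # Spearman feature-vs-volume per (group, role, contrast, feature)
        for (group, role, contrast, feat), sub in cell.groupby(
            ["group", "role", "contrast", "feature"], sort=True
        ):
            if len(sub) < 3:
                continue
            tag = "path" if role == "pathological" else "ctrl"
            stat_records.append(
                spearman_feature_volume(
                    sub["value"].to_numpy(),
                    sub["lesion_volume_mm3"].to_numpy(),
                    feature=feat, group=f"{group}-{tag}", contrast=contrast,
                    segmentation=seg, method=method, param=param,
                )
            )
        # rank-sum pathological vs control per (group, contrast, feature)
        for (group, contrast, feat), sub in cell.groupby(
            ["group", "contrast", "feature"], sort=True
        ):
            x = sub.loc[sub["role"] == "pathological", "value"].to_numpy()
            y = sub.loc[sub["role"] == "control", "value"].to_numpy()
            if len(x) < 2 or len(y) < 2:
                continue
            stat_records.append(
                ranksum_disease_vs_control(
                    x, y, feature=feat, group=group, contrast=contrast,
                    segmentation=seg, method=method, param=param,
                )
            )

    summaries = count_significant(stat_records, alpha=alpha)
    summary_df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])

    r2_tables: dict[str, pd.DataFrame] = {}
    spearman = [r for r in stat_records if r.kind == "spearman_rho"]
    seen = sorted({(r.method, r.param, r.segmentation) for r in spearman})
    for method, param, seg in seen:
        cell_recs = [
            r for r in spearman
            if (r.method, r.param, r.segmentation) == (method, param, seg)
        ]
        r2_tables[f"{method}_{param:g}_{seg}"] = correlation_matrix_table(cell_recs)

    records_df = pd.DataFrame([dataclasses.asdict(r) for r in stat_records])
    return records_df, summary_df, r2_tables


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig) -> dict:
    """Run the full experiment and write all outputs under config.out_dir.

    Returns a manifest dict with output paths, SHA-256 digests and row
    counts.  The run is a pure function of the config (including the
    design's master seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("generating cohort (%d subjects)", config.design.n_subjects)
    cohort = generate_cohort(config.design)
    cohort_manifest = save_cohort(cohort, out / "cohort")

    voi_records = build_voi_records(cohort, config)
    logger.info("constructed %d VOIs", len(voi_records))

    features = extract_feature_table(voi_records, config.schemes())
    features_path = out / "features.csv"
    features.to_csv(features_path, index=False)

    records_df, summary_df, r2_tables = compute_statistics(
        features, alpha=config.alpha
    )
    records_path = out / "stat_records.csv"
    summary_path = out / "significance_summary.csv"
    records_df.to_csv(records_path, index=False)
    summary_df.to_csv(summary_path, index=False)
    r2_paths = []
    for tag, table in r2_tables.items():
        p = out / f"r2_map_{tag}.csv"
        table.to_csv(p)
        r2_paths.append(p)

    manifest = {
        "n_subjects": config.design.n_subjects,
        "n_vois": len(voi_records),
        "n_feature_rows": int(len(features)),
        "n_stat_records": int(len(records_df)),
        "outputs": {
            str(p.relative_to(out)): _digest(p)
            for p in [features_path, records_path, summary_path, *r2_paths]
        },
    }
    with open(out / "run_manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def real_data_ingest(table: pd.DataFrame) -> list[VOIRecord]:
    """Build extraction-ready VOI records from real-data file paths.

    ``table`` needs columns subject_id, group, contrast, segmentation, role,
    lesion_id and either (volume_path, mask_path) pointing to NIfTI files on
    a shared grid, or voxel_list_path pointing to a plain-text per-voxel
    export.  Shape or spacing mismatches between a volume and its mask raise
    with both files named.
    """
    required = {"subject_id", "group", "contrast", "segmentation", "role",
                "lesion_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    out: list[VOIRecord] = []
    for _, row in table.iterrows():
        if "voxel_list_path" in table.columns and isinstance(
            row.get("voxel_list_path"), str
        ) and row["voxel_list_path"]:
            coords, vals = read_voxel_list(row["voxel_list_path"])
            vol, mask = grid_from_voxel_list(coords, vals)
            spacing = tuple(row.get("spacing", (1.0, 1.0, 1.0)))
        else:
            vol, spacing = load_nifti(row["volume_path"])
            mask_arr, mask_spacing = load_nifti(row["mask_path"])
            if vol.shape != mask_arr.shape:
                raise ValueError(
                    f"shape mismatch: {row['volume_path']} {vol.shape} vs "
                    f"{row['mask_path']} {mask_arr.shape}"
                )
            if not np.allclose(spacing, mask_spacing):
                raise ValueError(
                    f"spacing mismatch: {row['volume_path']} {spacing} vs "
                    f"{row['mask_path']} {mask_spacing}"
                )
            mask = mask_arr > 0.5
        out.append(
            VOIRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                contrast=str(row["contrast"]),
                segmentation=str(row["segmentation"]),
                role=str(row["role"]),
                lesion_id=int(row["lesion_id"]),
                volume=vol,
                mask=mask,
                spacing=tuple(float(s) for s in spacing),
            )
        )
    return out
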