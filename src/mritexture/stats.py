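"""Cohort-level statistics on texture indices.

Two analyses mirror the study design this package supports:

* Spearman rank correlation between each texture index and lesion volume,
  within every (disease group, VOI role, contrast) cell, reported as rho and
  R^2 = rho^2; |R| > sqrt(0.5) ~ 0.71 is flagged "highly correlated".
* Two-sided Wilcoxon rank-sum (Mann-Whitney) screening of pathological vs
  co-lateral control VOIs for every index, with an exact enumeration branch
  for small tie-free samples and the tie/continuity-corrected normal
  approximation otherwise.

Significance counting uses strict p < alpha with no multiple-testing
correction; the screening is deliberately liberal, matching common practice
in binning-sensitivity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatRecord",
    "SignificanceSummary",
    "HIGH_CORRELATION_R2",
    "high_correlation_abs_r",
    "spearman_feature_volume",
    "ranksum_disease_vs_control",
    "count_significant",
    "correlation_matrix_table",
    "EXACT_RANKSUM_MAX_N",
]

#: R^2 threshold above which a feature-volume correlation counts as "high".
HIGH_CORRELATION_R2 = 0.5

#: Largest combined sample size for the exact (enumeration) rank-sum branch.
EXACT_RANKSUM_MAX_N = 10


def high_correlation_abs_r(r2_threshold: float = HIGH_CORRELATION_R2) -> float:
    """|R| threshold equivalent to the R^2 high-correlation rule (~0.71)."""
    return math.sqrt(r2_threshold)


@dataclass
class StatRecord:
    """One statistical result keyed by its design cell."""

    feature: str
    group: str = ""
    contrast: str = ""
    segmentation: str = ""
    method: str = ""
    param: float = float("nan")
    kind: str = ""        # "spearman_rho" | "ranksum_p"
    value: float = float("nan")
    n_observations: int = 0
    degenerate: bool = False

    @property
    def r_squared(self) -> float:
        if self.kind != "spearman_rho":
            raise ValueError("r_squared only defined for spearman records")
        return self.value**2


@dataclass
class SignificanceSummary:
    """Significant-test count for one (method, param, segmentation) cell."""

    method: str
    param: float
    segmentation: str
    alpha: float
    n_tests: int
    n_significant: int


def spearman_feature_volume(
    values, volumes, *, feature: str = "", group: str = "", contrast: str = "",
    segmentation: str = "", method: str = "", param: float = float("nan"),
) -> StatRecord:
    """Spearman rho between a texture index and lesion volume.

    Average ranks are assigned to ties.  A constant feature or constant
    volume vector leaves rho undefined; the record is flagged degenerate and
    must be excluded from maps rather than treated as zero.
    """
    values = np.asarray(values, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if values.shape != volumes.shape or values.ndim != 1:
        raise ValueError("values and volumes must be equal-length 1D arrays")
    if values.size < 3:
        raise ValueError("need at least 3 paired observations")
    degenerate = bool(
        np.all(values == values[0]) or np.all(volumes == volumes[0])
    )
    if degenerate:
        rho = float("nan")
    else:
        rho = float(sps.spearmanr(values, volumes).statistic)
    return StatRecord(
        feature=feature, group=group, contrast=contrast,
        segmentation=segmentation, method=method, param=param,
        kind="spearman_rho", value=rho, n_observations=values.size,
        degenerate=degenerate,
    )


def ranksum_disease_vs_control(
    pathological, control, *, feature: str = "", group: str = "",
    contrast: str = "", segmentation: str = "", method: str = "",
    param: float = float("nan"),
) -> StatRecord:
    """Two-sided Wilcoxon rank-sum p-value, pathological vs control.

    Uses exact enumeration when n1 + n2 <= 10 and the pooled sample is
    tie-free, otherwise the normal approximation with tie correction and
    continuity correction (the behaviour of the classical ``ranksum``
    routine).  Two identical constant samples give p = 1 with a degeneracy
    flag.
    """
    x = np.asarray(pathological, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    degenerate = bool(np.all(pooled == pooled[0]))
    if degenerate:
        p = 1.0
    else:
        has_ties = np.unique(pooled).size < pooled.size
        if x.size + y.size <= EXACT_RANKSUM_MAX_N and not has_ties:
            p = float(
                sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            )
        else:
            p = float(
                sps.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic",
                    use_continuity=True,
                ).pvalue
            )
        p = min(p, 1.0)
    return StatRecord(
        feature=feature, group=group, contrast=contrast,
        segmentation=segmentation, method=method, param=param,
        kind="ranksum_p", value=p, n_observations=x.size + y.size,
        degenerate=degenerate,
    )


def count_significant(
    records: list[StatRecord], alpha: float = 0.05
) -> list[SignificanceSummary]:
    """Count rank-sum records with p < alpha per (method, param, segmentation).

    Strict inequality; degenerate records count toward n_tests but are never
    significant.  No multiple-testing correction is applied.
    """
    cells: dict[tuple, list[StatRecord]] = {}
    for rec in records:
        if rec.kind != "ranksum_p":
            continue
        cells.setdefault((rec.method, rec.param, rec.segmentation), []).append(rec)
    out = []
    for (method, param, seg), recs in sorted(cells.items()):
        n_sig = sum(
            1 for r in recs if (not r.degenerate) and r.value < alpha
        )
        out.append(
            SignificanceSummary(
                method=method, param=param, segmentation=seg, alpha=alpha,
                n_tests=len(recs), n_significant=n_sig,
            )
        )
    return out


def correlation_matrix_table(records: list[StatRecord]) -> pd.DataFrame:
    """Wide R^2 map: features as rows, (group, role-tag, contrast) columns.

    Expects the spearman records of one (method-param, segmentation) pair;
    the group field should already encode the VOI role (e.g. ``IS-path`` /
    ``IS-ctrl``).  Degenerate cells are emitted as NaN.
    """
    recs = [r for r in records if r.kind == "spearman_rho"]
    if not recs:
        raise ValueError("no spearman records supplied")
    keys = {(r.method, r.param, r.segmentation) for r in recs}
    if len(keys) > 1:
        raise ValueError(
            f"records span multiple (method, param, segmentation) cells: {keys}"
        )
    rows = [
        {
            "feature": r.feature,
            "column": f"{r.group}_{r.contrast}",
            "r2": float("nan") if r.degenerate else r.value**2,
        }
        for r in recs
    ]
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index="feature", columns="column", values="r2", dropna=False,
        aggfunc="first", sort=False,
    )
    table.index.name = "feature"
    return table


def high_correlation_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Boolean map of cells with R^2 above the high-correlation threshold."""
    return table > HIGH_CORRELATION_R2
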