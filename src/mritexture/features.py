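"""Standardised texture-index formulas on grey-level matrices.

The 40-feature roster is 18 co-occurrence (GLCM), 11 run-length (GLRLM) and
11 size-zone (GLSZM) indices, evaluated with the standard reference
definitions.  Names are prefixed with the matrix family in the combined
vector (``glcm_JMax`` ... ``glszm_ZP``).

Degenerate inputs (a single observed grey level) would divide by zero in a
few formulas; those get defined fallbacks instead of NaN so large synthetic
sweeps cannot poison downstream statistics: entropies are 0, GLCM
Correlation is set to 0 (zero marginal variance), and NormInvDiff is 1.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .discretization import DiscretizationScheme, DiscretizedVOI, discretize
from .matrices import (
    GreyLevelCooccurrenceMatrix,
    GreyLevelRunLengthMatrix,
    GreyLevelSizeZoneMatrix,
    build_glcm,
    build_glrlm,
    build_glszm,
)

__all__ = [
    "GLCM_FEATURES",
    "GLRLM_FEATURES",
    "GLSZM_FEATURES",
    "ALL_FEATURES",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_all",
    "extract_features",
]

GLCM_FEATURES = (
    "JMax", "JointAverage", "JVar", "JEntropy", "Dissim",
    "DifferenceVariance", "DifferenceEntropy", "SumAverage", "SumVar",
    "SumEntropy", "AngularSecondMoment", "Contrast", "Correlation",
    "ClusterTendency", "ClusterShade", "ClusterProm", "InverseDifference",
    "NormInvDiff",
)
GLRLM_FEATURES = (
    "SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE",
    "GLNU", "RLNU", "RP",
)
GLSZM_FEATURES = (
    "SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE",
    "GLNUz", "ZSNU", "ZP",
)
ALL_FEATURES = (
    tuple(f"glcm_{n}" for n in GLCM_FEATURES)
    + tuple(f"glrlm_{n}" for n in GLRLM_FEATURES)
    + tuple(f"glszm_{n}" for n in GLSZM_FEATURES)
)


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits over the nonzero probabilities."""
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(m: GreyLevelCooccurrenceMatrix) -> "OrderedDict[str, float]":
    """The 18 co-occurrence indices of a symmetric, normalised GLCM."""
    p = m.probabilities
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, ng + 1, dtype=np.float64)[None, :]

    # marginal (row) distribution; matrix is symmetric so rows == columns
    p_i = p.sum(axis=1)
    lv = np.arange(1, ng + 1, dtype=np.float64)
    mu = float((lv * p_i).sum())
    var = float(((lv - mu) ** 2 * p_i).sum())

    # difference distribution p_{|i-j|}(k), k = 0..ng-1
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(i - j).astype(int).ravel(), p.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    diff_var = float(((k_diff - diff_avg) ** 2 * p_diff).sum())

    # sum distribution p_{i+j}(k), k = 2..2*ng
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (i + j).astype(int).ravel() - 2, p.ravel())
    sum_avg = float((k_sum * p_sum).sum())
    sum_var = float(((k_sum - sum_avg) ** 2 * p_sum).sum())

    if var > 0:
        correlation = float((((i - mu) * (j - mu) * p).sum()) / var)
    else:
        correlation = 0.0  # degenerate: a single grey level has no spread

    out: "OrderedDict[str, float]" = OrderedDict()
    out["JMax"] = float(p.max())
    out["JointAverage"] = mu
    out["JVar"] = float((((i - mu) ** 2) * p).sum())
    out["JEntropy"] = _entropy(p.ravel())
    out["Dissim"] = diff_avg
    out["DifferenceVariance"] = diff_var
    out["DifferenceEntropy"] = _entropy(p_diff)
    out["SumAverage"] = sum_avg
    out["SumVar"] = sum_var
    out["SumEntropy"] = _entropy(p_sum)
    out["AngularSecondMoment"] = float((p**2).sum())
    out["Contrast"] = float((((i - j) ** 2) * p).sum())
    out["Correlation"] = correlation
    out["ClusterTendency"] = float((((i + j - 2 * mu) ** 2) * p).sum())
    out["ClusterShade"] = float((((i + j - 2 * mu) ** 3) * p).sum())
    out["ClusterProm"] = float((((i + j - 2 * mu) ** 4) * p).sum())
    out["InverseDifference"] = float((p / (1.0 + np.abs(i - j))).sum())
    out["NormInvDiff"] = float((p / (1.0 + np.abs(i - j) / ng)).sum())
    return out


def _rlm_style_features(
    counts: np.ndarray, n_voxels: int, denom_voxels: float,
    names: tuple[str, ...],
) -> "OrderedDict[str, float]":
    """Shared run-length / size-zone formula block.

    ``counts`` is the (level, length-or-size) matrix; ``denom_voxels`` is the
    denominator of the percentage feature (n_voxels * n_directions for runs,
    n_voxels for zones).
    """
    ns = counts.sum()
    if ns == 0:
        raise ValueError("degenerate matrix: no runs/zones")
    g = np.arange(1, counts.shape[0] + 1, dtype=np.float64)[:, None]
    r = np.arange(1, counts.shape[1] + 1, dtype=np.float64)[None, :]
    c = counts
    out: "OrderedDict[str, float]" = OrderedDict()
    out[names[0]] = float((c / r**2).sum() / ns)              # short / small
    out[names[1]] = float((c * r**2).sum() / ns)              # long / large
    out[names[2]] = float((c / g**2).sum() / ns)              # low grey
    out[names[3]] = float((c * g**2).sum() / ns)              # high grey
    out[names[4]] = float((c / (g**2 * r**2)).sum() / ns)
    out[names[5]] = float((c * g**2 / r**2).sum() / ns)
    out[names[6]] = float((c * r**2 / g**2).sum() / ns)
    out[names[7]] = float((c * g**2 * r**2).sum() / ns)
    out[names[8]] = float((c.sum(axis=1) ** 2).sum() / ns)    # grey-level non-uniformity
    out[names[9]] = float((c.sum(axis=0) ** 2).sum() / ns)    # length/size non-uniformity
    out[names[10]] = float(ns / denom_voxels)                 # percentage
    return out


def glrlm_features(m: GreyLevelRunLengthMatrix) -> "OrderedDict[str, float]":
    """The 11 run-length indices (RP uses the merged-direction denominator)."""
    return _rlm_style_features(
        m.counts, m.n_voxels, float(m.n_voxels * m.n_directions), GLRLM_FEATURES
    )


def glszm_features(m: GreyLevelSizeZoneMatrix) -> "OrderedDict[str, float]":
    """The 11 size-zone indices."""
    return _rlm_style_features(
        m.counts, m.n_voxels, float(m.n_voxels), GLSZM_FEATURES
    )


def extract_all(voi: DiscretizedVOI, distance: int = 1) -> "OrderedDict[str, float]":
    """All 40 texture indices of one discretized VOI, in stable order."""
    out: "OrderedDict[str, float]" = OrderedDict()
    for name, val in glcm_features(build_glcm(voi, distance=distance)).items():
        out[f"glcm_{name}"] = val
    for name, val in glrlm_features(build_glrlm(voi)).items():
        out[f"glrlm_{name}"] = val
    for name, val in glszm_features(build_glszm(voi)).items():
        out[f"glszm_{name}"] = val
    return out


def extract_features(
    volume: np.ndarray,
    mask: np.ndarray,
    scheme: DiscretizationScheme,
    spacing=None,
    distance: int = 1,
) -> "OrderedDict[str, float]":
    """Discretize the masked voxels with one scheme and compute all 40 TIs."""
    dv = discretize(volume, mask, scheme, spacing=spacing)
    return extract_all(dv, distance=distance)
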