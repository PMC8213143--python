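"""Scikit-learn-style transformers for discretization and feature extraction.

Both stages of the per-VOI pipeline are transform-shaped, so they are
exposed as estimators that compose with :class:`sklearn.pipeline.Pipeline`
and grid search: samples are VOIs, i.e. ``(volume, mask)`` array pairs (or
:class:`~mritexture.discretization.DiscretizedVOI` objects downstream).

>>> est = TextureFeatureExtractor(method="AR", bin_width=50.0)
>>> X = [(volume, mask)]          # one sample = one VOI        # doctest: +SKIP
>>> df = est.fit_transform(X)     # (n_vois, 40) DataFrame      # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .discretization import DiscretizationScheme, DiscretizedVOI, discretize
from .features import ALL_FEATURES, extract_all

__all__ = ["GreyLevelDiscretizer", "TextureFeatureExtractor"]


def _scheme_from_params(method, bin_width, bin_count, clip) -> DiscretizationScheme:
    if clip == "default":
        clip = (10.0, 90.0) if method in ("LAR", "AR") else None
    if method in ("LAR", "AR"):
        return DiscretizationScheme(method, bin_width=bin_width,
                                    clip_percentiles=clip)
    return DiscretizationScheme(method, bin_count=bin_count,
                                clip_percentiles=clip)


def _as_voi_pair(sample):
    if isinstance(sample, tuple) and len(sample) == 2:
        vol, mask = sample
        return np.asarray(vol, dtype=float), np.asarray(mask, dtype=bool)
    raise TypeError("each sample must be a (volume, mask) pair")


class GreyLevelDiscretizer(BaseEstimator, TransformerMixin):
    """Map VOI intensities to integer grey levels with one binning scheme.

    Parameters
    ----------
    method : {"LAR", "AR", "LRR"}
        Fixed-bin-size anchored at the VOI minimum (LAR) or at absolute
        zero (AR), or fixed-bin-number over the VOI range (LRR).
    bin_width : float, default 50.0
        Bin width B; used by LAR and AR.
    bin_count : int, default 64
        Bin count D; used by LRR.
    clip : tuple, None or "default"
        Winsorization percentiles; "default" applies (10, 90) to LAR/AR
        and no clipping to LRR.

    Attributes
    ----------
    scheme_ : DiscretizationScheme
        The resolved scheme after ``fit``.
    """

    def __init__(self, method: str = "AR", bin_width: float = 50.0,
                 bin_count: int = 64, clip="default"):
        self.method = method
        self.bin_width = bin_width
        self.bin_count = bin_count
        self.clip = clip

    def fit(self, X, y=None):
        self.scheme_ = _scheme_from_params(
            self.method, self.bin_width, self.bin_count, self.clip
        )
        return self

    def transform(self, X) -> list[DiscretizedVOI]:
        if not hasattr(self, "scheme_"):
            self.fit(X)
        return [
            discretize(*_as_voi_pair(sample), self.scheme_) for sample in X
        ]


class TextureFeatureExtractor(BaseEstimator, TransformerMixin):
    """Extract the 40 texture indices from each VOI under one scheme.

    ``transform`` accepts a list of ``(volume, mask)`` pairs or of
    already-discretized VOIs, and returns an ``(n_samples, 40)`` DataFrame
    with stable column names (``feature_names_``).
    """

    def __init__(self, method: str = "AR", bin_width: float = 50.0,
                 bin_count: int = 64, clip="default", distance: int = 1):
        self.method = method
        self.bin_width = bin_width
        self.bin_count = bin_count
        self.clip = clip
        self.distance = distance

    def fit(self, X, y=None):
        self.scheme_ = _scheme_from_params(
            self.method, self.bin_width, self.bin_count, self.clip
        )
        self.feature_names_ = list(ALL_FEATURES)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "scheme_"):
            self.fit(X)
        rows = []
        for sample in X:
            if isinstance(sample, DiscretizedVOI):
                dv = sample
            else:
                dv = discretize(*_as_voi_pair(sample), self.scheme_)
            rows.append(extract_all(dv, distance=self.distance))
        return pd.DataFrame(rows, columns=self.feature_names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
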