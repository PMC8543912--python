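"""Radiomics feature extraction for quantitative parameter maps.

For each (parameter map, lesion mask) pair this package computes the fixed
100-feature vector used throughout the pipeline:

* 18 first-order intensity features,
* 14 3D shape features,
* 22 gray-level co-occurrence matrix (GLCM) features,
* 16 gray-level run-length matrix (GLRLM) features,
* 16 gray-level size-zone matrix (GLSZM) features,
* 14 gray-level dependence matrix (GLDM) features,

plus the lesion-mean diffusion metric of every map and inter-reader
ICC(2,1) reproducibility scores.  Column names follow
``<map>__<group>__<feature>``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..fitting import MAP_NAMES, ParameterMap
from ._discretize import DEFAULT_BIN_WIDTHS, bin_width_for, discretize
from ._firstorder import FIRSTORDER_NAMES, firstorder_features
from ._shape import SHAPE_NAMES, shape_features
from ._texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
)
from .icc import icc, reproducible_features

__all__ = [
    "FEATURE_GROUPS",
    "N_FEATURES",
    "FeatureVector",
    "extract_features",
    "mean_metric",
    "mean_metric_vector",
    "feature_row",
    "build_feature_matrix",
    "icc",
    "reproducible_features",
    "DEFAULT_BIN_WIDTHS",
]

#: group name -> ordered feature names; sizes 18/14/22/16/16/14 = 100.
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
}
N_FEATURES = sum(len(v) for v in FEATURE_GROUPS.values())
assert N_FEATURES == 100


@dataclass
class FeatureVector:
    """The 100 named features for one (map, mask) pair."""

    map_id: str
    features: dict[str, float]  # "<group>__<feature>" -> value

    def __post_init__(self):
        expected = [f"{g}__{f}" for g, names in FEATURE_GROUPS.items()
                    for f in names]
        if list(self.features) != expected:
            raise ValueError("feature vector must contain exactly the 100 "
                             "canonical features in canonical order")

    def group(self, name: str) -> dict[str, float]:
        prefix = f"{name}__"
        return {k[len(prefix):]: v for k, v in self.features.items()
                if k.startswith(prefix)}

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.features.values(),
            index=[f"{self.map_id}__{k}" for k in self.features],
        )


def _values_and_mask(pmap, mask):
    values = pmap.values if isinstance(pmap, ParameterMap) else np.asarray(pmap)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask shape must match map shape")
    if not mask.any():
        raise ValueError("mask is empty")
    # exclude voxels the fitter flagged invalid
    mask = mask & np.isfinite(values)
    if not mask.any():
        raise ValueError("no valid fitted voxels inside mask")
    return values, mask


def extract_features(pmap, mask, spacing,
                     bin_width: float | None = None,
                     map_id: str | None = None) -> FeatureVector:
    """Compute the 100-feature vector of one parameter map over a mask.

    ``bin_width`` overrides the pinned per-map discretization width.
    Deterministic for fixed inputs and settings.
    """
    values, mask = _values_and_mask(pmap, mask)
    if map_id is None:
        map_id = pmap.parameter if isinstance(pmap, ParameterMap) else "map"
    if int(mask.sum()) < 2:
        raise ValueError(
            "shape and texture features are undefined for a single-voxel mask")
    spacing = tuple(float(s) for s in spacing)

    # crop to the mask bounding box (texture matrices only see the lesion)
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_vals = values[box]
    sub_mask = mask[box]

    width = bin_width if bin_width is not None else bin_width_for(
        map_id, values[mask])
    disc = np.where(sub_mask, discretize(np.where(sub_mask, sub_vals, 0.0),
                                         width), 0)

    feats: dict[str, float] = {}
    fo = firstorder_features(values[mask], disc[sub_mask],
                             float(np.prod(spacing)))
    feats.update({f"firstorder__{k}": fo[k] for k in FIRSTORDER_NAMES})
    sh = shape_features(mask, spacing)
    feats.update({f"shape__{k}": sh[k] for k in SHAPE_NAMES})
    for group, fn, names in (
        ("glcm", glcm_features, GLCM_NAMES),
        ("glrlm", glrlm_features, GLRLM_NAMES),
        ("glszm", glszm_features, GLSZM_NAMES),
        ("gldm", gldm_features, GLDM_NAMES),
    ):
        vals = fn(disc, sub_mask)
        feats.update({f"{group}__{k}": vals[k] for k in names})
    fv = FeatureVector(map_id=map_id, features=feats)
    bad = [k for k, v in feats.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    return fv


def mean_metric(pmap, mask) -> float:
    """Arithmetic mean of a parameter map over the (valid) mask voxels."""
    values, mask = _values_and_mask(pmap, mask)
    return float(values[mask].mean())


def mean_metric_vector(maps: dict[str, ParameterMap], mask) -> dict[str, float]:
    """The nine lesion-mean diffusion metrics, keyed mADC_all-b ... mK."""
    return {f"m{name}": mean_metric(maps[name], mask) for name in MAP_NAMES}


def feature_row(maps: dict[str, ParameterMap], mask, spacing) -> pd.Series:
    """All 900 features of one subject (9 maps x 100 features)."""
    parts = [
        extract_features(maps[name], mask, spacing, map_id=name).as_series()
        for name in MAP_NAMES
    ]
    return pd.concat(parts)


def build_feature_matrix(rows: dict[str, pd.Series],
                         labels: dict[str, str]) -> pd.DataFrame:
    """Stack per-subject feature rows into a matrix with a label column."""
    df = pd.DataFrame(rows).T
    df.index.name = "subject_id"
    df["label"] = pd.Series(labels)
    return df
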