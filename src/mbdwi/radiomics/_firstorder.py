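"""First-order (intensity histogram) features: 18 features."""

from __future__ import annotations

import numpy as np

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

_EPS = np.spacing(1.0)


def firstorder_features(values: np.ndarray, disc: np.ndarray,
                        voxel_volume: float) -> dict[str, float]:
    """18 first-order features of the masked intensities.

    ``values`` are the raw intensities inside the mask, ``disc`` their
    discretized gray levels (for Entropy/Uniformity), ``voxel_volume`` the
    voxel volume in mm^3 (for TotalEnergy).  Skewness and Kurtosis use the
    population moment ratios (Kurtosis is not excess-corrected); degenerate
    zero-variance input yields Skewness = Kurtosis = 0.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    p = np.bincount(disc)[1:].astype(float)
    p = p[p > 0] / n

    mean = float(x.mean())
    dev = x - mean
    m2 = float(np.mean(dev**2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2
    else:
        skew = kurt = 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p + _EPS))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": m2,
        "Uniformity": float(np.sum(p**2)),
    }
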