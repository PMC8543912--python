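"""Inter-reader reproducibility: two-way random-effects ICC.

ICC(2,1) — two-way random effects, absolute agreement, single rater —
computed in closed form from the two-way ANOVA mean squares, vectorized
over feature columns so a 900-feature matrix is scored in one pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["icc", "reproducible_features"]


def icc(readings_a, readings_b) -> pd.Series:
    """Per-feature ICC(2,1) between two readers' feature matrices.

    Inputs are aligned (subjects x features) DataFrames or arrays.  Features
    with zero between-subject variance have an undefined ICC and are
    returned as NaN (flagged, not dropped).
    """
    a = pd.DataFrame(readings_a)
    b = pd.DataFrame(readings_b)
    if a.shape != b.shape or not a.columns.equals(b.columns):
        raise ValueError("readings must have matching subjects and features")
    x = np.stack([a.to_numpy(dtype=float), b.to_numpy(dtype=float)])  # (2,n,f)
    k, n, _ = x.shape

    grand = x.mean(axis=(0, 1))
    row_mean = x.mean(axis=0)            # (n, f) subject means
    col_mean = x.mean(axis=1)            # (k, f) rater means

    ssr = k * ((row_mean - grand) ** 2).sum(axis=0)
    ssc = n * ((col_mean - grand) ** 2).sum(axis=0)
    sse = ((x - row_mean[None] - col_mean[:, None] + grand) ** 2).sum(axis=(0, 1))

    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (msr - mse) / denom
    vals = np.where(msr <= 1e-30, np.nan, vals)
    return pd.Series(vals, index=a.columns, name="icc")


def reproducible_features(icc_values: pd.Series,
                          threshold: float = 0.80) -> pd.Series:
    """Boolean flag per feature: ICC strictly above ``threshold``."""
    return icc_values > threshold
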