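"""Gray-level discretization for texture features.

Fixed-bin-width binning: gray level g = floor((x - min(x)) / width) + 1.
Default widths are pinned per parameter map so feature values are
comparable across subjects (roughly 25 bins over each map's physiological
range); an explicit width always wins, and unknown maps fall back to a
25-bin width derived from the observed range.
"""

from __future__ import annotations

import numpy as np

#: Pinned per-map bin widths (map units / bin).
DEFAULT_BIN_WIDTHS: dict[str, float] = {
    "ADC_all-b": 1.6e-4,
    "ADC_0-1000": 1.6e-4,
    "D": 1.6e-4,
    "D_kurt": 1.6e-4,
    "DDC": 1.6e-4,
    "D*": 2.0e-3,
    "f": 0.04,
    "alpha": 0.04,
    "K": 0.12,
}

FALLBACK_BIN_COUNT = 25


def bin_width_for(map_name: str | None, values: np.ndarray) -> float:
    if map_name in DEFAULT_BIN_WIDTHS:
        return DEFAULT_BIN_WIDTHS[map_name]
    rng = float(np.max(values) - np.min(values))
    if rng <= 0:
        return 1.0
    return rng / FALLBACK_BIN_COUNT


def discretize(values: np.ndarray, width: float) -> np.ndarray:
    """Map intensities to integer gray levels 1..Ng by fixed bin width."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    g = np.floor((values - np.min(values)) / width).astype(np.int64) + 1
    return g
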