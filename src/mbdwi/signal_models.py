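"""Forward signal equations for multi-b-value diffusion MRI.

Four voxel-level models of the normalized diffusion signal S_b / S_0 as a
function of the diffusion weighting b (s/mm^2):

* mono-exponential (ME):        exp(-b * ADC)
* biexponential IVIM (BE_IVIM): (1 - f) * exp(-b * D) + f * exp(-b * D*)
* stretched exponential (SE):   exp(-(b * DDC) ** alpha)
* diffusion kurtosis (DKI):     exp(-b * D + b^2 * D^2 * K / 6)

All diffusivities (ADC, D, D*, DDC) are in mm^2/s; f, alpha and K are
dimensionless.  The functions are pure, vectorized over ``b``, and shared by
the fitter (as the model to invert) and the phantom generator (as the ground
truth forward model).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_BVALUES",
    "BValueScheme",
    "MEParams",
    "IVIMParams",
    "SEParams",
    "DKIParams",
    "me_signal",
    "ivim_signal",
    "se_signal",
    "dki_signal",
    "dki_turnover_b",
]

#: Default 13-point acquisition scheme (s/mm^2).  A configurable stand-in for a
#: clinical multi-b breast protocol spanning 0-2500 s/mm^2; not tied to any
#: particular scanner product sequence.
DEFAULT_BVALUES: tuple[float, ...] = (
    0, 10, 30, 50, 100, 150, 200, 500, 800, 1000, 1500, 2000, 2500,
)


def _check_b(b):
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


@dataclass(frozen=True)
class BValueScheme:
    """An ordered set of diffusion weightings b (s/mm^2).

    Must be strictly increasing, non-negative and contain b=0 (the
    unweighted reference volume).
    """

    values: tuple[float, ...] = DEFAULT_BVALUES

    def __post_init__(self):
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2:
            raise ValueError("scheme needs at least two b-values")
        if vals[0] != 0.0:
            raise ValueError("scheme must contain b=0 as its first entry")
        if any(v < 0 for v in vals):
            raise ValueError("b-values must be non-negative")
        if any(b >= a for b, a in zip(vals, vals[1:])):
            raise ValueError("b-values must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def asarray(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def index_of(self, b: float) -> int:
        try:
            return self.values.index(float(b))
        except ValueError as exc:
            raise KeyError(f"b={b} not in scheme {self.values}") from exc

    def subset_indices(self, bvals: Sequence[float]) -> np.ndarray:
        return np.asarray([self.index_of(b) for b in bvals], dtype=int)


@dataclass(frozen=True)
class MEParams:
    """Mono-exponential model: a single apparent diffusion coefficient."""

    adc: float

    def __post_init__(self):
        if self.adc < 0:
            raise ValueError("ADC must be non-negative")


@dataclass(frozen=True)
class IVIMParams:
    """Biexponential intravoxel-incoherent-motion parameters.

    ``d`` is the true (tissue) diffusion coefficient, ``d_star`` the
    pseudo-diffusion coefficient of the microcirculation and ``f`` the
    perfusion fraction.  The conventional identifiability constraint
    d <= d_star is enforced.
    """

    d: float
    d_star: float
    f: float

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("perfusion fraction f must lie in [0, 1]")
        if self.d < 0:
            raise ValueError("D must be non-negative")
        if self.d_star < self.d:
            raise ValueError("D* must be >= D (pseudo-diffusion is faster)")


@dataclass(frozen=True)
class SEParams:
    """Stretched-exponential parameters: DDC and heterogeneity index alpha.

    alpha in (0, 1]; alpha = 1 is homogeneous (mono-exponential) diffusion,
    smaller alpha means a broader intravoxel distribution of diffusion rates.
    """

    ddc: float
    alpha: float

    def __post_init__(self):
        if self.ddc < 0:
            raise ValueError("DDC must be non-negative")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass(frozen=True)
class DKIParams:
    """Kurtosis model parameters: corrected diffusivity D and kurtosis K.

    K = 0 recovers Gaussian (mono-exponential) diffusion; larger K means a
    heavier-tailed displacement distribution.
    """

    d: float
    k: float

    def __post_init__(self):
        if self.d < 0:
            raise ValueError("D must be non-negative")
        if self.k < 0:
            raise ValueError("K must be non-negative")


def me_signal(params: MEParams, b) -> np.ndarray:
    """S_b/S_0 = exp(-b * ADC)."""
    b = _check_b(b)
    return np.exp(-b * params.adc)


def ivim_signal(params: IVIMParams, b) -> np.ndarray:
    """S_b/S_0 = (1 - f) exp(-b D) + f exp(-b D*)."""
    b = _check_b(b)
    return (1.0 - params.f) * np.exp(-b * params.d) + params.f * np.exp(
        -b * params.d_star
    )


def se_signal(params: SEParams, b) -> np.ndarray:
    """S_b/S_0 = exp(-(b * DDC) ** alpha)."""
    b = _check_b(b)
    return np.exp(-np.power(b * params.ddc, params.alpha))


def dki_signal(params: DKIParams, b) -> np.ndarray:
    """S_b/S_0 = exp(-b D + b^2 D^2 K / 6).

    The quadratic exponent makes the curve turn upward beyond
    b = 3 / (D K); the function evaluates everywhere (the fitter is
    responsible for staying inside the validity range).
    """
    b = _check_b(b)
    d, k = params.d, params.k
    return np.exp(-b * d + (b * d) ** 2 * k / 6.0)


def dki_turnover_b(params: DKIParams) -> float:
    """b-value at which the kurtosis signal model stops decreasing.

    Equals 3 / (D K); infinite for K = 0 or D = 0 (pure mono-exponential).
    """
    if params.d <= 0 or params.k <= 0:
        return np.inf
    return 3.0 / (params.d * params.k)
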