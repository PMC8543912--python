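"""Voxel-wise fitting of diffusion signal models to multi-b-value DWI.

Produces the nine quantitative parameter maps used throughout the pipeline:

====================  =================  =======================
model                 map names          units
====================  =================  =======================
ME (mono-exp)         ADC_all-b,
                      ADC_0-1000         mm^2/s
BE_IVIM               D, D*, f           mm^2/s, mm^2/s, (1)
SE (stretched exp)    DDC, alpha         mm^2/s, (1)
DKI (kurtosis)        D_kurt, K          mm^2/s, (1)
====================  =================  =======================

Fitting strategy
----------------
Every nonlinear fit treats S_0 as a free per-voxel scale so that noise in the
measured b=0 volume does not propagate into all parameters.  The
mono-exponential ADC is obtained by log-linear least squares (closed form);
DKI is seeded by a log-quadratic linear fit and polished by bounded
Levenberg-Marquardt (trust-region reflective); the stretched-exponential fit
is seeded from the ME solution; IVIM uses a segmented two-step fit (tissue D
from the b >= 200 s/mm^2 tail, then perfusion parameters with D fixed)
whose output initializes a joint bounded refinement, which makes noiseless
recovery exact while keeping the stability of the segmented approach.

Fits run only inside an optional mask; voxels with non-positive or
non-finite b=0 signal are flagged invalid and excluded from the maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .signal_models import (
    BValueScheme,
    DKIParams,
    IVIMParams,
    MEParams,
    SEParams,
)

__all__ = [
    "DWIVolume",
    "ParameterMap",
    "FitQuality",
    "MAP_NAMES",
    "gaussian_presmooth",
    "goodness_of_fit",
    "fit_voxel",
    "fit_volume",
    "generate_map_suite",
    "qc_filter_lesion",
]

#: The nine map identifiers, in canonical order.
MAP_NAMES: tuple[str, ...] = (
    "ADC_all-b",
    "ADC_0-1000",
    "D",
    "D*",
    "f",
    "DDC",
    "alpha",
    "K",
    "D_kurt",
)

MODEL_OF_MAP: dict[str, str] = {
    "ADC_all-b": "ME",
    "ADC_0-1000": "ME",
    "D": "BE_IVIM",
    "D*": "BE_IVIM",
    "f": "BE_IVIM",
    "DDC": "SE",
    "alpha": "SE",
    "K": "DKI",
    "D_kurt": "DKI",
}

UNITS_OF_MAP: dict[str, str] = {
    "ADC_all-b": "mm^2/s",
    "ADC_0-1000": "mm^2/s",
    "D": "mm^2/s",
    "D*": "mm^2/s",
    "f": "1",
    "DDC": "mm^2/s",
    "alpha": "1",
    "K": "1",
    "D_kurt": "mm^2/s",
}

# Physiological parameter bounds (mm^2/s for diffusivities).
D_MIN, D_MAX = 1e-6, 4e-3
DSTAR_MAX = 0.5
K_MAX = 3.0
#: IVIM fits use b-values up to this limit by default: beyond ~1000 s/mm^2
#: the biexponential stops describing tissue signal (kurtosis effects) and,
#: at realistic SNR, the high-b tail of fast-diffusing lesions sinks below
#: the Rician noise floor and biases D downward.
IVIM_B_MAX = 1000.0
# Diffusivities are fitted in units of 1e-3 mm^2/s for conditioning.
_SCALE = 1e3


@dataclass
class DWIVolume:
    """A 4D stack of diffusion-weighted volumes, one 3D volume per b-value.

    ``data`` has shape (x, y, z, n_b); ``spacing`` is the voxel size in mm.
    """

    data: np.ndarray
    scheme: BValueScheme
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, b)")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) must match the "
                f"b-value scheme length ({len(self.scheme)})"
            )
        if np.any(self.data < 0):
            raise ValueError("signal intensities must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def volume_at(self, b: float) -> np.ndarray:
        """The 3D volume acquired at diffusion weighting ``b``."""
        return self.data[..., self.scheme.index_of(b)]


@dataclass
class ParameterMap:
    """One 3D quantitative map produced by voxel-wise fitting."""

    model: str
    parameter: str
    values: np.ndarray
    units: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("parameter map must be 3D")


@dataclass
class FitQuality:
    """Per-voxel R^2 of one model's fit, with masked summaries."""

    model: str
    r2_map: np.ndarray

    def mean_r2(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        vals = self.r2_map[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no valid fitted voxels inside mask")
        return float(vals.mean())


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its SD."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_presmooth(volume: DWIVolume, fwhm_mm: float = 3.0) -> DWIVolume:
    """Smooth each b-volume with a 3D isotropic (in mm) Gaussian filter.

    ``fwhm_mm`` is expressed in millimetres and converted to a per-axis
    sigma in voxels via the voxel spacing, so anisotropic grids are smoothed
    isotropically in physical space.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigma_vox = [sigma_mm / s for s in volume.spacing]
    out = np.empty_like(volume.data)
    for j in range(volume.data.shape[3]):
        ndimage.gaussian_filter(volume.data[..., j], sigma=sigma_vox,
                                output=out[..., j], mode="nearest")
    return DWIVolume(out, volume.scheme, volume.spacing)


def goodness_of_fit(observed, predicted) -> float:
    """Coefficient of determination R^2 = 1 - SS_res / SS_tot.

    A perfect fit returns exactly 1.  When the observed signal has zero
    variance, R^2 is defined as 1.0 if the residuals are (numerically) zero
    and NaN otherwise.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        scale = max(1.0, float(np.abs(obs).max()))
        return 1.0 if ss_res <= (1e-12 * scale) ** 2 * obs.size else float("nan")
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# model residual helpers (work on scaled diffusivities)

def _ivim_model(x, b):
    s0, d, f, ds = x[0], x[1] / _SCALE, x[2], x[3] / _SCALE
    return s0 * ((1 - f) * np.exp(-b * d) + f * np.exp(-b * ds))


def _ivim_jac(x, b):
    s0, d, f, ds = x[0], x[1] / _SCALE, x[2], x[3] / _SCALE
    e1, e2 = np.exp(-b * d), np.exp(-b * ds)
    return np.stack([
        (1 - f) * e1 + f * e2,
        s0 * (1 - f) * (-b) * e1 / _SCALE,
        s0 * (e2 - e1),
        s0 * f * (-b) * e2 / _SCALE,
    ], axis=1)


def _se_model(x, b):
    s0, ddc, alpha = x[0], x[1] / _SCALE, x[2]
    return s0 * np.exp(-np.power(b * ddc, alpha))


def _se_jac(x, b):
    s0, ddc, alpha = x[0], x[1] / _SCALE, x[2]
    bd = b * ddc
    u = np.power(bd, alpha)
    e = np.exp(-u)
    with np.errstate(divide="ignore"):
        logbd = np.where(bd > 0, np.log(np.where(bd > 0, bd, 1.0)), 0.0)
    du_dddc = np.where(bd > 0, alpha * u / np.maximum(ddc, 1e-300), 0.0)
    return np.stack([
        e,
        -s0 * e * du_dddc / _SCALE,
        -s0 * e * u * logbd,
    ], axis=1)


def _dki_model(x, b):
    s0, d, k = x[0], x[1] / _SCALE, x[2]
    bd = b * d
    expo = -bd + bd**2 * k / 6.0
    # beyond the turnover point b = 3/(D K) the quadratic exponent re-grows,
    # which is nonphysical; predictions plateau at the curve minimum there.
    if k > 0 and d > 0:
        expo = np.where(b > 3.0 / (d * k), -1.5 / k, expo)
    return s0 * np.exp(expo)


def _dki_jac(x, b):
    s0, d, k = x[0], x[1] / _SCALE, x[2]
    bd = b * d
    expo = -bd + bd**2 * k / 6.0
    if k > 0 and d > 0:
        plateau = b > 3.0 / (d * k)
        expo = np.where(plateau, -1.5 / k, expo)
    else:
        plateau = np.zeros_like(b, dtype=bool)
    m = s0 * np.exp(expo)
    de_dd = np.where(plateau, 0.0, -b + b**2 * d * k / 3.0)
    de_dk = np.where(plateau, 1.5 / max(k, 1e-300) ** 2, bd**2 / 6.0)
    return np.stack([m / s0, m * de_dd / _SCALE, m * de_dk], axis=1)


def _loglin(signals: np.ndarray, b: np.ndarray, order: int = 1):
    """Weighted log-linear fit ln S = c0 + c1 b (+ c2 b^2), vectorized.

    ``signals`` has shape (N, B).  Non-positive samples are clipped to a tiny
    positive floor before the log.  Returns coefficient array (N, order+1).
    """
    floor = 1e-12 * max(1.0, float(np.nanmax(signals, initial=1.0)))
    logs = np.log(np.clip(signals, floor, None))
    cols = [np.ones_like(b)] + [b**p for p in range(1, order + 1)]
    X = np.stack(cols, axis=1)  # (B, order+1)
    coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
    return coef.T  # (N, order+1)


def _polish(fun, x0, bounds, b, y, jac=None):
    res = least_squares(
        lambda x: fun(x, b) - y, x0=x0, bounds=bounds, method="trf",
        jac=(lambda x: jac(x, b)) if jac is not None else "2-point",
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=100,
    )
    return res.x


def _fit_me_array(signals, b):
    coef = _loglin(signals, b, order=1)
    s0 = np.exp(coef[:, 0])
    adc = np.clip(-coef[:, 1], 0.0, D_MAX)
    pred = s0[:, None] * np.exp(-b[None, :] * adc[:, None])
    return {"ADC": adc, "s0": s0}, pred, np.arange(len(b))


def _fit_dki_array(signals, b, polish=True):
    coef = _loglin(signals, b, order=2)
    s0 = np.exp(coef[:, 0])
    d = np.clip(-coef[:, 1], D_MIN, D_MAX)
    k = np.clip(6.0 * coef[:, 2] / d**2, 0.0, K_MAX)
    n = signals.shape[0]
    out_d = np.empty(n)
    out_k = np.empty(n)
    out_s0 = np.empty(n)
    pred = np.empty_like(signals)
    lb = [1e-12, D_MIN * _SCALE, 0.0]
    ub = [np.inf, D_MAX * _SCALE, K_MAX]
    for i in range(n):
        x0 = [max(s0[i], 1e-9), d[i] * _SCALE, k[i]]
        x0 = np.clip(x0, lb, ub)
        x = _polish(_dki_model, x0, (lb, ub), b, signals[i], _dki_jac) if polish else x0
        out_s0[i], out_d[i], out_k[i] = x[0], x[1] / _SCALE, x[2]
        pred[i] = _dki_model(x, b)
    return {"D": out_d, "K": out_k, "s0": out_s0}, pred, np.arange(len(b))


def _fit_se_array(signals, b, polish=True):
    coef = _loglin(signals, b, order=1)
    s0 = np.exp(coef[:, 0])
    ddc = np.clip(-coef[:, 1], D_MIN, D_MAX)
    n = signals.shape[0]
    out = {k: np.empty(n) for k in ("DDC", "alpha", "s0")}
    pred = np.empty_like(signals)
    lb = [1e-12, D_MIN * _SCALE, 1e-3]
    ub = [np.inf, D_MAX * _SCALE, 1.0]
    for i in range(n):
        x0 = np.clip([max(s0[i], 1e-9), ddc[i] * _SCALE, 0.9], lb, ub)
        x = _polish(_se_model, x0, (lb, ub), b, signals[i], _se_jac) if polish else x0
        out["s0"][i], out["DDC"][i], out["alpha"][i] = x[0], x[1] / _SCALE, x[2]
        pred[i] = _se_model(x, b)
    return out, pred, np.arange(len(b))


def _fit_ivim_array(signals, b, mode="segmented", b_max=IVIM_B_MAX):
    """IVIM fit. Modes: 'segmented' (two-step + joint polish, default),
    'segmented-raw' (pure two-step), 'full' (joint NLLS from generic init).

    Only samples with b <= b_max participate (see IVIM_B_MAX)."""
    if mode not in ("segmented", "segmented-raw", "full"):
        raise ValueError(f"unknown IVIM mode {mode!r}")
    cols = np.flatnonzero(b <= (b_max if b_max else np.inf))
    if len(cols) < 4:
        cols = np.arange(len(b))
    b = b[cols]
    signals = signals[:, cols]
    high = b >= 200.0
    if high.sum() < 2:
        high = b >= np.median(b)
    coef_hi = _loglin(signals[:, high], b[high], order=1)
    d0 = np.clip(-coef_hi[:, 1], D_MIN, D_MAX)
    a0 = np.exp(coef_hi[:, 0])  # ~ S0 * (1 - f)
    s0_meas = signals[:, 0]
    f0 = np.clip(1.0 - a0 / np.maximum(s0_meas, 1e-12), 0.0, 0.6)

    n = signals.shape[0]
    out = {k: np.empty(n) for k in ("D", "D*", "f", "s0")}
    pred = np.empty_like(signals)
    for i in range(n):
        d_i = d0[i]
        if mode in ("segmented", "segmented-raw"):
            # step 2: D fixed, fit (s0, f, D*)
            lb = [1e-12, 0.0, max(d_i, D_MIN) * _SCALE]
            ub = [np.inf, 1.0, DSTAR_MAX * _SCALE]
            x0 = np.clip(
                [max(s0_meas[i], 1e-9), f0[i], 10e-3 * _SCALE], lb, ub
            )
            fun = lambda x, bb, d=d_i: _ivim_model(
                [x[0], d * _SCALE, x[1], x[2]], bb
            )
            jac = lambda x, bb, d=d_i: _ivim_jac(
                [x[0], d * _SCALE, x[1], x[2]], bb
            )[:, [0, 2, 3]]
            x = _polish(fun, x0, (lb, ub), b, signals[i], jac)
            s0_i, f_i, ds_i = x[0], x[1], x[2] / _SCALE
        else:
            s0_i, f_i, ds_i = max(s0_meas[i], 1e-9), 0.1, 10e-3
        if mode in ("segmented", "full"):
            lb = [1e-12, D_MIN * _SCALE, 0.0, D_MIN * _SCALE]
            ub = [np.inf, D_MAX * _SCALE, 1.0, DSTAR_MAX * _SCALE]
            x0 = np.clip(
                [s0_i, d_i * _SCALE, f_i, max(ds_i, d_i) * _SCALE], lb, ub
            )
            x = _polish(_ivim_model, x0, (lb, ub), b, signals[i], _ivim_jac)
            s0_i, d_i, f_i, ds_i = x[0], x[1] / _SCALE, x[2], x[3] / _SCALE
        ds_i = max(ds_i, d_i)
        out["s0"][i], out["D"][i], out["f"][i], out["D*"][i] = (
            s0_i, d_i, f_i, ds_i,
        )
        pred[i] = _ivim_model([s0_i, d_i * _SCALE, f_i, ds_i * _SCALE], b)
    return out, pred, cols


_PARAM_CLASSES = {
    "me": (MEParams, ("ADC",)),
    "ivim": (IVIMParams, ("D", "D*", "f")),
    "se": (SEParams, ("DDC", "alpha")),
    "dki": (DKIParams, ("D", "K")),
}


def _fit_array(signals, b, model, ivim_mode="segmented",
               ivim_b_max=IVIM_B_MAX):
    if model == "me":
        return _fit_me_array(signals, b)
    if model == "ivim":
        return _fit_ivim_array(signals, b, mode=ivim_mode, b_max=ivim_b_max)
    if model == "se":
        return _fit_se_array(signals, b)
    if model == "dki":
        return _fit_dki_array(signals, b)
    raise ValueError(f"unknown model {model!r}")


def fit_voxel(signal, scheme: BValueScheme, model: str,
              b_subset: Sequence[float] | None = None,
              ivim_mode: str = "segmented"):
    """Fit one model to a single voxel's per-b signal vector.

    Returns ``(params, r2)`` where ``params`` is the matching parameter
    dataclass (MEParams, IVIMParams, SEParams or DKIParams).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size != len(scheme):
        raise ValueError("signal length must match the b-value scheme")
    b = scheme.asarray()
    if b_subset is not None:
        idx = scheme.subset_indices(b_subset)
        b, signal = b[idx], signal[idx]
    # free model parameters excluding the S0 scale; the scale plus these
    # must not exceed the number of samples (the two-point ME fit is exact).
    n_free = {"me": 1, "ivim": 3, "se": 2, "dki": 2}[model]
    if signal.size < n_free + 1:
        raise ValueError(
            f"need at least {n_free + 1} b-values to fit {model!r}"
        )
    if not np.isfinite(signal[0]) or signal[0] <= 0:
        raise ValueError("signal at b=0 must be positive")
    params, pred, cols = _fit_array(signal[None, :], b, model, ivim_mode)
    r2 = goodness_of_fit(signal[cols], pred[0])
    cls, names = _PARAM_CLASSES[model]
    kwargs = {
        {"ADC": "adc", "D": "d", "D*": "d_star", "f": "f",
         "DDC": "ddc", "alpha": "alpha", "K": "k"}[nm]: float(params[nm][0])
        for nm in names
    }
    return cls(**kwargs), float(r2)


def fit_volume(volume: DWIVolume, model: str,
               mask: np.ndarray | None = None,
               b_subset: Sequence[float] | None = None,
               ivim_mode: str = "segmented",
               ivim_b_max: float = IVIM_B_MAX):
    """Voxel-wise fit of one model inside ``mask``.

    Returns ``(maps, quality)``: a dict of ParameterMap keyed by map name and
    a FitQuality with the per-voxel R^2.  Voxels outside the mask, or with
    invalid (non-positive) b=0 signal, are NaN in every output.
    """
    b = volume.scheme.asarray()
    if b_subset is not None:
        idx = volume.scheme.subset_indices(b_subset)
    else:
        idx = np.arange(len(volume.scheme))
    b_fit = b[idx]
    if mask is None:
        mask = np.ones(volume.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape must match volume shape")

    sig = volume.data[mask][:, idx]  # (N, B)
    valid = np.isfinite(sig).all(axis=1) & (sig[:, 0] > 0)
    params, pred, cols = _fit_array(sig[valid], b_fit, model, ivim_mode,
                                    ivim_b_max)

    fitted = sig[valid][:, cols]
    ss_res = np.sum((fitted - pred) ** 2, axis=1)
    ss_tot = np.sum((fitted - fitted.mean(axis=1, keepdims=True)) ** 2,
                    axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot,
                      np.where(ss_res < 1e-20, 1.0, np.nan))

    def _to_map(vals_valid):
        flat = np.full(mask.sum(), np.nan)
        flat[valid] = vals_valid
        out = np.full(volume.shape, np.nan)
        out[mask] = flat
        return out

    model_label = {"me": "ME", "ivim": "BE_IVIM", "se": "SE", "dki": "DKI"}[model]
    name_map = {
        "me": {"ADC": "ADC_all-b"},
        "ivim": {"D": "D", "D*": "D*", "f": "f"},
        "se": {"DDC": "DDC", "alpha": "alpha"},
        "dki": {"D": "D_kurt", "K": "K"},
    }[model]
    maps = {}
    for key, map_name in name_map.items():
        maps[map_name] = ParameterMap(
            model=model_label, parameter=map_name,
            values=_to_map(params[key]), units=UNITS_OF_MAP[map_name],
        )
    quality = FitQuality(model=model_label, r2_map=_to_map(r2))
    return maps, quality


def generate_map_suite(volume: DWIVolume,
                       mask: np.ndarray | None = None,
                       fwhm_mm: float | None = 3.0,
                       ivim_mode: str = "segmented",
                       ivim_b_max: float = IVIM_B_MAX):
    """Produce the full nine-map suite plus per-model fit quality.

    Maps: ME ADC_all-b (all b), ME ADC_0-1000 (b = 0 and 1000 only),
    IVIM D / D* / f, SE DDC / alpha, DKI K / D_kurt.  ``fwhm_mm`` applies
    Gaussian pre-smoothing (None disables it).
    """
    if 1000.0 not in volume.scheme.values:
        raise ValueError("scheme must include b=1000 for the ADC_0-1000 map")
    work = gaussian_presmooth(volume, fwhm_mm) if fwhm_mm else volume
    maps: dict[str, ParameterMap] = {}
    quality: dict[str, FitQuality] = {}

    m, q = fit_volume(work, "me", mask)
    maps["ADC_all-b"] = m["ADC_all-b"]
    quality["ME"] = q

    m2, _ = fit_volume(work, "me", mask, b_subset=(0.0, 1000.0))
    pm = m2["ADC_all-b"]
    maps["ADC_0-1000"] = ParameterMap("ME", "ADC_0-1000", pm.values, pm.units)

    m, q = fit_volume(work, "ivim", mask, ivim_mode=ivim_mode,
                      ivim_b_max=ivim_b_max)
    maps.update(m)
    quality["BE_IVIM"] = q
    m, q = fit_volume(work, "se", mask)
    maps.update(m)
    quality["SE"] = q
    m, q = fit_volume(work, "dki", mask)
    maps.update(m)
    quality["DKI"] = q

    assert set(maps) == set(MAP_NAMES)
    return maps, quality


def qc_filter_lesion(quality: FitQuality, mask: np.ndarray,
                     threshold: float = 0.8) -> bool:
    """Lesion-level fit-quality gate.

    Returns True (keep) when the mean R^2 over the mask is >= ``threshold``;
    a lesion is excluded only when its mean R^2 is strictly below the
    threshold (0.80 exactly passes).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    return not (quality.mean_r2(mask) < threshold)
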