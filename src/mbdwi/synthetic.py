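"""Synthetic multi-b DWI phantoms and labeled cohorts.

The generator emulates, at desk scale, the statistical structure a breast
multi-b DWI study assumes: ellipsoidal lesions with irregular margins
embedded in a tissue "body", per-voxel ground-truth IVIM parameter fields
with intra-lesion spatial texture, class-conditional parameter distributions
(malignant lesions diffuse more slowly, perfuse more, and are more
heterogeneous than benign ones), and Rician magnitude noise at a target
signal-to-noise ratio.

Voxel signals are produced by the biexponential IVIM forward model from
per-voxel (D, D*, f) ground-truth fields.  The mixture of two exponentials
plus intra-lesion heterogeneity makes the stretched-exponential and kurtosis
fits well-posed, and yields the expected ordering (malignant: higher K,
lower alpha) as an emergent property of the lower D and higher f of the
malignant class rather than through an explicit kurtosis field.

Ground-truth parameter maps are returned with every phantom so fitting
recovery error is measurable voxel by voxel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .fitting import DWIVolume, ParameterMap
from .signal_models import BValueScheme

__all__ = [
    "ClassParams",
    "LesionPhantomSpec",
    "CohortSpec",
    "Subject",
    "MALIGNANT_DEFAULTS",
    "BENIGN_DEFAULTS",
    "make_lesion_phantom",
    "add_rician_noise",
    "make_cohort",
    "iter_cohort",
    "perturb_mask",
]


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional ground-truth parameter distributions.

    Means and SDs of the subject-level lesion parameters (diffusivities in
    mm^2/s) plus the relative SD of the intra-lesion spatial field
    (``heterogeneity``) and the boundary irregularity amplitude.
    """

    d_mean: float
    d_sd: float
    dstar_mean: float
    dstar_sd: float
    f_mean: float
    f_sd: float
    s0_mean: float
    s0_sd: float
    heterogeneity: float
    irregularity: float


#: Malignant lesions: slow, heterogeneous, well perfused.
MALIGNANT_DEFAULTS = ClassParams(
    d_mean=0.95e-3, d_sd=0.15e-3,
    dstar_mean=9e-3, dstar_sd=2e-3,
    f_mean=0.10, f_sd=0.03,
    s0_mean=500.0, s0_sd=50.0,
    heterogeneity=0.15, irregularity=0.15,
)

#: Benign lesions: faster diffusion, smoother texture.
BENIGN_DEFAULTS = ClassParams(
    d_mean=1.55e-3, d_sd=0.20e-3,
    dstar_mean=11e-3, dstar_sd=2e-3,
    f_mean=0.06, f_sd=0.02,
    s0_mean=450.0, s0_sd=50.0,
    heterogeneity=0.07, irregularity=0.05,
)

# Surrounding body tissue (single compartment, mildly heterogeneous).
_BODY = dict(d=2.1e-3, dstar=8e-3, f=0.03, s0=300.0, heterogeneity=0.05)


@dataclass(frozen=True)
class LesionPhantomSpec:
    """Geometry + parameter distributions for one phantom lesion."""

    label: str = "malignant"
    semi_axes_mm: tuple[float, float, float] = (6.0, 5.0, 4.0)
    irregularity: float | None = None  # None -> class default
    matrix: tuple[int, int, int] = (32, 32, 14)
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.5)
    correlation_mm: float = 3.0
    class_params: ClassParams | None = None

    def __post_init__(self):
        if self.label not in ("benign", "malignant"):
            raise ValueError("label must be 'benign' or 'malignant'")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        extent = [m * s for m, s in zip(self.matrix, self.spacing)]
        if any(2 * a >= e for a, e in zip(self.semi_axes_mm, extent)):
            raise ValueError("lesion larger than the matrix")

    def params(self) -> ClassParams:
        if self.class_params is not None:
            return self.class_params
        return MALIGNANT_DEFAULTS if self.label == "malignant" else BENIGN_DEFAULTS


@dataclass(frozen=True)
class CohortSpec:
    """A labeled phantom cohort: exact class counts, shared SNR and seed."""

    n_subjects: int = 542
    n_malignant: int = 333
    snr: float = 30.0
    seed: int = 0
    matrix: tuple[int, int, int] = (32, 32, 14)
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.5)
    malignant: ClassParams = MALIGNANT_DEFAULTS
    benign: ClassParams = BENIGN_DEFAULTS

    def __post_init__(self):
        if not 0 <= self.n_malignant <= self.n_subjects:
            raise ValueError("need 0 <= n_malignant <= n_subjects")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class Subject:
    """One simulated subject: noisy DWI, lesion mask, truth, label."""

    subject_id: str
    label: str
    volume: DWIVolume
    mask: np.ndarray
    truth: dict[str, ParameterMap]
    noise_sigma: float


def _correlated_field(rng, shape, spacing, correlation_mm):
    """Zero-mean, unit-SD Gaussian random field with ~Gaussian correlation."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(correlation_mm / s, 1e-6) / 2.0 for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _ellipsoid_mask(matrix, spacing, center_mm, semi_axes_mm,
                    irregularity=0.0, rng=None, correlation_mm=3.0):
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(matrix, spacing)],
        indexing="ij",
    )
    q = sum(((g - c) / a) ** 2
            for g, c, a in zip(grids, center_mm, semi_axes_mm))
    radius = np.ones(matrix)
    if irregularity > 0:
        if rng is None:
            raise ValueError("irregular boundary needs an RNG")
        radius = 1.0 + irregularity * _correlated_field(
            rng, matrix, spacing, correlation_mm)
    return q <= radius**2


def make_lesion_phantom(spec: LesionPhantomSpec, scheme: BValueScheme,
                        seed: int):
    """Build one noiseless phantom.

    Returns ``(volume, mask, truth)`` where ``truth`` maps
    {"D", "D*", "f", "S0"} to ground-truth ParameterMap objects (defined on
    the whole matrix: lesion and body carry their own values, air is NaN
    except S0 = 0).
    """
    rng = np.random.default_rng(seed)
    cp = spec.params()
    matrix, spacing = spec.matrix, spec.spacing
    extent = [m * s for m, s in zip(matrix, spacing)]
    center = [e / 2.0 for e in extent]

    irr = spec.irregularity if spec.irregularity is not None else cp.irregularity
    mask = _ellipsoid_mask(matrix, spacing, center, spec.semi_axes_mm,
                           irr, rng, spec.correlation_mm)
    if not mask.any():
        raise ValueError("lesion mask is empty")
    body = _ellipsoid_mask(
        matrix, spacing, center,
        [min(0.42 * e, a * 2.8 + 4.0) for e, a in zip(extent, spec.semi_axes_mm)],
    )
    body |= mask

    def lesion_field(mean, sd, rel_sd, lo, hi):
        base = rng.normal(mean, sd)
        fld = base * (1.0 + rel_sd * _correlated_field(
            rng, matrix, spacing, spec.correlation_mm))
        return np.clip(fld, lo, hi)

    d_les = lesion_field(cp.d_mean, cp.d_sd, cp.heterogeneity, 0.2e-3, 3.5e-3)
    f_les = lesion_field(cp.f_mean, cp.f_sd, cp.heterogeneity, 0.0, 0.4)
    ds_les = np.clip(
        lesion_field(cp.dstar_mean, cp.dstar_sd, cp.heterogeneity, 3e-3, 40e-3),
        d_les + 1e-4, None)
    s0_les = lesion_field(cp.s0_mean, cp.s0_sd, cp.heterogeneity / 2, 50.0, None)

    def body_field(mean, rel_sd, lo, hi):
        fld = mean * (1.0 + rel_sd * _correlated_field(
            rng, matrix, spacing, spec.correlation_mm))
        return np.clip(fld, lo, hi)

    d_map = np.full(matrix, np.nan)
    ds_map = np.full(matrix, np.nan)
    f_map = np.full(matrix, np.nan)
    s0_map = np.zeros(matrix)

    bg = body & ~mask
    d_map[bg] = body_field(_BODY["d"], _BODY["heterogeneity"], 0.2e-3, 3.5e-3)[bg]
    ds_map[bg] = body_field(_BODY["dstar"], _BODY["heterogeneity"], 3e-3, 40e-3)[bg]
    f_map[bg] = _BODY["f"]
    s0_map[bg] = body_field(_BODY["s0"], _BODY["heterogeneity"], 10.0, None)[bg]

    d_map[mask] = d_les[mask]
    ds_map[mask] = ds_les[mask]
    f_map[mask] = f_les[mask]
    s0_map[mask] = s0_les[mask]

    b = scheme.asarray()
    data = np.zeros(matrix + (len(b),))
    inside = body
    dv = d_map[inside][:, None]
    dsv = ds_map[inside][:, None]
    fv = f_map[inside][:, None]
    s0v = s0_map[inside][:, None]
    sig = s0v * ((1 - fv) * np.exp(-b[None, :] * dv)
                 + fv * np.exp(-b[None, :] * dsv))
    data[inside] = sig

    volume = DWIVolume(data, scheme, spacing)
    truth = {
        "D": ParameterMap("BE_IVIM", "D", d_map, "mm^2/s"),
        "D*": ParameterMap("BE_IVIM", "D*", ds_map, "mm^2/s"),
        "f": ParameterMap("BE_IVIM", "f", f_map, "1"),
        "S0": ParameterMap("BE_IVIM", "S0", s0_map, "a.u."),
    }
    return volume, mask, truth


def add_rician_noise(volume: DWIVolume, snr: float, seed: int,
                     mask: np.ndarray | None = None) -> DWIVolume:
    """Apply magnitude (Rician) noise at a target b=0 SNR.

    Each voxel value S is replaced by sqrt((S + n1)^2 + n2^2) with n1, n2
    independent zero-mean Gaussians of SD = (mean S_0 over ``mask``) / snr.
    In signal-free background this produces the Rayleigh floor of magnitude
    MRI.  Deterministic for a fixed seed.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    b0 = volume.volume_at(0.0)
    if mask is not None:
        ref = float(b0[np.asarray(mask, dtype=bool)].mean())
    else:
        nz = b0[b0 > 0]
        ref = float(nz.mean()) if nz.size else float(b0.mean())
    sigma = ref / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, volume.data.shape)
    n2 = rng.normal(0.0, sigma, volume.data.shape)
    noisy = np.sqrt((volume.data + n1) ** 2 + n2**2)
    return DWIVolume(noisy, volume.scheme, volume.spacing)


def _subject_specs(spec: CohortSpec, scheme: BValueScheme):
    rng = np.random.default_rng(spec.seed)
    labels = np.array(
        ["malignant"] * spec.n_malignant
        + ["benign"] * (spec.n_subjects - spec.n_malignant)
    )
    rng.shuffle(labels)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    for i, (label, ss) in enumerate(zip(labels, seeds)):
        srng = np.random.default_rng(ss)
        axes = (
            float(srng.uniform(4.0, 9.0)),
            float(srng.uniform(4.0, 9.0)),
            float(srng.uniform(3.5, 6.0)),
        )
        cp = spec.malignant if label == "malignant" else spec.benign
        lspec = LesionPhantomSpec(
            label=label, semi_axes_mm=axes, matrix=spec.matrix,
            spacing=spec.spacing, class_params=cp,
        )
        phantom_seed = int(srng.integers(0, 2**31 - 1))
        noise_seed = int(srng.integers(0, 2**31 - 1))
        yield f"sub-{i:04d}", label, lspec, phantom_seed, noise_seed


def iter_cohort(spec: CohortSpec,
                scheme: BValueScheme | None = None) -> Iterator[Subject]:
    """Lazily generate the cohort (exact class counts, seeded)."""
    scheme = scheme or BValueScheme()
    for sid, label, lspec, pseed, nseed in _subject_specs(spec, scheme):
        vol, mask, truth = make_lesion_phantom(lspec, scheme, pseed)
        sigma = float(vol.volume_at(0.0)[mask].mean()) / spec.snr
        noisy = add_rician_noise(vol, spec.snr, nseed, mask=mask)
        yield Subject(sid, label, noisy, mask, truth, sigma)


def make_cohort(spec: CohortSpec,
                scheme: BValueScheme | None = None) -> list[Subject]:
    """Materialize the full cohort as a list of Subject objects."""
    return list(iter_cohort(spec, scheme))


def perturb_mask(mask: np.ndarray, magnitude_mm: float = 1.0,
                 seed: int = 0,
                 spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Morphologically jitter a mask to emulate a second reader's contour.

    The mask boundary is moved by a spatially correlated random offset of
    amplitude ``magnitude_mm`` applied to the signed Euclidean distance
    transform.  magnitude 0 returns the mask unchanged; the default keeps
    Dice overlap with the original >= 0.8 on typical lesion sizes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if magnitude_mm < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude_mm == 0:
        return mask.copy()
    spacing = tuple(float(s) for s in spacing)
    dist_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    dist_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    signed = dist_out - dist_in  # positive outside the mask
    rng = np.random.default_rng(seed)
    field = _correlated_field(rng, mask.shape, spacing, 4.0)
    out = (signed + magnitude_mm * field) <= 0
    if not out.any():
        raise ValueError("perturbation emptied the mask")
    return out
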