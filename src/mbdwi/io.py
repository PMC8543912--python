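"""File I/O: NIfTI volumes, FSL-style bval sidecars, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import DWIVolume, ParameterMap
from .signal_models import BValueScheme

__all__ = [
    "save_dwi",
    "load_dwi",
    "save_mask",
    "load_mask",
    "save_map",
    "load_map",
    "read_bvals",
    "write_bvals",
]


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def write_bvals(path, scheme: BValueScheme) -> None:
    """One b-value per line (FSL bval dialect, column layout)."""
    Path(path).write_text("\n".join(f"{v:g}" for v in scheme.values) + "\n")


def read_bvals(path) -> BValueScheme:
    text = Path(path).read_text().split()
    return BValueScheme(tuple(float(v) for v in text))


def save_dwi(volume: DWIVolume, prefix) -> None:
    """Write <prefix>.nii.gz plus <prefix>.bval."""
    prefix = Path(prefix)
    img = nib.Nifti1Image(volume.data.astype(np.float32),
                          _affine(volume.spacing))
    img.header.set_zooms(tuple(volume.spacing) + (1.0,))
    nib.save(img, str(prefix) + ".nii.gz")
    write_bvals(str(prefix) + ".bval", volume.scheme)


def load_dwi(prefix) -> DWIVolume:
    prefix = Path(prefix)
    img = nib.load(str(prefix) + ".nii.gz")
    scheme = read_bvals(str(prefix) + ".bval")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DWIVolume(np.asarray(img.dataobj, dtype=float), scheme, spacing)


def save_mask(mask: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_map(pmap: ParameterMap, spacing, path) -> None:
    """Write the map as NIfTI plus a JSON sidecar with model/units."""
    path = Path(path)
    img = nib.Nifti1Image(pmap.values.astype(np.float32), _affine(spacing))
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"model": pmap.model, "parameter": pmap.parameter,
         "units": pmap.units}, indent=2))


def load_map(path) -> ParameterMap:
    path = Path(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    values = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return ParameterMap(meta["model"], meta["parameter"], values,
                        meta["units"])
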