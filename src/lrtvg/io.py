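"""NIfTI I/O for volumes, masks and assembled spectra.

Volumes are written as NIfTI-1 at 64-bit float with a 1 mm isotropic
affine on the high-resolution grid; low-resolution observations record
their beta-mm through-slice spacing in the affine.  An assembled
spectrum is serialized as a real/imaginary pair of NIfTI volumes plus a
binary Omega mask.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core_ops import is_conjugate_symmetric
from .phantom_sim import AssembledSpectrum

logger = logging.getLogger("lrtvg")

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_spectrum",
    "write_spectrum",
    "write_diagnostics",
]


def write_volume(
    v: np.ndarray, path: str | Path, voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> None:
    v = np.asarray(v, dtype=np.float64)
    if v.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {v.ndim}D")
    affine = np.diag(list(voxel_sizes) + [1.0])
    nib.save(nib.Nifti1Image(v, affine), str(path))


def read_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    return data


def read_mask(path: str | Path) -> np.ndarray:
    data = read_volume(path)
    values = np.unique(data)
    if not set(values).issubset({0.0, 1.0}):
        raise ValueError(
            f"{path}: mask must contain only 0/1, found values {values[:5]}"
        )
    return data.astype(np.uint8)


def write_spectrum(s: AssembledSpectrum, prefix: str | Path) -> None:
    """Write <prefix>_real.nii.gz, <prefix>_imag.nii.gz, <prefix>_omega.nii.gz."""
    prefix = str(prefix)
    write_volume(s.f0_prime.real, prefix + "_real.nii.gz")
    write_volume(s.f0_prime.imag, prefix + "_imag.nii.gz")
    write_volume(s.omega.astype(np.float64), prefix + "_omega.nii.gz")


def read_spectrum(prefix: str | Path) -> AssembledSpectrum:
    prefix = str(prefix)
    re = read_volume(prefix + "_real.nii.gz")
    im = read_volume(prefix + "_imag.nii.gz")
    omega = read_mask(prefix + "_omega.nii.gz").astype(bool)
    if not (re.shape == im.shape == omega.shape):
        raise ValueError(
            f"spectrum triple shape mismatch: {re.shape}, {im.shape}, {omega.shape}"
        )
    f0 = re + 1j * im
    if not is_conjugate_symmetric(f0, rtol=1e-6):
        warnings.warn(
            "spectrum is not conjugate-symmetric to 1e-6; reconstructions "
            "of real images may be inconsistent",
            stacklevel=2,
        )
    return AssembledSpectrum(f0_prime=f0, omega=omega,
                             profile_spectrum=np.ones_like(re))


def write_diagnostics(diag: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(diag, indent=2, default=_default))
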