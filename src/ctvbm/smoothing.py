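"""Isotropic Gaussian smoothing of normalized gray-matter maps.

Smoothing a binary-ish gray-matter probability map with a wide kernel turns
it into a regional gray-matter *density*: each voxel becomes a weighted
average of the gray matter in its neighbourhood, so group differences in
the smoothed maps read as regional volume differences.  The conventional
kernel width for whole-brain morphometry is 12 mm FWHM.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume_io import Volume3D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """sigma = FWHM / (2 sqrt(2 ln 2)) ~= FWHM / 2.35482."""
    return float(fwhm_mm) * FWHM_TO_SIGMA


def smooth_gaussian(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Separable Gaussian smoothing with an isotropic world-space FWHM.

    The kernel sigma is converted to voxel units per axis, the kernel is
    truncated at 4 sigma, and the boundary is zero-padded — consistent with
    gray-matter maps that are zero outside the head.  A FWHM below half a
    voxel is below the sampling resolution: a warning is raised and an
    unsmoothed copy returned.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    voxel = vol.voxel_size_mm
    if fwhm_mm < 0.5 * float(np.min(voxel)):
        warnings.warn(
            f"FWHM {fwhm_mm} mm is below half a voxel ({voxel} mm); "
            "returning an unsmoothed copy", RuntimeWarning, stacklevel=2)
        return vol.copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel
    out = ndimage.gaussian_filter(
        np.asarray(vol.data, dtype=float), sigma=sigma_vox,
        mode="constant", cval=0.0, truncate=4.0)
    modality = vol.modality
    if modality == "probability":
        out = np.clip(out, 0.0, 1.0)
    return Volume3D(out, vol.affine.copy(), modality)
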