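"""CT brain extraction and grid matching.

CT heads carry structures a mixture segmenter must never see: the skull
(~1000 HU), the scanner head holder (a detached soft-tissue-density slab),
and surrounding air (-1000 HU).  Brain parenchyma and CSF occupy a narrow
soft-tissue band (roughly 0-60 HU), so a Hounsfield window plus
connected-component morphology isolates the brain reliably: the skull is
outside the window and therefore severs the brain from scalp soft tissue,
and the head holder is a separate component discarded by the
largest-component rule.

The second stage resamples the stripped volume onto the tissue-prior grid
(bounding box and voxel size of the atlas) after a rough world-space
initialisation, so that segmentation priors and data are co-registered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import NoBrainTissueError
from .volume_io import GridSpec, Volume3D, resample_to_grid


@dataclass(frozen=True)
class CtWindow:
    """Hounsfield bounds for soft-tissue candidacy and bone exclusion.

    Candidacy is ``lo_hu < HU <= hi_hu``; the lower bound is strict so that
    the background fill value written by :func:`extract_brain_ct` (``lo_hu``)
    is itself never a candidate, which makes the extraction idempotent.
    """

    lo_hu: float = 0.0
    hi_hu: float = 100.0
    bone_hu: float = 300.0

    def __post_init__(self) -> None:
        if not (self.lo_hu < self.hi_hu < self.bone_hu):
            raise ValueError(
                f"require lo_hu < hi_hu < bone_hu, got "
                f"({self.lo_hu}, {self.hi_hu}, {self.bone_hu})"
            )


@dataclass
class BrainMask:
    """Boolean brain support on the source grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


_CONN6 = ndimage.generate_binary_structure(3, 1)


def _ball(radius_mm: float, voxel_size_mm: np.ndarray) -> np.ndarray:
    """Ellipsoidal structuring element of the given world radius."""
    r_vox = np.maximum(np.round(radius_mm / voxel_size_mm).astype(int), 0)
    if np.all(r_vox == 0):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in r_vox)]
    dist = sum(
        (g / max(r, 1)) ** 2 for g, r in zip(grids, r_vox)
    )
    return dist <= 1.0


def extract_brain_ct(
    vol: Volume3D,
    window: CtWindow | None = None,
    close_radius_mm: float = 4.0,
) -> tuple[BrainMask, Volume3D]:
    """Strip skull, head holder, and air from a CT head volume.

    Soft-tissue candidates (``lo_hu < HU <= hi_hu``) are labelled with
    6-connectivity; the largest component — the brain, cut off from scalp
    by the out-of-window skull — is kept, then morphologically closed
    (radius ``close_radius_mm``) and hole-filled so thin CSF clefts and
    noise speckle do not perforate the mask.  The returned volume equals
    the input inside the mask and ``lo_hu`` outside.
    """
    if vol.modality != "ct":
        raise ValueError(f"extract_brain_ct requires a CT volume, got {vol.modality!r}")
    window = window or CtWindow()
    data = np.asarray(vol.data, dtype=float)
    cand = (data > window.lo_hu) & (data <= window.hi_hu)
    if not cand.any():
        raise NoBrainTissueError(
            f"no brain tissue found in window ({window.lo_hu}, {window.hi_hu}] HU"
        )
    labels, n = ndimage.label(cand, structure=_CONN6)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
    else:
        mask = cand
    if close_radius_mm > 0:
        struct = _ball(close_radius_mm, vol.voxel_size_mm)
        mask = ndimage.binary_closing(mask, structure=struct)
    mask = ndimage.binary_fill_holes(mask)
    # closing can merge shards; keep a single component
    labels, n = ndimage.label(mask, structure=_CONN6)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
    out = np.where(mask, data, window.lo_hu)
    return BrainMask(mask), Volume3D(out, vol.affine.copy(), "ct")


def _center_of_mass_world(vol: Volume3D) -> np.ndarray:
    """Intensity-weighted centroid in world mm.

    For CT the weight is the positive part of the image (air at -1000 HU
    would otherwise dominate the moment); for other modalities raw
    non-negative intensity is used.
    """
    data = np.asarray(vol.data, dtype=float)
    w = np.clip(data, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot compute centre of mass of a non-positive volume")
    com_vox = np.array(ndimage.center_of_mass(w))
    return vol.grid.voxel_to_world(com_vox)


def com_init_affine(vol: Volume3D, atlas_grid: GridSpec) -> np.ndarray:
    """Translation mapping the volume's intensity centroid to the atlas grid
    centre (the default rough initialisation for grid matching)."""
    com = _center_of_mass_world(vol)
    center_vox = (np.asarray(atlas_grid.shape) - 1) / 2.0
    center_world = atlas_grid.voxel_to_world(center_vox)
    init_affine = np.eye(4)
    init_affine[:3, 3] = center_world - com
    return init_affine


def match_prior_grid(
    vol: Volume3D,
    atlas_grid: GridSpec,
    init_affine: np.ndarray | None = None,
) -> Volume3D:
    """Resample a subject volume onto the tissue-prior grid.

    ``init_affine`` maps subject world coordinates into atlas world
    coordinates; when omitted, a translation aligning the subject's
    intensity centroid with the atlas grid centre is used.  The output has
    exactly the atlas grid's shape and affine.
    """
    if init_affine is None:
        init_affine = com_init_affine(vol, atlas_grid)
    init_affine = np.asarray(init_affine, dtype=float)
    moved = Volume3D(vol.data, init_affine @ vol.affine, vol.modality)
    interp = "nearest" if vol.modality == "label" else "trilinear"
    fill = 0.0
    return resample_to_grid(moved, atlas_grid, interp=interp, fill=fill)
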