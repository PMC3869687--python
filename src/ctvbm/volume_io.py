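"""NIfTI-1 volume I/O, grid specifications, and world-space resampling.

One coordinate convention is used everywhere in this package: voxel indices
are 0-based, the world frame is RAS with coordinates in millimetres, and the
``affine`` of a volume maps voxel index ``(i, j, k, 1)`` to world position
``(x, y, z, 1)``.  Every module boundary exchanges world coordinates in mm.

Volumes are carried as :class:`Volume3D` (data + affine + modality tag) and
target sampling grids as :class:`GridSpec`.  Resampling is always performed
in world space, so volumes on different grids compose correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionalityError, FormatError

MODALITIES = ("ct", "mr", "probability", "label")

_DESCRIP_PREFIX = "ctvbm:"


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass(frozen=True)
class GridSpec:
    """A 3-D sampling grid: array shape plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", _check_affine(self.affine))

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def fov_mm(self) -> np.ndarray:
        """Field of view extents in mm along each voxel axis."""
        return self.voxel_size_mm * np.asarray(self.shape)

    @classmethod
    def isotropic(cls, shape, voxel_mm: float) -> "GridSpec":
        """A centred RAS-aligned grid with isotropic voxels.

        World origin sits at the grid centre, which keeps phantom geometry
        definitions (ellipsoids about 0) independent of the grid size.
        """
        shape = tuple(int(s) for s in shape)
        affine = np.eye(4)
        affine[:3, :3] *= float(voxel_mm)
        affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * float(voxel_mm)
        return cls(shape, affine)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to (..., 3) world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class Volume3D:
    """A 3-D scalar volume with voxel-to-world affine and modality tag.

    ``modality`` is one of ``ct`` (Hounsfield units), ``mr`` (arbitrary
    units), ``probability`` (values in [0, 1]) or ``label`` (integer codes).
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "mr"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {data.ndim} dimensions"
            )
        self.affine = _check_affine(self.affine)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "probability":
            lo, hi = float(np.min(data)), float(np.max(data))
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ValueError(
                    f"probability volume out of [0, 1]: range [{lo}, {hi}]"
                )
            data = np.clip(data, 0.0, 1.0)
        self.data = data

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.affine)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return self.grid.voxel_size_mm

    def copy(self) -> "Volume3D":
        return Volume3D(self.data.copy(), self.affine.copy(), self.modality)


def read_volume(path, modality: str | None = None) -> Volume3D:
    """Read a 3-D NIfTI-1 volume, reoriented to RAS.

    The modality tag is recovered from the header description if the file
    was written by :func:`write_volume`; otherwise ``modality`` (default
    ``mr``) is used.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected 3 spatial dimensions, got shape {img.shape}"
        )
    img = nib.as_closest_canonical(img)
    if modality is None:
        descrip = ""
        try:
            descrip = img.header["descrip"].tobytes().decode("ascii", "ignore")
        except Exception:
            pass
        descrip = descrip.rstrip("\x00")
        if descrip.startswith(_DESCRIP_PREFIX):
            tag = descrip[len(_DESCRIP_PREFIX):].strip()
            modality = tag if tag in MODALITIES else "mr"
        else:
            modality = "mr"
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64)
    return Volume3D(data, img.affine, modality)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1, embedding the modality tag in the header.

    Float data is stored as float64 so that write/read round-trips are
    bit-exact; label volumes are stored as int32.
    """
    data = vol.data
    if vol.modality == "label" or np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    img = nib.Nifti1Image(data, vol.affine)
    img.set_data_dtype(data.dtype)
    img.header["descrip"] = f"{_DESCRIP_PREFIX}{vol.modality}".encode("ascii")
    nib.save(img, str(path))


def resample_to_grid(
    vol: Volume3D,
    grid: GridSpec,
    interp: str = "trilinear",
    fill: float = 0.0,
) -> Volume3D:
    """Resample a volume onto a target grid in world space.

    Each output voxel centre is mapped through ``grid.affine`` to world mm,
    then through the inverse of ``vol.affine`` into source voxel space, and
    the source is interpolated there (``trilinear`` or ``nearest``).  Output
    voxels falling outside the source field of view receive ``fill``.
    """
    if interp not in ("nearest", "trilinear"):
        raise ValueError(f"interp must be 'nearest' or 'trilinear', got {interp!r}")
    order = 0 if interp == "nearest" else 1
    # output voxel -> source voxel map
    M = np.linalg.inv(vol.affine) @ grid.affine
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float),
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=grid.shape,
        order=order,
        mode="constant",
        cval=float(fill),
        prefilter=False,
    )
    if vol.modality == "label":
        out = np.round(out).astype(vol.data.dtype)
    if vol.modality == "probability":
        out = np.clip(out, 0.0, 1.0)
    return Volume3D(out, grid.affine, vol.modality)
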