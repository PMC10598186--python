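"""NIfTI volume and mask I/O with geometry contracts.

All images are reoriented at load time to a canonical RAS+ voxel order
(increasing index -> patient Right / Anterior / Superior) so that the
left/right and superior/inferior conventions used by the lobe classifier
and trachea finder are fixed. Downstream geometry is expressed in world
millimetres: ``world = origin + index * spacing``.

Masks are required to be strictly co-registered with their CT (same grid
shape and spacing); no resampling is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "apply_display_window",
]

#: Standard lung display window (HU), centre and full width.
DEFAULT_WINDOW_LEVEL = -500.0
DEFAULT_WINDOW_WIDTH = 1500.0


@dataclass
class ImageVolume:
    """A 3D scalar image in Hounsfield units on a regular grid.

    Attributes
    ----------
    data : np.ndarray
        3D array of HU values, canonical RAS+ axis order.
    spacing : tuple of float
        Voxel edge lengths (sx, sy, sz) in mm; all positive.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    axis_codes : tuple of str
        Anatomical orientation labels, ('R', 'A', 'S') after load.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values (NaN/Inf)")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to world mm, shape (..., 3)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Map world mm to (fractional) voxel indices, shape (..., 3)."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff


@dataclass
class BinaryMask:
    """A {0,1} mask on the same grid as its paired :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_codes: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if not self.data.any():
            raise ValueError("mask contains no foreground voxels")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    index_to_world = ImageVolume.index_to_world
    world_to_index = ImageVolume.world_to_index
    affine = ImageVolume.affine


def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    codes = tuple(nib.aff2axcodes(img.affine))
    return data, zooms, origin, codes


def load_volume(path: str | Path) -> ImageVolume:
    """Load a CT volume from NIfTI, reoriented to RAS+; HU values untouched."""
    data, spacing, origin, codes = _load_canonical(path)
    return ImageVolume(data=data, spacing=spacing, origin=origin, axis_codes=codes)


def load_mask(path: str | Path, reference: ImageVolume, atol_mm: float = 1e-3) -> BinaryMask:
    """Load an airway mask and check it is voxel-aligned to ``reference``.

    Any nonzero voxel maps to 1. Raises if the grid shape or spacing
    disagrees with the reference beyond ``atol_mm``.
    """
    data, spacing, origin, codes = _load_canonical(path)
    if data.shape != reference.shape:
        raise ValueError(
            f"mask grid {data.shape} does not match reference grid {reference.shape}"
        )
    if not np.allclose(spacing, reference.spacing, atol=atol_mm):
        raise ValueError(
            f"mask spacing {spacing} does not match reference spacing "
            f"{reference.spacing} within {atol_mm} mm"
        )
    return BinaryMask(data=data, spacing=spacing, origin=origin, axis_codes=codes)


def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI with a diagonal RAS+ affine."""
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def apply_display_window(
    volume: ImageVolume | np.ndarray,
    level: float = DEFAULT_WINDOW_LEVEL,
    width: float = DEFAULT_WINDOW_WIDTH,
) -> np.ndarray:
    """Linearly rescale HU to [0, 1] under a display window.

    Values at or below ``level - width/2`` map to 0, at or above
    ``level + width/2`` to 1. Defaults are the standard lung window
    (level -500 HU, width 1500 HU).
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    lo = level - width / 2.0
    return np.clip((data - lo) / width, 0.0, 1.0)
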