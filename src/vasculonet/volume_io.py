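"""3D volume and mask containers with physical geometry, TIFF I/O and cropping.

Axis convention: arrays are indexed ``values[i, j, k]`` = (x, y, z) with z the
slice (TIFF page) index.  The world coordinate of the center of voxel
(i, j, k) is ``origin + voxel_size * (i, j, k)`` in μm.  Only isotropic voxels
are supported; coordinates are 0-based throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


class FormatError(ValueError):
    """Raised for malformed or inconsistent image input."""


@dataclass
class _Grid:
    values: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if min(self.values.shape) < 1:
            raise ValueError("all shape entries must be >= 1")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (μm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world(self, index) -> np.ndarray:
        """World coordinate (μm) of a voxel-center index triple."""
        return self.origin + self.voxel_size * np.asarray(index, dtype=float)

    def index(self, position) -> np.ndarray:
        """Nearest voxel index for a world position (μm); may lie outside."""
        return np.rint((np.asarray(position, dtype=float) - self.origin)
                       / self.voxel_size).astype(int)

    def same_geometry(self, other: "_Grid") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.voxel_size, other.voxel_size)
                and np.allclose(self.origin, other.origin))


@dataclass
class VolumeImage(_Grid):
    """3D scalar intensity grid with isotropic voxel size in μm."""

    def __post_init__(self):
        super().__post_init__()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")


@dataclass
class BinaryMask(_Grid):
    """3D boolean grid sharing VolumeImage geometry."""

    def __post_init__(self):
        super().__post_init__()
        if self.values.dtype != bool:
            self.values = self.values.astype(bool)

    @property
    def count(self) -> int:
        return int(self.values.sum())


def read_stack(path, voxel_size: float) -> VolumeImage:
    """Read a multi-page TIFF (or a directory of single-page TIFFs in
    lexicographic z-order) into a :class:`VolumeImage`.

    Pages are stored as (row, col) = (y, x); they are transposed so the array
    is indexed (x, y, z) with z = page index.
    """
    if os.path.isdir(path):
        pages = []
        names = sorted(f for f in os.listdir(path)
                       if f.lower().endswith((".tif", ".tiff")))
        if not names:
            raise FormatError(f"no TIFF pages found in directory {path!r}")
        for name in names:
            page = tifffile.imread(os.path.join(path, name))
            if page.ndim != 2:
                raise FormatError(f"{name}: expected single-page 2D TIFF")
            pages.append(page)
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise FormatError(f"inconsistent page dimensions: {sorted(shapes)}")
        data = np.stack(pages, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise FormatError(f"expected a 3D TIFF stack, got ndim={data.ndim}")
        if data.size == 0:
            raise FormatError("empty TIFF stack")
    # pages arrive as (z, y, x) -> (x, y, z)
    return VolumeImage(np.ascontiguousarray(data.transpose(2, 1, 0)), voxel_size)


def read_mask(path, voxel_size: float, threshold: float = 0.5) -> BinaryMask:
    """Read a TIFF stack as a binary mask (any value > threshold is on)."""
    vol = read_stack(path, voxel_size)
    return BinaryMask(vol.values > threshold, voxel_size, vol.origin)


def write_stack(vol: VolumeImage | BinaryMask, path) -> None:
    """Write a volume or mask as a multi-page grayscale TIFF.

    Masks are written as 0/255 8-bit for compatibility with external viewers.
    """
    data = vol.values
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(path, np.ascontiguousarray(data.transpose(2, 1, 0)),
                     photometric="minisblack")


def crop_block(vol, origin_voxel, size_voxels):
    """Crop a block; the physical origin shifts so world coordinates of the
    retained voxels are unchanged.

    Raises IndexError if the block extends outside the volume.
    """
    o = np.asarray(origin_voxel, dtype=int)
    s = np.asarray(size_voxels, dtype=int)
    if np.any(o < 0) or np.any(s < 1) or np.any(o + s > vol.shape):
        raise IndexError(
            f"block origin={tuple(o)} size={tuple(s)} outside volume {vol.shape}")
    sub = vol.values[o[0]:o[0] + s[0], o[1]:o[1] + s[1], o[2]:o[2] + s[2]].copy()
    return replace(vol, values=sub, origin=vol.origin + vol.voxel_size * o)
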