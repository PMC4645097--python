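"""Grayscale volume → single connected, lumen-filled binary vessel network.

The three stages mirror how intraluminally stained vasculature is extracted:

1. :func:`local_threshold` — adaptive binarisation against the local mean,
   robust to uneven illumination across a large volume;
2. :func:`fill_lumina` — "insideness" gap closing: a background voxel is
   converted when a sufficient fraction of rays cast from it hit vessel
   material within a search radius, so wall shells with staining gaps are
   filled into solid lumina;
3. :func:`largest_component` — keep the single largest connected network.
"""

from __future__ import annotations

import json
import math
import warnings

import numpy as np
from scipy import ndimage

from .volume_io import VolumeImage, BinaryMask

#: fill_lumina settings for closing staining gaps in hollow vessel walls:
#: a fine direction set and a threshold low enough that wall punctures close
#: progressively from their rim, yet above the ~0.5 insideness of background
#: voxels resting on an intact surface (which would otherwise dilate).
GAP_FILL_PARAMS = {"max_radius": 20.0, "n_rays": 66, "inside_fraction": 0.60}

#: 26 voxel-neighbour directions (all nonzero offsets in {-1,0,1}^3)
NEIGHBOUR_DIRECTIONS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)], dtype=float)


def local_threshold(vol: VolumeImage, window_radius: int = 25,
                    offset: float = 10.0) -> BinaryMask:
    """Binarise: voxel on iff intensity > local mean + offset.

    The local mean is taken over a cubic window of half-width
    ``window_radius`` voxels, truncated at the volume borders (the mean is
    over the voxels actually inside the volume).
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    size = 2 * int(window_radius) + 1
    vals = vol.values.astype(np.float64)
    # truncated-window mean: sum with zero padding / count of in-volume voxels
    s = ndimage.uniform_filter(vals, size=size, mode="constant", cval=0.0)
    c = ndimage.uniform_filter(np.ones_like(vals), size=size,
                               mode="constant", cval=0.0)
    local_mean = s / np.maximum(c, 1e-12)
    return BinaryMask(vals > local_mean + offset, vol.voxel_size, vol.origin)


def _shifted_or(dst: np.ndarray, src: np.ndarray, off) -> None:
    """dst |= src shifted by integer offset ``off`` (zero padding)."""
    slc_d, slc_s = [], []
    for o, n in zip(off, src.shape):
        if o >= 0:
            slc_d.append(slice(0, n - o))
            slc_s.append(slice(o, n))
        else:
            slc_d.append(slice(-o, n))
            slc_s.append(slice(0, n + o))
    if all(s.stop > s.start for s in slc_d):
        dst[tuple(slc_d)] |= src[tuple(slc_s)]


def ray_directions(n_rays: int) -> np.ndarray:
    """A deterministic, approximately uniform set of directions on the sphere.

    ``n_rays == 26`` uses the voxel-neighbour directions; otherwise a
    Fibonacci sphere.
    """
    if n_rays == 26:
        return NEIGHBOUR_DIRECTIONS / np.linalg.norm(
            NEIGHBOUR_DIRECTIONS, axis=1, keepdims=True)
    i = np.arange(n_rays)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_rays
    r = np.sqrt(1.0 - z * z)
    theta = golden * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def insideness(mask: BinaryMask, max_radius: float, n_rays: int = 26) -> np.ndarray:
    """Fraction of rays from each voxel that hit an on-voxel within
    ``max_radius`` μm.  Rays step voxel-by-voxel along a fixed direction set;
    a hit at any step counts the ray once."""
    vox = mask.voxel_size
    # work on the bounding box of the structure, inflated by the reach
    reach = int(math.ceil(max_radius / vox)) + 1
    on = np.argwhere(mask.values)
    if len(on) == 0:
        return np.zeros(mask.shape)
    lo = np.maximum(on.min(axis=0) - reach, 0)
    hi = np.minimum(on.max(axis=0) + reach + 1, mask.shape)
    sub = mask.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    frac = np.zeros(mask.shape)
    frac[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = _insideness_dense(
        sub, vox, max_radius, n_rays)
    return frac


def _insideness_dense(values: np.ndarray, vox: float, max_radius: float,
                      n_rays: int) -> np.ndarray:
    dirs = ray_directions(n_rays)
    hits = np.zeros(values.shape, dtype=np.uint16)
    # steps at half-voxel spacing, deduplicated to integer voxel offsets
    n_steps = int(math.ceil(2.0 * max_radius / vox))
    ts = (np.arange(1, n_steps + 1) * 0.5) * vox
    ts = ts[ts <= max_radius]
    for d in dirs:
        offs = np.unique(np.rint(np.outer(ts, d) / vox).astype(int), axis=0)
        offs = offs[np.any(offs != 0, axis=1)]
        hit_d = np.zeros(values.shape, bool)
        for off in offs:
            _shifted_or(hit_d, values, off)
        hits += hit_d
    return hits / float(len(dirs))


def fill_lumina(mask: BinaryMask, max_radius: float = 45.0, n_rays: int = 26,
                inside_fraction: float = 0.85, max_iter: int = 10) -> BinaryMask:
    """Insideness-based lumen filling.

    Background voxels whose insideness (fraction of rays hitting vessel
    material within ``max_radius`` μm) reaches ``inside_fraction`` are
    converted to foreground.  Applied iteratively to a fixpoint (converted
    voxels support further conversions), capped at ``max_iter`` passes.
    The output is always a superset of the input.
    """
    if max_radius < mask.voxel_size:
        raise ValueError("max_radius must be >= voxel_size")
    if n_rays < 6:
        raise ValueError("n_rays must be >= 6")
    if not (0 < inside_fraction <= 1):
        raise ValueError("inside_fraction must be in (0, 1]")
    current = mask
    for _ in range(max_iter):
        frac = insideness(current, max_radius, n_rays)
        grown = current.values | (frac >= inside_fraction - 1e-12)
        if np.array_equal(grown, current.values):
            break
        current = BinaryMask(grown, mask.voxel_size, mask.origin)
    return BinaryMask(current.values | mask.values, mask.voxel_size, mask.origin)


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the connected component with the most voxels.

    Ties break deterministically to the component containing the
    lexicographically smallest (i, j, k) voxel.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels, n = ndimage.label(mask.values, structure=_STRUCTS[connectivity])
    if n == 0:
        warnings.warn("largest_component: empty mask", stacklevel=2)
        return BinaryMask(np.zeros(mask.shape, bool), mask.voxel_size, mask.origin)
    sizes = np.bincount(labels.ravel())[1:]
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        # first occurrence in C order == lexicographically smallest (i, j, k)
        flat = labels.ravel()
        firsts = {lab: np.flatnonzero(flat == lab)[0] for lab in candidates}
        keep = min(firsts, key=firsts.get)
    return BinaryMask(labels == keep, mask.voxel_size, mask.origin)


def extract_network(vol: VolumeImage, window_radius: int = 25,
                    offset: float = 10.0, max_radius: float = 45.0,
                    n_rays: int = 26, inside_fraction: float = 0.85,
                    connectivity: int = 26) -> BinaryMask:
    """Full segmentation pipeline: threshold → fill → largest component."""
    mask = local_threshold(vol, window_radius, offset)
    mask = fill_lumina(mask, max_radius, n_rays, inside_fraction)
    return largest_component(mask, connectivity)


def write_provenance(path, **params) -> None:
    """Write a JSON sidecar recording the parameters of a processing step."""
    from . import __version__
    with open(path, "w") as fh:
        json.dump({"vasculonet": __version__, **params}, fh, indent=2)
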