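"""Parametric vascular phantoms: ground-truth trees and their rasterisation.

The phantom generator produces branching tube trees with known topology and
rasterises them into solid volumes (the idealised filled lumen) or hollow
volumes (a wall shell with optional contiguous staining gaps, emulating
intraluminal staining where the lumen itself is dark and the wall signal has
holes).  The exact tree — node positions, connectivity, per-segment radii —
is exported as a :class:`~vasculonet.network.NetworkTopology`, so every stage
of the extraction pipeline can be validated against a known answer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import NetworkTopology
from .volume_io import BinaryMask


@dataclass
class PhantomSpec:
    """Parameters of a random binary vascular tree.

    All lengths in μm.  ``levels`` is the bifurcation depth: a tree has
    ``2**(levels+1) - 1`` segments.  ``min_separation`` (optional) asks the
    generator to guarantee a surface-to-surface gap of at least that many μm
    between non-adjacent segments, retrying with fresh geometry until
    satisfied.
    """
    seed: int = 0
    levels: int = 4
    root_position: tuple = (0.0, 0.0, 0.0)
    root_direction: tuple = (0.0, 0.0, 1.0)
    root_radius: float = 30.0
    radius_ratio: float = 0.75
    segment_length: tuple = (60.0, 100.0)
    branch_angle: tuple = (25.0, 50.0)       # degrees
    wall_thickness: float = 0.0              # 0 = solid
    gap_fraction: float = 0.0
    gap_patch_radius: float = 4.0            # μm, contiguous gap patch radius
    domain_size: tuple = (800.0, 800.0, 800.0)
    min_separation: float | None = None

    def __post_init__(self):
        if not self.root_radius > 0:
            raise ValueError("root_radius must be > 0")
        if not (0 < self.radius_ratio <= 1):
            raise ValueError("radius_ratio must be in (0, 1]")
        if not (0 <= self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.levels < 0:
            raise ValueError("levels must be >= 0")


def ln_like_spec(**overrides) -> PhantomSpec:
    """The default "LN-like" preset: a 6-level tree rooted in a vein-scale
    vessel (30 μm radius) tapering by 0.75 per generation, giving diameters
    spanning roughly 4–60 μm at 2 μm voxels."""
    kw = dict(levels=6, root_radius=30.0, radius_ratio=0.75,
              segment_length=(50.0, 90.0), domain_size=(1000.0, 1000.0, 1000.0),
              root_position=(500.0, 500.0, 60.0))
    kw.update(overrides)
    return PhantomSpec(**kw)


def recovery_spec(seed: int, levels: int = 5, **overrides) -> PhantomSpec:
    """Validation preset for topology recovery: solid trees at 2 μm voxels
    with all radii ≥ 2 voxels and a guaranteed 20 μm (10 voxel) surface gap
    between non-adjacent branches.  Per-depth geometry keeps the tree inside
    its domain while staying at capillary-to-arteriole scale."""
    cfg = {
        4: dict(root_radius=10.0, radius_ratio=0.80, segment_length=(50.0, 80.0),
                branch_angle=(25.0, 50.0), domain_size=(700.0, 700.0, 700.0)),
        5: dict(root_radius=10.0, radius_ratio=0.85, segment_length=(45.0, 70.0),
                branch_angle=(25.0, 50.0), domain_size=(800.0, 800.0, 800.0)),
        6: dict(root_radius=9.0, radius_ratio=0.90, segment_length=(45.0, 65.0),
                branch_angle=(30.0, 55.0), domain_size=(1000.0, 1000.0, 1000.0)),
    }[levels]
    d = cfg["domain_size"]
    kw = dict(seed=seed, levels=levels, min_separation=20.0,
              root_position=(d[0] / 2.0, d[1] / 2.0, 40.0), **cfg)
    kw.update(overrides)
    return PhantomSpec(**kw)


def hollow_spec(seed: int, gap_fraction: float = 0.10, **overrides) -> PhantomSpec:
    """Validation preset for wall-gap closing: hollow arteriole/venule-scale
    trees (radii ≈ 10–20 μm) with a 4 μm wall and contiguous staining gaps.
    Staining-gap physics concerns vessels whose lumen spans several voxels;
    capillary-scale walls are below the method's working range."""
    kw = dict(seed=seed, levels=3, root_radius=20.0, radius_ratio=0.80,
              segment_length=(60.0, 90.0), branch_angle=(25.0, 50.0),
              domain_size=(500.0, 500.0, 500.0), root_position=(250.0, 250.0, 40.0),
              min_separation=20.0, wall_thickness=4.0, gap_fraction=gap_fraction)
    kw.update(overrides)
    return PhantomSpec(**kw)


@dataclass
class GroundTruth:
    """A generated tree plus the tissue region containing it."""
    topology: NetworkTopology
    region: BinaryMask
    spec: PhantomSpec
    # per-segment true radius (μm), keyed by segment id
    radii: dict = field(default_factory=dict)


class GenerationError(RuntimeError):
    """Raised when a tree cannot be fitted into the domain."""


def _orthonormal(d):
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def _segment_pair_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between 3D line segments p1p2 and q1q2."""
    u, v, w = p2 - p1, q2 - q1, p1 - q1
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    # re-clamp s for the clamped t
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p1 + s * u) - (q1 + t * v)))


def _build_tree(spec: PhantomSpec, rng) -> tuple[NetworkTopology, dict]:
    net = NetworkTopology(voxel_size=0.0)
    radii: dict[int, float] = {}
    domain = np.asarray(spec.domain_size, dtype=float)
    root = net.add_node(np.asarray(spec.root_position, dtype=float))
    d0 = np.asarray(spec.root_direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)
    lo, hi = spec.segment_length
    a_lo, a_hi = np.deg2rad(spec.branch_angle[0]), np.deg2rad(spec.branch_angle[1])

    def clashes(start, end, radius, parent_id):
        """New segment too close to an existing non-adjacent segment?"""
        if spec.min_separation is None:
            return False
        for other in net.segments.values():
            if parent_id in other.nodes:
                continue
            d = _segment_pair_distance(start, end,
                                       other.points[0], other.points[-1])
            if d - radius - radii[other.id] < spec.min_separation:
                return True
        return False

    def branch_dir(din, rng):
        u, v = _orthonormal(din)
        theta = rng.uniform(a_lo, a_hi)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        d = (math.cos(theta) * din
             + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v))
        return d / np.linalg.norm(d)

    min_sibling = min(2.0 * a_lo, math.radians(170.0))

    # (parent node id, incoming direction, generation, sibling directions)
    stack = [(root.id, d0, 0, [])]
    while stack:
        parent_id, din, gen, siblings = stack.pop()
        radius = spec.root_radius * spec.radius_ratio ** gen
        margin = radius + spec.wall_thickness + 2.0
        start = net.nodes[parent_id].position
        end = None
        cand = din
        for attempt in range(200):
            length = rng.uniform(lo, hi)
            trial = start + length * cand
            ok = (np.all(trial >= margin) and np.all(trial <= domain - margin)
                  and all(float(np.arccos(np.clip(cand @ s, -1, 1))) >= min_sibling
                          for s in siblings)
                  and not clashes(start, trial, radius, parent_id))
            if ok:
                end = trial
                break
            if gen == 0:
                break  # the trunk direction is fixed by the spec
            # re-sample a fresh branch direction about the incoming axis,
            # keeping branch-angle statistics intact
            cand = branch_dir(din, rng)
        if end is None:
            raise GenerationError("segment does not fit inside the domain")
        child = net.add_node(end)
        seg = net.add_segment(parent_id, child.id,
                              np.stack([start, end]),
                              np.array([radius, radius]))
        radii[seg.id] = radius
        siblings.append(cand)  # visible to the co-sibling sharing this list
        if gen < spec.levels:
            sibs: list = []
            u, v = _orthonormal(cand)
            phi0 = rng.uniform(0.0, 2.0 * math.pi)
            for k in (0, 1):
                theta = rng.uniform(a_lo, a_hi)
                phi = phi0 + k * math.pi + rng.uniform(-0.3, 0.3)
                cdir = (math.cos(theta) * cand
                        + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v))
                cdir /= np.linalg.norm(cdir)
                stack.append((child.id, cdir, gen + 1, sibs))
    return net, radii


def _separation_ok(net: NetworkTopology, radii: dict, min_gap: float) -> bool:
    segs = list(net.segments.values())
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            a, b = segs[i], segs[j]
            if set(a.nodes) & set(b.nodes):
                continue  # adjacent segments touch by construction
            d = _segment_pair_distance(a.points[0], a.points[-1],
                                       b.points[0], b.points[-1])
            if d - radii[a.id] - radii[b.id] < min_gap:
                return False
    return True


def generate_tree(spec: PhantomSpec, max_retries: int = 300) -> GroundTruth:
    """Generate a random binary vascular tree; deterministic for a fixed seed.

    The tree has ``2**(levels+1) - 1`` segments and one more node than
    segments, radii shrinking by ``radius_ratio`` per generation.  When
    ``min_separation`` is set, whole-tree geometry is re-sampled (from the
    same seeded stream) until all non-adjacent segments keep that surface
    gap; a :class:`GenerationError` is raised if no attempt fits.
    """
    rng = np.random.default_rng(spec.seed)
    last_err = None
    for _ in range(max_retries):
        try:
            net, radii = _build_tree(spec, rng)
        except GenerationError as err:
            last_err = err
            continue
        if spec.min_separation is not None and not _separation_ok(
                net, radii, spec.min_separation):
            continue
        region = _domain_region(spec)
        return GroundTruth(net, region, spec, radii)
    raise GenerationError(
        f"could not generate a fitting tree after {max_retries} attempts"
    ) from last_err


def _domain_region(spec: PhantomSpec, voxel_size: float = 2.0) -> BinaryMask:
    shape = tuple(int(math.ceil(s / voxel_size)) for s in spec.domain_size)
    return BinaryMask(np.ones(shape, bool), voxel_size)


def _distance_to_segment(P, a, b):
    ab = b - a
    denom = ab @ ab
    if denom < 1e-12:
        return np.linalg.norm(P - a, axis=1)
    t = np.clip((P - a) @ ab / denom, 0.0, 1.0)
    closest = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(P - closest, axis=1)


def _paint(shape, voxel_size, segments, radii_by_id, inflate):
    """Boolean volume: voxel center within (radius + inflate) of any segment."""
    out = np.zeros(shape, bool)
    for seg in segments:
        r = radii_by_id[seg.id] + inflate
        a, b = seg.points[0], seg.points[-1]
        lo = np.floor((np.minimum(a, b) - r) / voxel_size).astype(int)
        hi = np.ceil((np.maximum(a, b) + r) / voxel_size).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)],
                                 indexing="ij")
        P = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * voxel_size
        dist = _distance_to_segment(P, a, b)
        box = (dist <= r).reshape(ii.shape)
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= box
    return out


def rasterize(gt: GroundTruth, voxel_size: float, mode: str = "solid") -> BinaryMask:
    """Rasterise a ground-truth tree into a binary volume.

    ``solid``: voxel on iff its center lies within the segment radius of the
    centerline (a union of capsules).  ``hollow``: only the wall shell
    [radius − wall_thickness, radius] is on; a seeded fraction
    ``gap_fraction`` of wall voxels is then deleted in contiguous spherical
    patches, emulating staining gaps.
    """
    spec = gt.spec
    min_r = min(gt.radii.values())
    if voxel_size > min_r:
        warnings.warn(
            f"voxel_size {voxel_size} μm exceeds the smallest radius {min_r} μm; "
            "thin branches may rasterise disconnected", stacklevel=2)
    shape = tuple(int(math.ceil(s / voxel_size)) for s in spec.domain_size)
    segments = list(gt.topology.segments.values())
    solid = _paint(shape, voxel_size, segments, gt.radii, inflate=0.0)
    if mode == "solid":
        return BinaryMask(solid, voxel_size)
    if mode != "hollow":
        raise ValueError(f"mode must be 'solid' or 'hollow', got {mode!r}")
    if spec.wall_thickness <= 0:
        raise ValueError("hollow mode requires wall_thickness > 0")
    lumen = _paint(shape, voxel_size, segments,
                   {k: v for k, v in gt.radii.items()}, inflate=-spec.wall_thickness)
    wall = solid & ~lumen
    if spec.gap_fraction > 0:
        wall = _carve_gaps(wall, voxel_size, spec)
    return BinaryMask(wall, voxel_size)


def _carve_gaps(wall: np.ndarray, voxel_size: float, spec: PhantomSpec) -> np.ndarray:
    """Delete ~gap_fraction of wall voxels in contiguous spherical patches."""
    rng = np.random.default_rng(spec.seed + 1)
    out = wall.copy()
    target = int(round(spec.gap_fraction * wall.sum()))
    removed = 0
    pr = max(1, int(round(spec.gap_patch_radius / voxel_size)))
    idx = np.argwhere(wall)
    order = rng.permutation(len(idx))
    # offsets within a ball of radius pr
    rng_grid = np.indices((2 * pr + 1,) * 3).reshape(3, -1).T - pr
    ball_off = rng_grid[np.linalg.norm(rng_grid, axis=1) <= pr]
    for oi in order:
        if removed >= target:
            break
        c = idx[oi]
        pts = c + ball_off
        ok = np.all((pts >= 0) & (pts < wall.shape), axis=1)
        pts = pts[ok]
        sel = out[pts[:, 0], pts[:, 1], pts[:, 2]]
        removed += int(sel.sum())
        out[pts[:, 0], pts[:, 1], pts[:, 2]] = False
    return out


def capsule_volume(radius: float, length: float) -> float:
    """Closed-form volume of a single capsule (cylinder + hemispherical caps)."""
    return math.pi * radius**2 * length + (4.0 / 3.0) * math.pi * radius**3
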