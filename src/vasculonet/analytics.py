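"""Topological measurements on a traced vascular network.

Branch counts to the feeding vessels, diameter-range subnetworks (putative
HEVs, arterial/venous trees), organ-region delineation, nearest-vessel
distance fields and voids, the 2D histology tool, and subregion statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_io import BinaryMask
from .network import NetworkTopology, NetworkSummary, UM3_PER_MM3

MM2_PER_UM2 = 1e-6


# ---------------------------------------------------------------------------
# branch counts

@dataclass
class BranchCountMap:
    """Minimum number of branches (edges) from each node to a source node."""
    source_node: int
    counts: dict                      # node id -> int
    unreachable: set = field(default_factory=set)


def branch_counts(net: NetworkTopology, source: int) -> BranchCountMap:
    """Breadth-first edge distance from ``source`` to every node.

    Parallel segments between the same node pair count as one step; nodes in
    other components are flagged unreachable, never silently 0.
    """
    if source not in net.nodes:
        raise KeyError(f"unknown source node {source}")
    g = net.to_networkx()
    counts = dict(nx.single_source_shortest_path_length(g, source))
    unreachable = set(net.nodes) - set(counts)
    return BranchCountMap(source, counts, unreachable)


def suggest_feeders(net: NetworkTopology, n: int = 5) -> list[int]:
    """Candidate feeder nodes: degree-1 nodes attached to the widest segments."""
    cands = []
    for node in net.nodes.values():
        if node.degree == 1:
            seg = net.segments[node.segments[0]]
            cands.append((seg.diameter, node.id))
    cands.sort(reverse=True)
    return [nid for _, nid in cands[:n]]


# ---------------------------------------------------------------------------
# diameter-range subnetworks

def select_by_diameter(net: NetworkTopology, dmin: float = 0.0,
                       dmax: float = math.inf,
                       min_length: float = 0.0,
                       exclude: set | None = None) -> NetworkTopology:
    """Subnetwork of segments with dmin ≤ diameter ≤ dmax and length ≥
    min_length; ``exclude`` drops explicit segment ids (e.g. known arterial
    branches).  Only nodes with at least one kept segment are retained; the
    result may be disconnected."""
    if dmin > dmax:
        raise ValueError("dmin must be <= dmax")
    exclude = exclude or set()
    sub = NetworkTopology(voxel_size=net.voxel_size)
    keep = [s for s in net.segments.values()
            if dmin <= s.diameter <= dmax and s.length >= min_length
            and s.id not in exclude]
    used_nodes = {nid for s in keep for nid in s.nodes}
    for nid in sorted(used_nodes):
        n = net.nodes[nid]
        sub.add_node(n.position, node_id=nid)
    for s in keep:
        sub.add_segment(s.nodes[0], s.nodes[1], s.points.copy(),
                        s.radii.copy(), segment_id=s.id)
    return sub


def phev_select(net: NetworkTopology, dmin: float = 16.0, dmax: float = 32.0,
                min_length: float = 40.0,
                exclude: set | None = None) -> NetworkTopology:
    """Putative-HEV selection: intermediate-diameter vessels (16–32 μm) at
    least 40 μm long, with an explicit exclusion list standing in for the
    manual removal of arterial branches."""
    return select_by_diameter(net, dmin, dmax, min_length, exclude)


def split_trees(net: NetworkTopology, dmin: float = 15.0) -> tuple:
    """Arterial/venous tree separation: keep vessels wider than ``dmin`` μm
    and return the two largest connected subnetworks (no flow direction is
    inferred — the caller decides which is which)."""
    big = select_by_diameter(net, dmin=dmin)
    g = big.to_networkx()
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    out = []
    for comp in comps[:2]:
        keep = {s.id for s in big.segments.values()
                if s.nodes[0] in comp and s.nodes[1] in comp}
        tree = NetworkTopology(voxel_size=net.voxel_size)
        for nid in sorted(comp):
            tree.add_node(big.nodes[nid].position, node_id=nid)
        for sid in sorted(keep):
            s = big.segments[sid]
            tree.add_segment(s.nodes[0], s.nodes[1], s.points.copy(),
                             s.radii.copy(), segment_id=sid)
        out.append(tree)
    while len(out) < 2:
        out.append(NetworkTopology(voxel_size=net.voxel_size))
    return tuple(out)


# ---------------------------------------------------------------------------
# organ region and distance fields

def ln_region(mask: BinaryMask, closing_radius: float = 60.0) -> BinaryMask:
    """Estimate the organ region occupied by the network: morphological
    closing of the vessel mask with a Euclidean ball of ``closing_radius``
    μm followed by hole filling.  The result is a superset of the vessel
    mask.

    The closing is computed with two distance transforms (dilate: points
    within the radius of the mask; erode: points deeper than the radius
    inside the dilation), which is exact and stays cheap for the large
    radii organ delineation needs.
    """
    r = closing_radius / mask.voxel_size
    vals = mask.values
    if r > 0:
        pad = int(math.ceil(r)) + 1
        padded = np.pad(vals, pad)
        dilated = ndimage.distance_transform_edt(~padded) <= r
        closed = ndimage.distance_transform_edt(dilated) > r
        vals = closed[pad:-pad, pad:-pad, pad:-pad]
    filled = ndimage.binary_fill_holes(vals)
    return BinaryMask(filled | mask.values, mask.voxel_size, mask.origin)


@dataclass
class DistanceField:
    """Nearest-vessel distances on a regular grid restricted to a region.

    Points inside vessels are excluded.  ``indices`` are the grid indices of
    each retained point; ``grid_shape``/``grid_origin`` describe the full
    grid so void masks can be reconstituted at grid resolution.
    """
    spacing: float
    grid_origin: np.ndarray
    grid_shape: tuple
    points: np.ndarray                # (N, 3) μm
    indices: np.ndarray               # (N, 3) int
    distances: np.ndarray             # (N,) μm

    @property
    def mean(self) -> float:
        return float(self.distances.mean())

    def fraction_within(self, d: float) -> float:
        return float((self.distances <= d).mean())

    def histogram(self, bin_width: float = 1.0):
        top = math.ceil(self.distances.max()) + bin_width
        bins = np.arange(0, top + bin_width, bin_width)
        return np.histogram(self.distances, bins=bins)


def distance_field(region: BinaryMask, vessels: BinaryMask,
                   spacing: float = 4.0) -> DistanceField:
    """Distance to the nearest vessel voxel center for every grid point (at
    ``spacing`` μm) inside ``region`` and outside ``vessels``."""
    if vessels.count == 0:
        raise ValueError("empty vessel mask: distance undefined")
    if not region.same_geometry(vessels):
        raise ValueError("region and vessel masks must share geometry")
    vox = region.voxel_size
    extent = np.asarray(region.shape) * vox
    n = np.maximum(np.floor((extent - vox / 2.0) / spacing).astype(int) + 1, 1)
    grid_origin = region.origin.copy()

    axes = [grid_origin[d] + spacing * np.arange(n[d]) for d in range(3)]
    II, JJ, KK = np.meshgrid(*[np.arange(len(a)) for a in axes], indexing="ij")
    idx = np.stack([II, JJ, KK], axis=-1).reshape(-1, 3)
    pts = idx * spacing + grid_origin

    # nearest voxel of each grid point, for the region/vessel membership test
    vidx = np.rint((pts - region.origin) / vox).astype(int)
    vidx = np.clip(vidx, 0, np.asarray(region.shape) - 1)
    in_region = region.values[vidx[:, 0], vidx[:, 1], vidx[:, 2]]
    in_vessel = vessels.values[vidx[:, 0], vidx[:, 1], vidx[:, 2]]
    keep = in_region & ~in_vessel
    idx, pts = idx[keep], pts[keep]

    ratio = spacing / vox
    if abs(ratio - round(ratio)) < 1e-9 and np.allclose(grid_origin, region.origin):
        # grid points coincide with voxel centers: sample the EDT
        step = int(round(ratio))
        edt = ndimage.distance_transform_edt(~vessels.values) * vox
        dists = edt[idx[:, 0] * step, idx[:, 1] * step, idx[:, 2] * step]
    else:
        tree = cKDTree(np.argwhere(vessels.values) * vox + vessels.origin)
        dists, _ = tree.query(pts, workers=-1)
    return DistanceField(spacing, grid_origin, tuple(n), pts, idx,
                         np.asarray(dists, dtype=float))


def find_voids(df: DistanceField, threshold: float = 60.0) -> BinaryMask:
    """Mask (at grid resolution) of points farther than ``threshold`` μm from
    any vessel — candidate under-supplied voids."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    vals = np.zeros(df.grid_shape, bool)
    far = df.distances > threshold
    sel = df.indices[far]
    vals[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return BinaryMask(vals, df.spacing, df.grid_origin)


# ---------------------------------------------------------------------------
# 2D histology tool

@dataclass
class HistologyResult:
    axis: int                          # 0, 1, 2 for x, y, z
    coordinate: float                  # μm
    intersections: list                # (segment id, position (3,), diameter)
    area_mm2: float                    # region cross-section area
    @property
    def count(self) -> int:
        return len(self.intersections)

    @property
    def density(self) -> float:
        """Intersections per mm² of region cross-section."""
        return self.count / self.area_mm2 if self.area_mm2 > 0 else 0.0

    @property
    def diameters(self) -> np.ndarray:
        return np.array([d for _, _, d in self.intersections])


_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


def _segment_crossings(seg, axis: int, coord: float):
    """Crossing positions/diameters of a polyline with a plane.

    One crossing per sign change; runs of points exactly on the plane count
    once, at the run's first point.
    """
    c = seg.points[:, axis] - coord
    out = []
    n = len(c)
    i = 0
    while i < n - 1:
        a, b = c[i], c[i + 1]
        if a == 0.0:
            # a run of points exactly on the plane counts as one crossing
            j = i
            while j < n and c[j] == 0.0:
                j += 1
            out.append((seg.points[i].copy(), 2.0 * seg.radii[i]))
            i = j
            continue
        if (a > 0 > b) or (a < 0 < b):
            t = a / (a - b)
            pos = (1 - t) * seg.points[i] + t * seg.points[i + 1]
            dia = 2.0 * ((1 - t) * seg.radii[i] + t * seg.radii[i + 1])
            out.append((pos, dia))
        i += 1
    if n and c[-1] == 0.0 and (n == 1 or c[-2] != 0.0):
        out.append((seg.points[-1].copy(), 2.0 * seg.radii[-1]))
    return out


def histology_2d(net: NetworkTopology, region: BinaryMask, axis="z",
                 coordinate: float = 0.0) -> HistologyResult:
    """Count vessel centerline crossings of a single plane, their local
    (interpolated) diameters, and the areal density over the region
    cross-section.  Crossings outside the region slice are not counted, so
    the density is consistent with its area."""
    ax = _AXES[axis]
    vox = region.voxel_size
    k = int(round((coordinate - region.origin[ax]) / vox))
    if not (0 <= k < region.shape[ax]):
        raise IndexError(f"plane {axis}={coordinate} μm outside the volume")
    slc = [slice(None)] * 3
    slc[ax] = k
    region_slice = region.values[tuple(slc)]
    area_mm2 = float(region_slice.sum()) * vox * vox * MM2_PER_UM2

    inter = []
    other = [d for d in range(3) if d != ax]
    for s in net.segments.values():
        for pos, dia in _segment_crossings(s, ax, coordinate):
            ij = np.rint((pos[other] - region.origin[other]) / vox).astype(int)
            shp = (region.shape[other[0]], region.shape[other[1]])
            if not (0 <= ij[0] < shp[0] and 0 <= ij[1] < shp[1]):
                continue
            if not region_slice[ij[0], ij[1]]:
                continue
            inter.append((s.id, pos, dia))
    return HistologyResult(ax, coordinate, inter, area_mm2)


# ---------------------------------------------------------------------------
# subregion statistics

@dataclass
class RegionStats:
    label: str
    mean_distance: float               # μm
    density_3d: float                  # segments / mm³
    density_2d: float                  # intersections / mm²
    mean_diameter: float               # μm
    n_segments: int


def region_stats(net: NetworkTopology, df: DistanceField, block_origin,
                 block_size, region: BinaryMask | None = None,
                 label: str = "") -> RegionStats:
    """Statistics over a rectangular block (world μm origin + size).

    3D density counts segments whose arc-length midpoint falls in the block
    (a partition rule: no double counting across blocks); 2D density comes
    from the histology tool on the block's central z-plane.
    """
    o = np.asarray(block_origin, dtype=float)
    s = np.asarray(block_size, dtype=float)
    if np.any(s <= 0):
        raise ValueError("block size must be positive")
    in_block = np.all((df.points >= o) & (df.points < o + s), axis=1)
    if not np.any(in_block):
        raise ValueError("block contains no distance-field points")
    mean_dist = float(df.distances[in_block].mean())

    mids = {sid: seg.midpoint() for sid, seg in net.segments.items()}
    inside = [sid for sid, m in mids.items()
              if np.all(m >= o) and np.all(m < o + s)]
    vol_mm3 = float(np.prod(s)) / UM3_PER_MM3
    density_3d = len(inside) / vol_mm3
    mean_dia = (float(np.mean([net.segments[sid].diameter for sid in inside]))
                if inside else 0.0)

    zc = o[2] + s[2] / 2.0
    count2d = 0
    for seg in net.segments.values():
        for pos, _ in _segment_crossings(seg, 2, zc):
            if (o[0] <= pos[0] < o[0] + s[0]) and (o[1] <= pos[1] < o[1] + s[1]):
                count2d += 1
    area_mm2 = float(s[0] * s[1]) * MM2_PER_UM2
    density_2d = count2d / area_mm2
    return RegionStats(label, mean_dist, density_3d, density_2d,
                       mean_dia, len(inside))


# ---------------------------------------------------------------------------
# in-table ratio arithmetic

def table_ratio_report(total: NetworkSummary, sub: NetworkSummary,
                       organ_volume_mm3: float | None = None) -> dict:
    """Percentage cells comparing a subnetwork (e.g. the pHEV set) with the
    full network, formatted at reporting precision: integer percent for
    counts, diameters and volume, one decimal for the length fraction, two
    decimals for organ-volume fractions."""
    def pct(a, b):
        return 100.0 * a / b if b else float("nan")

    out = {
        "segments_pct": round(pct(sub.n_segments, total.n_segments)),
        "nodes_pct": round(pct(sub.n_nodes, total.n_nodes)),
        "mean_diameter_pct": round(pct(sub.mean_diameter, total.mean_diameter)),
        "mean_length_pct": round(pct(sub.mean_length, total.mean_length)),
        "length_pct": round(pct(sub.total_length, total.total_length), 1),
        "volume_pct": round(pct(sub.total_volume, total.total_volume)),
    }
    if organ_volume_mm3:
        out["total_organ_volume_pct"] = round(
            pct(total.total_volume, organ_volume_mm3), 2)
        out["sub_organ_volume_pct"] = round(
            pct(sub.total_volume, organ_volume_mm3), 2)
    return out
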