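"""The topology map: a geometric network of nodes and vessel segments.

A :class:`NetworkTopology` is the numerical description of a vascular network:
nodes (junctions, endpoints, cycle anchors) and segments (centerline polylines
with a radius at every point).  Self-loops and parallel segments are first-class
citizens — capillary beds contain reconnecting arcades, so the graph model is a
multigraph.

Derived per-segment quantities:

* length  = sum of consecutive point distances (μm)
* diameter = length-weighted mean of 2·radius over the polyline; when a segment
  has ≥ 4 points its first and last point (inside the junction blob, where a
  distance-transform radius overestimates) are excluded from the average
* volume  = sum of conical-frustum volumes between consecutive points (μm³)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import networkx as nx


@dataclass
class Node:
    id: int
    position: np.ndarray          # μm
    segments: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)

    @property
    def degree(self) -> int:
        return len(self.segments)


@dataclass
class Segment:
    id: int
    nodes: tuple[int, int]        # (a, b); a == b for a self-loop
    points: np.ndarray            # (n, 3) μm, ordered from a to b, n >= 2
    radii: np.ndarray             # (n,) μm, all > 0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"segment {self.id}: points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError(f"segment {self.id}: needs >= 2 points")
        if len(self.radii) != len(self.points):
            raise ValueError(f"segment {self.id}: radii/points length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError(f"segment {self.id}: radii must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def diameter(self) -> float:
        """Length-weighted mean diameter, excluding junction-adjacent
        endpoints when the polyline has at least 4 points."""
        pts, rad = self.points, self.radii
        if len(pts) >= 4:
            pts, rad = pts[1:-1], rad[1:-1]
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if len(pts) < 2 or seg_len.sum() == 0:
            return float(2.0 * rad.mean())
        pair_d = rad[:-1] + rad[1:]   # mean diameter of each piece
        return float((seg_len * pair_d).sum() / seg_len.sum())

    @property
    def volume(self) -> float:
        """Sum of conical frusta between consecutive points (μm³)."""
        h = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        r1, r2 = self.radii[:-1], self.radii[1:]
        return float((math.pi / 3.0) * (h * (r1 * r1 + r1 * r2 + r2 * r2)).sum())

    def midpoint(self) -> np.ndarray:
        """Point at half arc length along the polyline."""
        d = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(d)])
        half = cum[-1] / 2.0
        i = int(np.searchsorted(cum, half, side="right")) - 1
        i = min(i, len(d) - 1)
        if d[i] == 0:
            return self.points[i].copy()
        t = (half - cum[i]) / d[i]
        return (1 - t) * self.points[i] + t * self.points[i + 1]


class NetworkTopology:
    """Nodes + segments with centerline polylines and per-point radii."""

    def __init__(self, nodes=(), segments=(), voxel_size: float = 1.0):
        self.nodes: dict[int, Node] = {n.id: n for n in nodes}
        self.segments: dict[int, Segment] = {s.id: s for s in segments}
        self.voxel_size = float(voxel_size)

    # -- construction -----------------------------------------------------

    def add_node(self, position, node_id: int | None = None) -> Node:
        if node_id is None:
            node_id = max(self.nodes, default=-1) + 1
        node = Node(node_id, position)
        self.nodes[node_id] = node
        return node

    def add_segment(self, a: int, b: int, points, radii,
                    segment_id: int | None = None) -> Segment:
        if segment_id is None:
            segment_id = max(self.segments, default=-1) + 1
        seg = Segment(segment_id, (a, b), points, radii)
        self.segments[segment_id] = seg
        self.nodes[a].segments.append(segment_id)
        if b != a:
            self.nodes[b].segments.append(segment_id)
        else:
            self.nodes[a].segments.append(segment_id)  # self-loop counts twice
        return seg

    # -- views ------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, position=n.position)
        for s in self.segments.values():
            g.add_edge(s.nodes[0], s.nodes[1], key=s.id, segment=s.id,
                       length=s.length, diameter=s.diameter)
        return g

    def n_components(self) -> int:
        g = self.to_networkx()
        return nx.number_connected_components(g) if g.number_of_nodes() else 0

    def n_cycles(self) -> int:
        """Independent cycle count (first Betti number) of the multigraph."""
        g = self.to_networkx()
        if g.number_of_nodes() == 0:
            return 0
        return (g.number_of_edges() - g.number_of_nodes()
                + nx.number_connected_components(g))

    def validate(self, atol: float = 1e-6) -> None:
        """Check adjacency symmetry and endpoint/node coincidence."""
        for s in self.segments.values():
            a, b = s.nodes
            for nid in (a, b):
                if nid not in self.nodes:
                    raise ValueError(f"segment {s.id}: unknown node {nid}")
                if s.id not in self.nodes[nid].segments:
                    raise ValueError(f"adjacency asymmetry: seg {s.id}, node {nid}")
            if not np.allclose(s.points[0], self.nodes[a].position, atol=atol):
                raise ValueError(f"segment {s.id}: first point != node {a}")
            if not np.allclose(s.points[-1], self.nodes[b].position, atol=atol):
                raise ValueError(f"segment {s.id}: last point != node {b}")
        for n in self.nodes.values():
            for sid in n.segments:
                if sid not in self.segments:
                    raise ValueError(f"node {n.id}: unknown segment {sid}")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "voxel_size": self.voxel_size,
            "nodes": [
                {"id": n.id, "pos": n.position.tolist(), "segs": list(n.segments)}
                for n in self.nodes.values()
            ],
            "segments": [
                {"id": s.id, "nodes": list(s.nodes),
                 "points": s.points.tolist(), "radii": s.radii.tolist()}
                for s in self.segments.values()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkTopology":
        net = cls(voxel_size=d.get("voxel_size", 1.0))
        for n in d["nodes"]:
            node = Node(n["id"], n["pos"], list(n["segs"]))
            net.nodes[node.id] = node
        for s in d["segments"]:
            seg = Segment(s["id"], tuple(s["nodes"]), s["points"], s["radii"])
            net.segments[seg.id] = seg
        return net

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "NetworkTopology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class NetworkSummary:
    """Whole-network statistics; totals are sums over segments.

    Units follow reporting convention: mean diameter/length in μm,
    total length in cm, total volume in mm³.
    """
    n_segments: int
    n_nodes: int
    mean_diameter: float          # μm
    mean_length: float            # μm
    total_length: float           # cm
    total_volume: float           # mm³
    diameter_histogram: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    length_histogram: np.ndarray = field(default_factory=lambda: np.zeros(0, int))


UM_PER_CM = 1e4
UM3_PER_MM3 = 1e9


def summarize(net: NetworkTopology) -> NetworkSummary:
    """Counts, means, totals and 1 μm-bin histograms for a network."""
    if net.n_segments == 0:
        return NetworkSummary(0, net.n_nodes, 0.0, 0.0, 0.0, 0.0)
    diams = np.array([s.diameter for s in net.segments.values()])
    lens = np.array([s.length for s in net.segments.values()])
    vols = np.array([s.volume for s in net.segments.values()])
    dbins = np.arange(0, math.ceil(diams.max()) + 2)
    lbins = np.arange(0, math.ceil(lens.max()) + 2)
    return NetworkSummary(
        n_segments=net.n_segments,
        n_nodes=net.n_nodes,
        mean_diameter=float(diams.mean()),
        mean_length=float(lens.mean()),
        total_length=float(lens.sum() / UM_PER_CM),
        total_volume=float(vols.sum() / UM3_PER_MM3),
        diameter_histogram=np.histogram(diams, bins=dbins)[0],
        length_histogram=np.histogram(lens, bins=lbins)[0],
    )
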