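"""AmiraMesh 3D ASCII SpatialGraph writer/reader and attribute export.

The SpatialGraph layout: VERTEX (VertexCoordinates), EDGE (EdgeConnectivity,
NumEdgePoints), POINT (EdgePointCoordinates, thickness).  Per-point
``thickness`` stores the RADIUS (the common SpatialGraph convention).
Coordinates are μm, written with fixed 4-decimal formatting so output is
byte-stable for identical input.
"""

from __future__ import annotations

import csv

import numpy as np

from .network import NetworkTopology

_FMT = "{:.4f}"


def _spatialgraph_text(net: NetworkTopology, extra_field=None) -> str:
    node_ids = sorted(net.nodes)
    vindex = {nid: i for i, nid in enumerate(node_ids)}
    seg_ids = sorted(net.segments)
    npoints = sum(len(net.segments[s].points) for s in seg_ids)

    lines = ["# AmiraMesh 3D ASCII 2.0", ""]
    lines.append(f"define VERTEX {len(node_ids)}")
    lines.append(f"define EDGE {len(seg_ids)}")
    lines.append(f"define POINT {npoints}")
    lines += ["", "Parameters {", '    ContentType "HxSpatialGraph"', "}", ""]
    lines.append("VERTEX { float[3] VertexCoordinates } @1")
    lines.append("EDGE { int[2] EdgeConnectivity } @2")
    lines.append("EDGE { int NumEdgePoints } @3")
    lines.append("POINT { float[3] EdgePointCoordinates } @4")
    lines.append("POINT { float thickness } @5")
    if extra_field is not None:
        lines.append(f"POINT {{ float {extra_field[0]} }} @6")
    lines += ["", "@1"]
    for nid in node_ids:
        p = net.nodes[nid].position
        lines.append(" ".join(_FMT.format(x) for x in p))
    lines += ["", "@2"]
    for sid in seg_ids:
        a, b = net.segments[sid].nodes
        lines.append(f"{vindex[a]} {vindex[b]}")
    lines += ["", "@3"]
    for sid in seg_ids:
        lines.append(str(len(net.segments[sid].points)))
    lines += ["", "@4"]
    for sid in seg_ids:
        for p in net.segments[sid].points:
            lines.append(" ".join(_FMT.format(x) for x in p))
    lines += ["", "@5"]
    for sid in seg_ids:
        for r in net.segments[sid].radii:
            lines.append(_FMT.format(r))
    if extra_field is not None:
        lines += ["", "@6"]
        for sid in seg_ids:
            for v in extra_field[1][sid]:
                lines.append(_FMT.format(v))
    lines.append("")
    return "\n".join(lines)


def write_spatialgraph(net: NetworkTopology, path) -> None:
    """Write an ASCII AmiraMesh 3D SpatialGraph (deterministic output)."""
    with open(path, "w", newline="\n") as fh:
        fh.write(_spatialgraph_text(net))


def read_spatialgraph(path, voxel_size: float = 1.0) -> NetworkTopology:
    """Parse the SpatialGraph dialect written by :func:`write_spatialgraph`."""
    with open(path) as fh:
        text = fh.read()
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("@"):
            current = line
            sections[current] = []
        elif current and line:
            sections[current].append(line)

    verts = np.array([[float(x) for x in ln.split()] for ln in sections["@1"]])
    edges = [[int(x) for x in ln.split()] for ln in sections.get("@2", [])]
    counts = [int(ln) for ln in sections.get("@3", [])]
    pts = np.array([[float(x) for x in ln.split()]
                    for ln in sections.get("@4", [])])
    thick = np.array([float(ln) for ln in sections.get("@5", [])])

    net = NetworkTopology(voxel_size=voxel_size)
    for i, p in enumerate(verts):
        net.add_node(p, node_id=i)
    off = 0
    for sid, ((a, b), n) in enumerate(zip(edges, counts)):
        net.add_segment(a, b, pts[off:off + n], thick[off:off + n],
                        segment_id=sid)
        off += n
    return net


def attribute_export(net: NetworkTopology, values: dict, path,
                     kind: str = "segment", field_name: str = "attribute",
                     spatialgraph_path=None) -> None:
    """Export a per-node or per-segment scalar attribute.

    Writes a CSV of (element id, value) and optionally a SpatialGraph with
    the value as a per-point float field (for colour mapping downstream).
    Segment attributes are constant along the segment; node attributes are
    linearly interpolated between the two endpoint values along the point
    index.  Raises KeyError listing any element without a value.
    """
    if kind not in ("segment", "node"):
        raise ValueError("kind must be 'segment' or 'node'")
    ids = sorted(net.segments) if kind == "segment" else sorted(net.nodes)
    missing = [i for i in ids if i not in values]
    if missing:
        raise KeyError(f"missing {kind} values for ids {missing}")

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"{kind}_id", field_name])
        for i in ids:
            w.writerow([i, values[i]])

    if spatialgraph_path is not None:
        per_point: dict[int, np.ndarray] = {}
        for sid in sorted(net.segments):
            seg = net.segments[sid]
            n = len(seg.points)
            if kind == "segment":
                per_point[sid] = np.full(n, float(values[sid]))
            else:
                va, vb = float(values[seg.nodes[0]]), float(values[seg.nodes[1]])
                per_point[sid] = np.linspace(va, vb, n)
        text = _spatialgraph_text(net, extra_field=(field_name, per_point))
        with open(spatialgraph_path, "w", newline="\n") as fh:
            fh.write(text)
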