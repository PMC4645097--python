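"""CMGUI exnode/exelem export: node coordinates + radius field, and 1-D
linear elements over segment endpoints.

This is a minimal, self-consistent dialect of the CMGUI EX format: nodes are
renumbered contiguously from 1 regardless of internal ids, each network
segment becomes one linear element between its endpoint nodes.  Output is
deterministic byte-for-byte for identical input.
"""

from __future__ import annotations

from .network import NetworkTopology

_FMT = "{:.4f}"

_EXNODE_HEADER = """Group name: vessels
#Fields=2
1) coordinates, coordinate, rectangular cartesian, #Components=3
 x. Value index=1, #Derivatives=0
 y. Value index=2, #Derivatives=0
 z. Value index=3, #Derivatives=0
2) radius, field, rectangular cartesian, #Components=1
 r. Value index=4, #Derivatives=0
"""

_EXELEM_HEADER = """Group name: vessels
Shape. Dimension=1
#Scale factor sets=0
#Nodes=2
#Fields=1
1) coordinates, coordinate, rectangular cartesian, #Components=3
 x. l.Lagrange, no modify, standard node based.
  #Nodes=2
  1. #Values=1
   Value indices: 1
  2. #Values=1
   Value indices: 1
 y. l.Lagrange, no modify, standard node based.
  #Nodes=2
  1. #Values=1
   Value indices: 1
  2. #Values=1
   Value indices: 1
 z. l.Lagrange, no modify, standard node based.
  #Nodes=2
  1. #Values=1
   Value indices: 1
  2. #Values=1
   Value indices: 1
"""


def _node_radius(net: NetworkTopology, nid: int) -> float:
    """Radius at a node: the adjacent segment endpoint radius (max over
    incident segments; 0 for a bare node)."""
    best = 0.0
    node = net.nodes[nid]
    for sid in node.segments:
        seg = net.segments[sid]
        if seg.nodes[0] == nid:
            best = max(best, float(seg.radii[0]))
        if seg.nodes[1] == nid:
            best = max(best, float(seg.radii[-1]))
    return best


def write_cmgui(net: NetworkTopology, basename) -> tuple[str, str]:
    """Write ``basename.exnode`` and ``basename.exelem``; returns the paths."""
    node_ids = sorted(net.nodes)
    renum = {nid: i + 1 for i, nid in enumerate(node_ids)}

    exnode = str(basename) + ".exnode"
    with open(exnode, "w", newline="\n") as fh:
        fh.write(_EXNODE_HEADER)
        for nid in node_ids:
            p = net.nodes[nid].position
            fh.write(f"Node: {renum[nid]}\n")
            fh.write(" " + " ".join(_FMT.format(x) for x in p) + "\n")
            fh.write(" " + _FMT.format(_node_radius(net, nid)) + "\n")

    exelem = str(basename) + ".exelem"
    with open(exelem, "w", newline="\n") as fh:
        fh.write(_EXELEM_HEADER)
        for i, sid in enumerate(sorted(net.segments), start=1):
            a, b = net.segments[sid].nodes
            fh.write(f"Element: {i} 0 0\n")
            fh.write(f" Nodes: {renum[a]} {renum[b]}\n")
    return exnode, exelem
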