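"""Shared builders and independent oracles for the test suite.

Oracles here are deliberately naive (brute-force distance scans, exhaustive
path enumeration, direct voxel-center geometry tests) and independent of the
library code paths they check.
"""

import numpy as np

from vasculonet import BinaryMask, NetworkTopology


def straight_cylinder_mask(radius_um, length_um, voxel=2.0, pad=6,
                           axis=2, half=None) -> BinaryMask:
    """Axis-aligned solid cylinder with hemispherical caps (a capsule),
    rasterised by direct voxel-center testing.  ``half`` fixes the
    transverse half-width in voxels (to give capsules of different radii
    identical shapes)."""
    r_vox = radius_um / voxel
    l_vox = length_um / voxel
    n_ax = int(np.ceil(l_vox)) + 2 * pad
    if half is None:
        half = int(np.ceil(r_vox)) + pad
    n_tr = 2 * half + 1
    shape = [n_tr, n_tr, n_tr]
    shape[axis] = n_ax
    c = (n_tr - 1) / 2.0
    idx = np.indices(shape).astype(float)
    tr = [d for d in range(3) if d != axis]
    a = np.clip(idx[axis], pad, pad + l_vox)   # nearest point on the axis segment
    d2 = (idx[tr[0]] - c) ** 2 + (idx[tr[1]] - c) ** 2 + (idx[axis] - a) ** 2
    return BinaryMask(d2 <= r_vox ** 2, voxel)


def brute_force_capsule_count(a, b, radius, shape, voxel):
    """Number of voxel centers within `radius` of segment ab (world μm)."""
    idx = np.indices(shape).reshape(3, -1).T * voxel
    ab = np.asarray(b) - np.asarray(a)
    t = np.clip((idx - a) @ ab / (ab @ ab), 0, 1)
    closest = np.asarray(a) + t[:, None] * ab
    return int((np.linalg.norm(idx - closest, axis=1) <= radius).sum())


def make_path_network(positions, radius=5.0, voxel_size=2.0) -> NetworkTopology:
    """A chain network A-B-C-... from a list of node positions."""
    net = NetworkTopology(voxel_size=voxel_size)
    for p in positions:
        net.add_node(np.asarray(p, dtype=float))
    for i in range(len(positions) - 1):
        a, b = np.asarray(positions[i], float), np.asarray(positions[i + 1], float)
        net.add_segment(i, i + 1, np.stack([a, b]),
                        np.array([radius, radius]))
    return net


def random_connected_network(rng, n_nodes, extra_edges=3) -> NetworkTopology:
    """Random connected multigraph as a NetworkTopology (straight segments,
    arbitrary positions): a random spanning tree plus a few extra edges
    (possibly parallel or self-loops excluded)."""
    net = NetworkTopology(voxel_size=1.0)
    pos = rng.uniform(0, 100, size=(n_nodes, 3))
    for p in pos:
        net.add_node(p)
    order = rng.permutation(n_nodes)
    for i in range(1, n_nodes):
        a = int(order[i])
        b = int(order[rng.integers(0, i)])
        net.add_segment(a, b, np.stack([pos[a], pos[b]]), np.array([1.0, 1.0]))
    for _ in range(int(extra_edges)):
        a, b = int(rng.integers(n_nodes)), int(rng.integers(n_nodes))
        if a == b:
            continue
        net.add_segment(a, b, np.stack([pos[a], pos[b]]), np.array([1.0, 1.0]))
    return net


def exhaustive_min_edge_counts(net: NetworkTopology, source: int) -> dict:
    """Minimum number of edges from source to every node by exhaustive
    enumeration of simple paths (independent of any graph library)."""
    adj: dict[int, set[int]] = {nid: set() for nid in net.nodes}
    for s in net.segments.values():
        a, b = s.nodes
        adj[a].add(b)
        adj[b].add(a)
    best = {source: 0}

    def walk(node, depth, seen):
        for nxt in adj[node]:
            if nxt in seen:
                continue
            if nxt not in best or depth + 1 < best[nxt]:
                best[nxt] = depth + 1
            if depth + 1 < len(net.nodes):
                walk(nxt, depth + 1, seen | {nxt})

    walk(source, 0, {source})
    return best


def brute_force_distances(points, vessel_mask: BinaryMask):
    """O(N·M) nearest vessel-voxel-center distance for each query point."""
    centers = np.argwhere(vessel_mask.values) * vessel_mask.voxel_size \
        + vessel_mask.origin
    out = np.empty(len(points))
    for i, p in enumerate(points):
        out[i] = np.sqrt(((centers - p) ** 2).sum(axis=1)).min()
    return out


def count_plane_crossings(points, axis, coord):
    """Independent crossing counter for one polyline: sign changes of the
    axis coordinate, with on-plane runs counted once."""
    c = np.asarray(points)[:, axis] - coord
    count = 0
    i = 0
    n = len(c)
    while i < n - 1:
        if c[i] == 0:
            j = i
            while j < n and c[j] == 0:
                j += 1
            count += 1
            i = j
            continue
        if c[i] * c[i + 1] < 0:
            count += 1
        i += 1
    if n and c[-1] == 0 and (n == 1 or c[-2] != 0):
        count += 1
    return count
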