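"""Validation batteries: phantom recovery benchmarks and published
whole-organ reference statistics.

``LN_BENCHMARK_*`` hold published whole-network measurements of a murine
lymph-node blood vessel network and its putative-HEV subnetwork (segment and
node counts; mean diameter/length in μm; total length in cm; volume in mm³;
whole-LN volume in mm³).  They serve as inputs for ratio arithmetic — the
original image volume is not publicly deposited, so absolute re-extraction is
not possible and the phantom batteries below validate the pipeline instead.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .network import NetworkSummary
from .phantom import generate_tree, rasterize, recovery_spec, hollow_spec
from .segmentation import (GAP_FILL_PARAMS, fill_lumina, largest_component,
                           local_threshold)
from .tracing import extract_topology
from .volume_io import VolumeImage
from .analytics import table_ratio_report

LN_BENCHMARK_TOTAL = NetworkSummary(
    n_segments=16336, n_nodes=12561, mean_diameter=13.47, mean_length=57.0,
    total_length=90.0, total_volume=0.171)

LN_BENCHMARK_PHEV = NetworkSummary(
    n_segments=1107, n_nodes=1256, mean_diameter=21.14, mean_length=107.5,
    total_length=11.4, total_volume=0.043)

LN_VOLUME_MM3 = 2.31

#: bifurcation depths cycled through in the recovery battery
RECOVERY_LEVELS = (4, 5, 6, 4, 5)


def benchmark_ratio_report() -> dict:
    """pHEV / whole-network percentage cells from the published totals."""
    return table_ratio_report(LN_BENCHMARK_TOTAL, LN_BENCHMARK_PHEV,
                              organ_volume_mm3=LN_VOLUME_MM3)


def recover_one(seed: int, levels: int, voxel_size: float = 2.0) -> dict:
    """Trace one solid phantom and score it against its ground truth.

    Returns exactness of the recovered topology (segment count and node
    degree multiset), and per-segment diameter/length agreement (segments
    matched to truth by arc-length midpoint).
    """
    gt = generate_tree(recovery_spec(seed, levels))
    mask = rasterize(gt, voxel_size, "solid")
    net = extract_topology(mask)
    true = gt.topology
    exact = (net.n_segments == true.n_segments
             and Counter(n.degree for n in net.nodes.values())
             == Counter(n.degree for n in true.nodes.values()))
    true_mid = {sid: s.midpoint() for sid, s in true.segments.items()}
    diam_ok = length_ok = 0
    for s in net.segments.values():
        m = s.midpoint()
        best = min(true_mid, key=lambda k: np.linalg.norm(true_mid[k] - m))
        ts = true.segments[best]
        diam_ok += abs(s.diameter - 2.0 * gt.radii[best]) <= voxel_size
        length_ok += abs(s.length - ts.length) <= 0.10 * ts.length
    return {"exact": exact, "diam_ok": diam_ok, "length_ok": length_ok,
            "n_segments": net.n_segments}


def topology_recovery_batch(n_phantoms: int = 20, seed_base: int = 100) -> dict:
    """Run the solid-phantom recovery battery (depths 4–6, 2 μm voxels,
    radii ≥ 2 voxels, ≥ 10-voxel branch separation)."""
    exact = diam = length = total = 0
    for i in range(n_phantoms):
        res = recover_one(seed_base + i, RECOVERY_LEVELS[i % len(RECOVERY_LEVELS)])
        exact += res["exact"]
        diam += res["diam_ok"]
        length += res["length_ok"]
        total += res["n_segments"]
    return {"n_phantoms": n_phantoms, "exact": exact,
            "diam_fraction": diam / total, "length_fraction": length / total,
            "n_segments_total": total}


def gap_closing_one(seed: int, gap_fraction: float = 0.10,
                    voxel_size: float = 2.0, noise_sd: float = 3.0) -> dict:
    """Run the full segmentation pipeline on one hollow phantom with wall
    staining gaps and score voxel recovery against the solid rasterisation.

    The grayscale input is wall signal (200) on background (10) with mild
    Gaussian noise, binarised by local thresholding, gap-closed with the
    fill parameters of :data:`~vasculonet.segmentation.GAP_FILL_PARAMS`, and
    reduced to the largest component.
    """
    gt = generate_tree(hollow_spec(seed, gap_fraction=gap_fraction))
    solid = rasterize(gt, voxel_size, "solid")
    hollow = rasterize(gt, voxel_size, "hollow")
    rng = np.random.default_rng(seed)
    img = np.where(hollow.values, 200.0, 10.0) \
        + rng.normal(0.0, noise_sd, hollow.shape)
    mask = local_threshold(VolumeImage(img, voxel_size), 25, 20.0)
    filled = fill_lumina(mask, **GAP_FILL_PARAMS)
    big = largest_component(filled)
    true = solid.values
    recovered = (big.values & true).sum() / true.sum()
    spurious = (big.values & ~true).sum() / true.sum()
    net = extract_topology(big)
    return {"recovered": float(recovered), "spurious": float(spurious),
            "n_components": net.n_components()}
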