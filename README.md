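# vasculonet

Extraction and topological analysis of 3D microvascular networks from
volume images.

Organ-scale imaging of luminally stained blood vessels (for example the
complete vasculature of a murine lymph node imaged at 2 μm isotropic
voxels) produces grayscale volumes in which the vessel *walls* carry
signal, the lumina are dark, and the staining has gaps. To measure such a
network — diameters, lengths, branching, the distance of every tissue
point to its nearest vessel — the image must first be turned into a
geometric network description, the **topology map**: nodes (junctions and
endpoints) and segments (centerline polylines with a radius at every
point).

`vasculonet` implements that pipeline end to end:

1. **Segmentation** — local-mean thresholding; *insideness* gap closing
   (a background voxel is converted when a sufficient fraction of rays
   cast from it hit vessel material within a search radius, which seals
   wall gaps and fills lumina); largest connected component.
2. **Skeletonisation and tracing** — topology-preserving 3D thinning,
   per-voxel radii from the Euclidean distance transform, and conversion
   of the skeleton into a multigraph of segments with junction-artifact
   collapse, spur pruning and tip restoration.
3. **Analytics** — network summaries (counts, diameter/length histograms,
   volume by conical frusta); BFS branch counts from the feeding vessels
   (`|counts[u] − counts[v]| ≤ 1` across every segment); diameter-window
   subnetworks such as putative high-endothelial venules (pHEV: diameter
   16–32 μm, length ≥ 40 μm); organ-region delineation; nearest-vessel
   distance fields on a 4 μm grid with void detection (> 60 μm from any
   vessel); a virtual 2D histology tool; per-block subregion statistics.
4. **Interchange** — ASCII AmiraMesh SpatialGraph (read and write), CMGUI
   exnode/exelem, JSON, CSV attribute tables, multi-page TIFF volumes.
5. **Phantoms** — a parametric generator of branching tube trees with
   exact ground-truth topology, rasterised solid or hollow with seeded
   wall gaps. Every stage of the pipeline is validated against these
   phantoms; no external data is required.

## Worked example

```python
import vasculonet as vn

gt = vn.generate_tree(vn.recovery_spec(seed=1, levels=4))   # ground truth
mask = vn.rasterize(gt, voxel_size=2.0, mode="solid")       # 2 μm voxels
net = vn.extract_topology(mask)                             # topology map
true, found = vn.summarize(gt.topology), vn.summarize(net)
```

Running `python examples/01_phantom_to_topology.py` prints:

```
ground truth : 31 segments, 32 nodes, mean diameter 10.20 um, mean length 66.3 um
re-extracted : 31 segments, 32 nodes, mean diameter 9.43 um, mean length 66.0 um
total volume : truth 183.9 x10^-6 mm3, traced 161.4 x10^-6 mm3
```

The tracer recovered the branching topology exactly (31 segments, 32
nodes); mean diameter agrees to well within one voxel (the radius
estimator quantises at the 2 μm grid) and mean segment length to 0.5%.
The other scripts in `examples/` walk through gap closing
(`02_gap_closing.py` reports 99.5% of true vessel voxels recovered from a
wall-stained volume with 10% staining gaps), branch counts and pHEV
selection, distance fields/voids/histology, and the export formats.

## Command line

A thin CLI mirrors the library for shell pipelines:

```sh
vasculonet phantom --seed 1 --out-volume vol.tif --out-truth truth.json
vasculonet segment vol.tif mask.tif --window 25 --offset 10
vasculonet fill mask.tif filled.tif --max-radius 45 --rays 26 --inside-frac 0.85
vasculonet largest filled.tif net.tif
vasculonet trace net.tif net.json
vasculonet stats net.json --out summary.csv
vasculonet phev net.json phev.json --dmin 16 --dmax 32 --min-length 40
vasculonet distances region.tif net.tif --spacing 4 --void-threshold 60 --out-voids voids.tif
vasculonet run --config pipeline.yaml    # whole pipeline from one config
```

## Network JSON schema

`NetworkTopology` serialises to
`{"voxel_size": μm, "nodes": [{"id", "pos": [x,y,z] μm, "segs": [...]}], "segments": [{"id", "nodes": [a,b], "points": [[x,y,z],...], "radii": [...]}]}`;
segment endpoints coincide with their node positions, self-loops (`a == b`)
and parallel segments are allowed.

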