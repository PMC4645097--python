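"""Nearest-vessel distances, void detection and virtual 2D histology.

Overlays the phantom tissue region with a 4 μm grid, measures the distance
from every interior grid point to the nearest vessel voxel, flags "voids"
farther than 60 μm from any vessel, and sections the network with a single
plane the way a histological slide would.
"""

import numpy as np

import vasculonet as vn

gt = vn.generate_tree(vn.recovery_spec(seed=3, levels=5))
vessels = vn.rasterize(gt, 2.0, "solid")
net = vn.extract_topology(vessels)

# tissue region: close the vessel mask with a 60 μm ball and fill holes
region = vn.ln_region(vessels, closing_radius=60.0)
df = vn.distance_field(region, vessels, spacing=4.0)
voids = vn.find_voids(df, threshold=60.0)

print(f"region voxels: {region.count}, interior grid points: {len(df.points)}")
print(f"mean distance to nearest vessel: {df.mean:.1f} um")
print(f"points within 60 um of a vessel: {100 * df.fraction_within(60.0):.1f}%")
print(f"void grid points (>60 um):       {voids.count}")

z0 = float(np.median([n.position[2] for n in net.nodes.values()]))
hist = vn.histology_2d(net, region, axis="z", coordinate=z0)
print(f"histology plane z={z0:.0f} um: {hist.count} vessel crossings, "
      f"density {hist.density:.0f} /mm2, "
      f"mean crossing diameter {hist.diameters.mean():.1f} um")

# Distances are measured to vessel voxel centers, points inside vessels are
# excluded; the 2D density divides plane crossings by the region's
# cross-section area on that plane.
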