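"""Close staining gaps in hollow vessel walls by insideness filling.

Intraluminal staining marks the vessel wall, not the lumen, and leaves
gaps where the stain did not bind.  This example rasterises a hollow tree
with 10% of its wall carved away in contiguous patches, adds imaging noise,
then runs local thresholding → insideness filling → largest component, and
scores the result against the ideal solid (filled) vessel volume.
"""

import numpy as np

import vasculonet as vn

gt = vn.generate_tree(vn.hollow_spec(seed=11, gap_fraction=0.10))
solid = vn.rasterize(gt, 2.0, "solid")      # the answer we want back
hollow = vn.rasterize(gt, 2.0, "hollow")    # what staining actually shows

rng = np.random.default_rng(11)
image = np.where(hollow.values, 200.0, 10.0) + rng.normal(0, 3, hollow.shape)
vol = vn.VolumeImage(image, voxel_size=2.0)

mask = vn.local_threshold(vol, window_radius=25, offset=20.0)
filled = vn.fill_lumina(mask, **vn.GAP_FILL_PARAMS)
network = vn.largest_component(filled)

true = solid.values
recovered = (network.values & true).sum() / true.sum()
spurious = (network.values & ~true).sum() / true.sum()
net = vn.extract_topology(network)

print(f"wall voxels in stained image : {hollow.count}")
print(f"voxels after gap closing     : {network.count}")
print(f"true solid voxels recovered  : {100 * recovered:.2f}%")
print(f"spurious voxels added        : {100 * spurious:.2f}%")
print(f"connected components traced  : {net.n_components()}")

# Recovery above 99% with a few percent spurious voxels means the wall
# punctures were sealed and the lumina filled; a single component confirms
# the gaps no longer break the network apart.
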