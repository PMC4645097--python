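import numpy as np
import pytest

import vasculonet as vn


@pytest.fixture(scope="session")
def small_tree():
    """A two-level solid tree with well-separated branches."""
    spec = vn.PhantomSpec(seed=3, levels=2, root_radius=8.0, radius_ratio=0.8,
                          segment_length=(45.0, 65.0), branch_angle=(30.0, 50.0),
                          domain_size=(400.0, 400.0, 400.0),
                          root_position=(200.0, 200.0, 30.0),
                          min_separation=20.0)
    return vn.generate_tree(spec)


@pytest.fixture(scope="session")
def small_tree_mask(small_tree):
    return vn.rasterize(small_tree, 2.0, "solid")


@pytest.fixture(scope="session")
def traced_small(small_tree, small_tree_mask):
    return vn.extract_topology(small_tree_mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(20151116)
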