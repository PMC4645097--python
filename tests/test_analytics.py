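import numpy as np
import pytest

import vasculonet as vn
from vasculonet import BinaryMask, NetworkSummary
from helpers import (make_path_network, random_connected_network,
                     exhaustive_min_edge_counts, brute_force_distances,
                     count_plane_crossings, straight_cylinder_mask)


class TestBranchCounts:
    def test_path_graph(self):
        net = make_path_network([(0, 0, 0), (10, 0, 0), (20, 0, 0)])
        bc = vn.branch_counts(net, 0)
        assert bc.counts == {0: 0, 1: 1, 2: 2}
        assert not bc.unreachable

    def test_binary_tree_counts_equal_depth(self):
        gt = vn.generate_tree(vn.recovery_spec(4, levels=4))
        root = 0
        bc = vn.branch_counts(gt.topology, root)
        # depth via parent structure: node i>0 was created at the end of
        # segment i-1; count equals the number of segments up to the root
        g = gt.topology.to_networkx()
        import networkx as nx
        for nid, cnt in bc.counts.items():
            assert cnt == nx.shortest_path_length(g, root, nid)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_exhaustive_enumeration(self, case):
        rng = np.random.default_rng(300 + case)
        net = random_connected_network(rng, int(rng.integers(5, 13)))
        src = int(rng.integers(net.n_nodes))
        bc = vn.branch_counts(net, src)
        oracle = exhaustive_min_edge_counts(net, src)
        assert bc.counts == oracle

    def test_adjacent_counts_differ_by_at_most_one(self, traced_small):
        src = min(traced_small.nodes)
        bc = vn.branch_counts(traced_small, src)
        for s in traced_small.segments.values():
            a, b = s.nodes
            assert abs(bc.counts[a] - bc.counts[b]) <= 1

    def test_unreachable_nodes_flagged(self):
        net = make_path_network([(0, 0, 0), (10, 0, 0)])
        net.add_node((99.0, 99.0, 99.0))   # isolated
        bc = vn.branch_counts(net, 0)
        assert bc.unreachable == {2}
        assert 2 not in bc.counts

    def test_unknown_source_raises(self, traced_small):
        with pytest.raises(KeyError):
            vn.branch_counts(traced_small, -1)

    def test_suggest_feeders_prefers_wide_terminals(self):
        net = make_path_network([(0, 0, 0), (50, 0, 0), (100, 0, 0)])
        net.segments[0].radii[:] = 20.0
        cands = vn.suggest_feeders(net)
        assert cands[0] == 0


def _three_diameter_net():
    net = vn.NetworkTopology(voxel_size=2.0)
    for i in range(6):
        net.add_node((float(50 * i), 0.0, 0.0))
    for i, r in enumerate([5.0, 10.0, 20.0]):
        a, b = 2 * i, 2 * i + 1
        net.add_segment(a, b, [net.nodes[a].position, net.nodes[b].position],
                        [r, r])
    return net   # diameters 10, 20, 40; lengths 50


class TestSelectByDiameter:
    def test_full_window_is_identity(self):
        net = _three_diameter_net()
        out = vn.select_by_diameter(net, 0.0, np.inf, 0.0)
        assert set(out.segments) == set(net.segments)

    def test_window_16_32_keeps_the_20um_segment(self):
        out = vn.select_by_diameter(_three_diameter_net(), 16.0, 32.0)
        assert [s.diameter for s in out.segments.values()] == [20.0]

    def test_orphan_nodes_dropped(self):
        out = vn.select_by_diameter(_three_diameter_net(), 16.0, 32.0)
        assert set(out.nodes) == {2, 3}

    def test_min_length_filter(self):
        out = vn.phev_select(_three_diameter_net(), 16.0, 32.0, min_length=60.0)
        assert out.n_segments == 0

    def test_widening_windows_are_monotone(self, traced_small):
        kept = [set(vn.select_by_diameter(traced_small, 16.0 - w, 32.0 + w).segments)
                for w in (0.0, 4.0, 8.0, 1e6)]
        for small, big in zip(kept, kept[1:]):
            assert small <= big

    def test_exclusion_list(self):
        net = _three_diameter_net()
        out = vn.select_by_diameter(net, 0.0, np.inf, exclude={1})
        assert set(out.segments) == {0, 2}

    def test_phev_preset_on_phantom_matches_truth(self):
        # radii 10, 8, 6.4 μm → diameters 20, 16, 12.8; window [16, 32]
        # must keep exactly generations 0 and 1
        gt = vn.generate_tree(vn.PhantomSpec(
            seed=9, levels=2, root_radius=10.0, radius_ratio=0.8,
            segment_length=(45.0, 60.0), domain_size=(500.0,) * 3,
            root_position=(250.0, 250.0, 40.0), min_separation=20.0))
        expected = {sid for sid, r in gt.radii.items() if 16.0 <= 2 * r <= 32.0}
        out = vn.phev_select(gt.topology, 16.0, 32.0, min_length=40.0)
        assert set(out.segments) == expected

    def test_split_trees_returns_two_largest_components(self):
        net = _three_diameter_net()   # three disjoint segments
        t1, t2 = vn.split_trees(net, dmin=5.0)
        assert t1.n_segments == 1 and t2.n_segments == 1


class TestLnRegion:
    def test_region_is_superset_of_mask(self, small_tree_mask):
        region = vn.ln_region(small_tree_mask, closing_radius=10.0)
        assert not np.any(small_tree_mask.values & ~region.values)

    def test_zero_radius_only_fills_holes(self):
        outer = straight_cylinder_mask(10.0, 40.0, voxel=2.0)
        inner = straight_cylinder_mask(5.0, 40.0, voxel=2.0, half=None)
        inner2 = straight_cylinder_mask(5.0, 40.0, voxel=2.0,
                                        half=(outer.shape[0] - 1) // 2)
        wall = BinaryMask(outer.values & ~inner2.values, 2.0)
        region = vn.ln_region(wall, closing_radius=0.0)
        assert np.all(region.values[outer.values])

    def test_tube_lattice_closing_covers_interior_box(self):
        # parallel tubes 16 μm apart; closing with a 16 μm ball must cover
        # ≥99% of the lattice's bounding box interior
        vals = np.zeros((40, 40, 16), bool)
        idx = np.indices(vals.shape)
        for cx in (4, 12, 20, 28, 36):
            for cy in (4, 12, 20, 28, 36):
                d = np.sqrt((idx[0] - cx) ** 2 + (idx[1] - cy) ** 2)
                vals |= d <= 2.0
        mask = BinaryMask(vals, 2.0)
        region = vn.ln_region(mask, closing_radius=16.0)
        box = np.zeros_like(vals)
        box[4:37, 4:37, 2:14] = True   # interior; tube end faces excluded
        assert region.values[box].mean() >= 0.99


class TestDistanceField:
    def test_point_to_single_voxel_distance(self):
        vessels = np.zeros((30, 30, 30), bool)
        vessels[5, 5, 5] = True
        region = BinaryMask(np.ones((30, 30, 30), bool), 2.0)
        df = vn.distance_field(region, BinaryMask(vessels, 2.0), spacing=2.0)
        # the grid point 10 μm away on-axis
        i = np.flatnonzero((df.indices == [10, 5, 5]).all(axis=1))[0]
        assert df.distances[i] == pytest.approx(10.0)

    @pytest.mark.parametrize("spacing", [4.0, 6.0, 5.0])
    def test_matches_brute_force_on_small_grids(self, spacing, rng):
        for _ in range(6):
            shape = tuple(int(x) for x in rng.integers(12, 33, 3))
            vessels = rng.random(shape) > 0.97
            if not vessels.any():
                vessels[0, 0, 0] = True
            region = rng.random(shape) > 0.2
            vm = BinaryMask(vessels, 2.0)
            df = vn.distance_field(BinaryMask(region, 2.0), vm, spacing=spacing)
            expected = brute_force_distances(df.points, vm)
            assert np.allclose(df.distances, expected, atol=1e-9)

    def test_points_inside_vessels_excluded(self):
        vessels = np.zeros((20, 20, 20), bool)
        vessels[4:10, 4:10, 4:10] = True
        region = BinaryMask(np.ones((20, 20, 20), bool), 2.0)
        df = vn.distance_field(region, BinaryMask(vessels, 2.0), spacing=4.0)
        for ij in df.indices * 2:     # grid index -> voxel index
            assert not vessels[tuple(ij)]

    def test_summary_statistics(self):
        vessels = np.zeros((20, 20, 20), bool)
        vessels[10, 10, 10] = True
        region = BinaryMask(np.ones((20, 20, 20), bool), 2.0)
        df = vn.distance_field(region, BinaryMask(vessels, 2.0), spacing=4.0)
        assert df.fraction_within(np.inf) == 1.0
        counts, _ = df.histogram()
        assert counts.sum() == len(df.distances)
        assert df.mean == pytest.approx(df.distances.mean())

    def test_empty_vessels_rejected(self):
        region = BinaryMask(np.ones((10, 10, 10), bool), 2.0)
        with pytest.raises(ValueError, match="empty vessel"):
            vn.distance_field(region, BinaryMask(np.zeros((10, 10, 10), bool), 2.0))


class TestFindVoids:
    def _df_single_vessel(self):
        vessels = np.zeros((100, 100, 100), bool)
        vessels[50, 50, 50] = True
        region = BinaryMask(np.ones((100, 100, 100), bool), 2.0)
        return vn.distance_field(region, BinaryMask(vessels, 2.0), spacing=4.0)

    def test_threshold_above_max_gives_empty(self):
        df = self._df_single_vessel()
        voids = vn.find_voids(df, threshold=1e6)
        assert voids.count == 0

    def test_counts_match_brute_force(self):
        df = self._df_single_vessel()
        voids = vn.find_voids(df, threshold=60.0)
        assert voids.count == int((df.distances > 60.0).sum())
        assert voids.voxel_size == df.spacing

    def test_tiny_threshold_marks_all_interior_points(self):
        df = self._df_single_vessel()
        voids = vn.find_voids(df, threshold=1e-9)
        assert voids.count == len(df.distances)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            vn.find_voids(self._df_single_vessel(), threshold=0.0)


def _tube_lattice_net(nx_t=3, ny_t=3, pitch=60.0, radius=5.0, height=120.0):
    """Parallel z-tubes on a square lattice."""
    net = vn.NetworkTopology(voxel_size=2.0)
    nid = 0
    for i in range(nx_t):
        for j in range(ny_t):
            x, y = 30.0 + i * pitch, 30.0 + j * pitch
            net.add_node((x, y, 0.0), node_id=nid)
            net.add_node((x, y, height), node_id=nid + 1)
            net.add_segment(nid, nid + 1, [(x, y, 0.0), (x, y, height)],
                            [radius, radius])
            nid += 2
    return net


class TestHistology2D:
    def _region(self, size=100, depth=60):
        return BinaryMask(np.ones((size, size, depth), bool), 2.0)

    def test_perpendicular_tube_crosses_once_with_its_diameter(self):
        net = _tube_lattice_net(1, 1)
        res = vn.histology_2d(net, self._region(), "z", 60.0)
        assert res.count == 1
        assert res.diameters[0] == pytest.approx(10.0)

    def test_u_shape_crosses_twice(self):
        net = vn.NetworkTopology(voxel_size=2.0)
        net.add_node((20.0, 20.0, 100.0))
        net.add_node((60.0, 20.0, 100.0))
        pts = [(20, 20, 100), (20, 20, 20), (40, 20, 10), (60, 20, 20),
               (60, 20, 100)]
        net.add_segment(0, 1, pts, [5.0] * 5)
        res = vn.histology_2d(net, self._region(), "z", 50.0)
        assert res.count == 2

    def test_density_is_tubes_per_area(self):
        net = _tube_lattice_net(3, 3)
        region = self._region(size=100, depth=60)
        res = vn.histology_2d(net, region, "z", 60.0)
        assert res.count == 9
        area_mm2 = (100 * 2.0) ** 2 * 1e-6
        assert res.density == pytest.approx(9 / area_mm2)

    def test_traced_phantom_crossings_match_ground_truth_polylines(
            self, small_tree, traced_small):
        z0 = 150.0
        expected = sum(count_plane_crossings(s.points, 2, z0)
                       for s in small_tree.topology.segments.values())
        region = BinaryMask(np.ones((200, 200, 200), bool), 2.0)
        res = vn.histology_2d(traced_small, region, "z", z0)
        assert res.count == expected

    def test_plane_outside_volume_rejected(self):
        with pytest.raises(IndexError):
            vn.histology_2d(_tube_lattice_net(1, 1), self._region(), "z", 1e5)


class TestRegionStats:
    def _setup(self):
        net = _tube_lattice_net(3, 3, pitch=60.0, height=120.0)
        vessels = np.zeros((100, 100, 60), bool)
        idx = np.indices(vessels.shape)
        for i in range(3):
            for j in range(3):
                d = np.sqrt((idx[0] * 2.0 - (30 + 60 * i)) ** 2
                            + (idx[1] * 2.0 - (30 + 60 * j)) ** 2)
                vessels |= d <= 5.0
        region = BinaryMask(np.ones((100, 100, 60), bool), 2.0)
        df = vn.distance_field(region, BinaryMask(vessels, 2.0), spacing=4.0)
        return net, df

    def test_global_block_counts_all_segments(self):
        net, df = self._setup()
        rs = vn.region_stats(net, df, (0, 0, 0), (200, 200, 130))
        assert rs.n_segments == 9
        vol_mm3 = 200 * 200 * 130 / 1e9
        assert rs.density_3d == pytest.approx(9 / vol_mm3)

    def test_disjoint_blocks_partition_segments(self):
        net, df = self._setup()
        left = vn.region_stats(net, df, (0, 0, 0), (100, 200, 130))
        right = vn.region_stats(net, df, (100, 0, 0), (100, 200, 130))
        assert left.n_segments + right.n_segments == 9

    def test_2d_density_matches_analytic_lattice(self):
        net, df = self._setup()
        rs = vn.region_stats(net, df, (0, 0, 0), (180, 180, 120))
        assert rs.density_2d == pytest.approx(9 / (180 * 180 * 1e-6))

    def test_empty_block_rejected(self):
        net, df = self._setup()
        with pytest.raises(ValueError):
            vn.region_stats(net, df, (1e5, 1e5, 1e5), (10, 10, 10))


class TestTableRatioReport:
    def test_simple_arithmetic(self):
        total = NetworkSummary(1000, 800, 10.0, 50.0, 5.0, 0.2)
        sub = NetworkSummary(100, 80, 15.0, 100.0, 1.0, 0.05)
        rep = vn.table_ratio_report(total, sub, organ_volume_mm3=2.0)
        assert rep["segments_pct"] == 10
        assert rep["nodes_pct"] == 10
        assert rep["mean_diameter_pct"] == 150
        assert rep["mean_length_pct"] == 200
        assert rep["length_pct"] == 20.0
        assert rep["volume_pct"] == 25
        assert rep["total_organ_volume_pct"] == 10.0
        assert rep["sub_organ_volume_pct"] == 2.5
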