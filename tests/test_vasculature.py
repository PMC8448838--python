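"""Segmentation, skeleton tracing, the synthetic phantom, and grid embedding."""

import numpy as np
import pytest

import tmesim as ts
from tmesim import vasculature as vasc


def brute_force_two_means(values):
    """Exhaustive optimal 1-D 2-means split over all threshold positions."""
    v = np.sort(values)
    best, best_cost = None, np.inf
    for cut in range(1, v.size):
        lo, hi = v[:cut], v[cut:]
        cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if cost < best_cost:
            best_cost, best = cost, (v[cut - 1] + v[cut]) / 2.0
    return best  # midpoint threshold of the optimal split


class TestKMeansSegment:
    def test_two_level_image_is_midpoint_threshold(self):
        img = np.full((20, 20), 10.0)
        img[5:15, 8:12] = 240.0
        mask = vasc.kmeans_segment(vasc.GrayImage(img))
        assert (mask == (img > 125)).all()

    def test_matches_exhaustive_two_means(self, rng):
        values = np.concatenate([rng.normal(20, 3, 500), rng.normal(200, 10, 500)])
        values = np.clip(values, 0, None)
        img = vasc.GrayImage(values.reshape(25, 40))
        mask = vasc.kmeans_segment(img, rng=rng)
        threshold = brute_force_two_means(values)
        assert (mask.reshape(-1) == (values > threshold)).all()

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            vasc.kmeans_segment(vasc.GrayImage(np.eye(4)), k=1)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            vasc.kmeans_segment(vasc.GrayImage(np.full((5, 5), 3.0)))

    def test_invariant_under_affine_rescaling(self):
        img = np.full((10, 10), 10.0)
        img[2:8, 4:6] = 240.0
        m1 = vasc.kmeans_segment(vasc.GrayImage(img))
        m2 = vasc.kmeans_segment(vasc.GrayImage(img * 3.0 + 7.0))
        assert (m1 == m2).all()

    def test_bandpass_suppresses_out_of_window(self):
        img = np.full((10, 10), 10.0)
        img[2:8, 4:6] = 240.0
        img[0, 0] = 900.0  # bright artifact outside the window
        mask = vasc.kmeans_segment(vasc.GrayImage(img, bandpass=(100, 500)))
        assert not mask[0, 0]
        assert mask[5, 4]


class TestExtractNetwork:
    def test_straight_line(self):
        mask = np.zeros((10, 20), dtype=bool)
        mask[5, 3:13] = True  # 10 pixels
        net = vasc.extract_network(mask, pixel_um=20.0)
        assert len(net.segments) == 1
        assert net.segments[0].length_um == pytest.approx(180.0)  # 9 gaps
        assert len(net.tip_nodes) == 2
        assert len(net.branch_points) == 0

    def test_y_junction(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[15, 5:15] = True  # west arm, 10 px
        rr = np.arange(10)
        mask[15 - 1 - rr, 15 + rr] = True  # northeast arm
        mask[15 + 1 + rr, 15 + rr] = True  # southeast arm
        mask[15, 15] = True  # junction pixel
        net = vasc.extract_network(mask, pixel_um=20.0)
        assert len(net.branch_points) == 1
        assert len(net.tip_nodes) == 3
        assert len(net.segments) == 3

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        net = vasc.extract_network(mask)
        assert len(net.nodes) == 1
        assert len(net.segments) == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vasc.extract_network(np.zeros((4, 4), dtype=bool))


class TestSynthPhantom:
    def test_seeded_determinism(self):
        p = vasc.PhantomParams()
        img1, _ = vasc.synth_phantom(p, np.random.default_rng(5))
        img2, _ = vasc.synth_phantom(p, np.random.default_rng(5))
        assert (img1.pixels == img2.pixels).all()

    def test_zero_branch_probability_gives_no_branch_points(self):
        p = vasc.PhantomParams(branch_prob=0.0)
        _, net = vasc.synth_phantom(p, np.random.default_rng(2))
        assert len(net.branch_points) == 0

    def test_zero_trunks_rejected(self):
        with pytest.raises(ValueError):
            vasc.synth_phantom(vasc.PhantomParams(n_trunks=0),
                               np.random.default_rng(0))

    @pytest.mark.parametrize("seed", [3, 7, 11])
    def test_roundtrip_recovers_topology(self, seed):
        """Noise-free phantom: segment+extract matches the generator graph."""
        img, truth = vasc.synth_phantom(vasc.PhantomParams(), np.random.default_rng(seed))
        mask = vasc.kmeans_segment(img, rng=np.random.default_rng(0))
        net = vasc.extract_network(mask, img.pixel_um)
        assert len(net.branch_points) == len(truth.branch_points)
        assert len(net.tip_nodes) == len(truth.tip_nodes)

    def test_network_file_round_trip(self, tmp_path, phantom_pair):
        _, net = phantom_pair
        net.save(tmp_path / "net")
        loaded = vasc.VesselNetwork.load(tmp_path / "net")
        assert len(loaded.segments) == len(net.segments)
        assert loaded.total_length_um == pytest.approx(net.total_length_um)
        assert len(loaded.branch_points) == len(net.branch_points)


class TestEmbedNetwork:
    def _net(self, points_cm, edges):
        net = vasc.VesselNetwork()
        for x, y in points_cm:
            net.add_node(x, y)
        for a, b, label in edges:
            xa, ya = net.nodes[a]
            xb, yb = net.nodes[b]
            net.add_segment(a, b, label, np.hypot(xb - xa, yb - ya) * 1e4)
        return net

    def test_segment_spanning_three_tmes(self, tiny_grid):
        # horizontal segment crossing sites (0,0)-(0,2) at y=100µm
        net = self._net([(0.001, 0.001), (0.05, 0.001)], [(0, 1, "stalk")])
        vasc.embed_network(tiny_grid, net)
        for col in range(3):
            assert 0 in tiny_grid.segments_at(0, col)
        assert tiny_grid.stalk_count[0, :3].sum() == 3

    def test_empty_network_is_noop(self, tiny_grid):
        vasc.embed_network(tiny_grid, vasc.VesselNetwork())
        assert tiny_grid.stalk_count.sum() == 0

    def test_diagonal_registers_exactly_diagonal_tmes(self):
        cfg = ts.SimulationConfig(domain_cm=0.2, initial_cells=10)  # 10x10
        grid = ts.build_grid(cfg)
        net = self._net([(0.0, 0.0), (0.2, 0.2)], [(0, 1, "stalk")])
        vasc.embed_network(grid, net)
        sites = set(grid.site_segments)
        assert sites == {(i, i) for i in range(10)}

    def test_out_of_bounds_rejected(self, tiny_grid):
        net = self._net([(0.0, 0.0), (5.0, 5.0)], [(0, 1, "stalk")])
        with pytest.raises(ValueError, match="outside"):
            vasc.embed_network(tiny_grid, net)

    def test_length_conservation(self, phantom_pair):
        """Sum of per-site sub-lengths equals the network total length."""
        img, net = phantom_pair
        cfg = ts.SimulationConfig(domain_cm=0.5, initial_cells=10)
        grid = ts.build_grid(cfg)
        vasc.embed_network(grid, net)
        assert grid._vp_weight.sum() == pytest.approx(net.total_length_um, rel=1e-9)


class TestAssimilation:
    def _toy_net(self, offset_cm=0.0):
        net = vasc.VesselNetwork()
        a = net.add_node(0.01 + offset_cm, 0.01)
        b = net.add_node(0.05 + offset_cm, 0.01)
        net.add_segment(a, b, "stalk", 400.0)
        return net

    def test_merge_idempotent(self):
        net = self._toy_net()
        merged = vasc.merge_networks(net, net, tol_um=200.0)
        assert len(merged.segments) == len(net.segments)

    def test_disjoint_union(self):
        merged = vasc.merge_networks(self._toy_net(), self._toy_net(0.3),
                                     tol_um=200.0)
        assert len(merged.segments) == 2

    def test_duplicate_collapses_to_observed(self):
        current = self._toy_net()
        observed = self._toy_net()
        observed.add_segment(observed.add_node(0.2, 0.2),
                             observed.add_node(0.25, 0.2), "stalk", 500.0)
        merged = vasc.merge_networks(current, observed, tol_um=200.0)
        assert len(merged.segments) == 2  # union size, duplicate collapsed

    def test_empty_observation_is_noop(self, tiny_grid):
        from tmesim.agents import VesselSystem

        vs = VesselSystem(tiny_grid)
        before = vs.n_segments
        vasc.assimilate_network(tiny_grid, vs, vasc.VesselNetwork(), episode=3)
        assert vs.n_segments == before

    def test_assimilation_adds_disjoint_segments(self, tiny_grid):
        from tmesim.agents import VesselSystem

        vs = VesselSystem(tiny_grid)
        vasc.load_vessels_into(tiny_grid, vs, self._toy_net())
        n0 = vs.n_segments
        vasc.assimilate_network(tiny_grid, vs, self._toy_net(0.03), episode=3)
        assert vs.n_segments == n0 + 1
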