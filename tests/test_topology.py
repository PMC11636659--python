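"""Skeleton pixel classification, node clustering, and branching metrics."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from octamorph import DataError, classify_skeleton, branching_metrics, skeletonize
from octamorph.regions import RegionPartition
from octamorph.topology import BRANCH, ENDPOINT, ISOLATED, ORDINARY
from tests.conftest import random_blob_mask


def brute_force_classes(sk):
    """Independent per-pixel 8-neighbour scan."""
    H, W = sk.shape
    out = np.full((H, W), -1, dtype=int)
    for r in range(H):
        for c in range(W):
            if not sk[r, c]:
                continue
            n = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < H and 0 <= cc < W and sk[rr, cc]:
                        n += 1
            out[r, c] = {0: ISOLATED, 1: ENDPOINT, 2: ORDINARY}.get(n, BRANCH)
    return out


def full_partition(shape):
    return RegionPartition(
        fovea_mask=np.ones(shape, dtype=bool),
        parafovea_mask=np.zeros(shape, dtype=bool),
        center_px=(shape[0] / 2, shape[1] / 2),
    )


class TestClassify:
    def test_straight_line(self):
        sk = np.zeros((5, 12), dtype=bool)
        sk[2, 2:10] = True
        topo = classify_skeleton(sk)
        assert topo.n_endpoints == 2
        assert topo.n_nodes == 0
        assert (topo.pixel_class[2, 3:9] == ORDINARY).all()

    def test_y_shape(self):
        sk = np.zeros((12, 12), dtype=bool)
        sk[6, 1:6] = True            # stem
        for i in range(1, 5):        # two diagonal arms
            sk[6 - i, 5 + i] = True
            sk[6 + i, 5 + i] = True
        topo = classify_skeleton(sk)
        assert topo.n_endpoints == 3
        assert topo.n_nodes == 1

    def test_closed_ring_all_ordinary(self):
        rr, cc = np.mgrid[0:21, 0:21]
        d = np.hypot(rr - 10, cc - 10)
        ring = skeletonize((d >= 5) & (d <= 7))
        topo = classify_skeleton(ring)
        assert topo.n_endpoints == 0
        assert topo.n_nodes == 0
        assert (topo.pixel_class[ring] == ORDINARY).all()

    def test_isolated_pixel_counts_as_endpoint(self):
        sk = np.zeros((8, 8), dtype=bool)
        sk[3, 3] = True
        topo = classify_skeleton(sk)
        assert topo.pixel_class[3, 3] == ISOLATED
        assert topo.n_endpoints == 1

    def test_non_thin_skeleton_rejected(self):
        sk = np.zeros((6, 6), dtype=bool)
        sk[2:4, 2:4] = True
        with pytest.raises(DataError):
            classify_skeleton(sk)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_thin_skeletons(self, seed):
        rng = np.random.default_rng(seed)
        sk = skeletonize(random_blob_mask(rng, size=72))
        topo = classify_skeleton(sk)
        np.testing.assert_array_equal(topo.pixel_class, brute_force_classes(sk))

    def test_cluster_count_bounded_by_branch_pixels(self, skel_256):
        topo = classify_skeleton(skel_256)
        assert topo.n_nodes <= int(topo.branch_pixel_mask.sum())


class TestBranchingMetrics:
    def test_density_is_count_over_length(self):
        sk = np.zeros((12, 12), dtype=bool)
        sk[6, 1:6] = True
        for i in range(1, 5):
            sk[6 - i, 5 + i] = True
            sk[6 + i, 5 + i] = True
        topo = classify_skeleton(sk)
        parts = full_partition(sk.shape)
        out = branching_metrics(topo, parts, {"fovea": 0.5, "parafovea": 0.0},
                                region_names=("fovea",))
        assert out["fovea"]["BNN"] == 1
        assert out["fovea"]["BND_per_mm"] == pytest.approx(2.0)
        assert out["fovea"]["EPN"] == 3
        assert out["fovea"]["EPD_per_mm"] == pytest.approx(6.0)

    def test_empty_region_zero_counts(self):
        sk = np.zeros((8, 8), dtype=bool)
        sk[4, 1:7] = True
        topo = classify_skeleton(sk)
        parts = full_partition(sk.shape)
        out = branching_metrics(topo, parts, {"fovea": 1.0, "parafovea": 1.0})
        assert out["parafovea"]["EPN"] == 0
        assert out["parafovea"]["EPD_per_mm"] == 0.0

    def test_recovers_truth_counts_within_ten_percent(self, net_256, skel_256):
        topo = classify_skeleton(skel_256)
        parts = full_partition(skel_256.skeleton.shape)
        from octamorph import vessel_length

        vl = {"fovea": vessel_length(skel_256, parts.fovea_mask),
              "parafovea": 0.0}
        out = branching_metrics(topo, parts, vl, region_names=("fovea",))
        assert len(net_256.nodes) >= 20
        assert abs(out["fovea"]["BNN"] - len(net_256.nodes)) <= 0.1 * len(net_256.nodes)
        assert abs(out["fovea"]["EPN"] - len(net_256.endpoints)) <= 0.1 * len(net_256.endpoints)

    def test_tree_handshake_identity_on_truth_networks(self, growth_256):
        """On cycle-free networks EPN = sum(degree-2 over nodes) + 2*components."""
        from dataclasses import replace
        from octamorph import grow_network

        p = replace(growth_256, perifoveal_ring=False, gap_fill=False, n_roots=6)
        for seed in range(5):
            net = grow_network(p, seed=seed)
            deg = {}
            for s in net.segments:
                for pt in (s.start, s.end):
                    k = (round(pt[0], 4), round(pt[1], 4))
                    deg[k] = deg.get(k, 0) + 1
            n_comp = len({_root(net, i) for i in range(len(net.segments))})
            lhs = len(net.endpoints)
            rhs = sum(d - 2 for d in deg.values() if d >= 3) + 2 * n_comp
            assert lhs == rhs


def _root(net, i):
    while net.segments[i].parent is not None:
        i = net.segments[i].parent
    return i
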