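"""Generator contracts: exact topology bookkeeping, degradation semantics,
rasterization truth masks, and seed determinism."""

import numpy as np
import pytest

from octamorph import (
    ConfigurationError,
    DegradationConfig,
    GrowthParams,
    degrade,
    grow_network,
    rasterize,
)
from octamorph.synthetic import Segment, GroundTruthNetwork


def brute_force_degrees(net):
    """Independent adjacency oracle: count segment-end incidences per
    coordinate by scanning every polyline end."""
    deg = {}
    for s in net.segments:
        for pt in (tuple(np.round(s.points[0], 4)), tuple(np.round(s.points[-1], 4))):
            deg[pt] = deg.get(pt, 0) + 1
    return deg


def line_network(length=40, size=256):
    pts = np.stack([np.full(length, 100.0), 50.0 + np.arange(length)], axis=1)
    net = GroundTruthNetwork(
        segments=[Segment(points=pts, width_px=3.0)],
        size_px=size,
        faz_center_px=(200.0, 200.0),
        faz_radius_mm=0.1,
    )
    net.annotate()
    return net


class TestGrowth:
    def test_unbranched_single_root(self):
        p = GrowthParams(n_roots=1, branch_prob=0.0, perifoveal_ring=False,
                         gap_fill=False, size_px=256).scaled(256)
        net = grow_network(p, seed=3)
        assert len(net.nodes) == 0
        assert len(net.endpoints) == 2
        assert len(net.segments) == 1

    def test_single_forced_bifurcation_is_y_shape(self):
        p = GrowthParams(n_roots=1, branch_prob=1.0, max_depth=1,
                         perifoveal_ring=False, gap_fill=False, size_px=256)
        net = grow_network(p, seed=5)
        assert len(net.nodes) == 1
        assert len(net.endpoints) == 3
        deg = brute_force_degrees(net)
        assert sorted(deg.values()) == [1, 1, 1, 3]

    def test_annotations_match_adjacency_oracle(self, growth_256):
        for seed in range(10):
            net = grow_network(growth_256, seed=seed)
            deg = brute_force_degrees(net)
            assert sorted(net.nodes) == sorted(k for k, d in deg.items() if d >= 3)
            assert sorted(net.endpoints) == sorted(k for k, d in deg.items() if d == 1)

    def test_seed_determinism(self, growth_256):
        a = grow_network(growth_256, seed=11)
        b = grow_network(growth_256, seed=11)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
        assert a.nodes == b.nodes and a.endpoints == b.endpoints

    def test_invariants_inside_field_and_faz(self, net_256):
        size = net_256.size_px
        faz_r = net_256.faz_radius_px
        cr, cc = net_256.faz_center_px
        for s in net_256.segments:
            assert (s.points >= 0).all() and (s.points <= size - 1).all()
            d = np.hypot(s.points[:, 0] - cr, s.points[:, 1] - cc)
            assert (d >= faz_r).all(), "segment crosses the FAZ disc interior"
            assert 1.0 <= s.width_px <= 10.0

    def test_oversized_faz_rejected(self):
        with pytest.raises(ConfigurationError):
            grow_network(GrowthParams(faz_radius_mm=2.0), seed=0)


class TestDegrade:
    def test_identity_config(self, net_256):
        out = degrade(net_256, DegradationConfig(seed=0))
        assert len(out.segments) == len(net_256.segments)
        assert out.nodes == net_256.nodes
        assert out.endpoints == net_256.endpoints

    def test_planted_fragment_count(self, net_256):
        out = degrade(net_256, DegradationConfig(n_fragments=7, seed=1))
        assert len(out.fragments) == len(net_256.fragments) + 7

    def test_fragments_isolated_from_everything(self, net_256):
        out = degrade(net_256, DegradationConfig(n_fragments=6, seed=2))
        frag_ids = set(out.fragments)
        others = np.concatenate(
            [s.points for i, s in enumerate(out.segments) if i not in frag_ids]
        )
        for i in frag_ids:
            s = out.segments[i]
            d = np.hypot(
                s.points[:, None, 0] - others[None, :, 0],
                s.points[:, None, 1] - others[None, :, 1],
            )
            assert d.min() > 2.0

    def test_node_count_monotone_in_prune_fraction(self, net_256):
        counts = []
        for frac in (0.0, 0.2, 0.5, 0.8, 1.0):
            out = degrade(net_256, DegradationConfig(prune_fraction=frac, seed=9))
            counts.append(len(out.nodes))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_full_prune_of_binary_tree_leaves_root_path(self):
        p = GrowthParams(n_roots=1, branch_prob=1.0, max_depth=3,
                         perifoveal_ring=False, gap_fill=False, size_px=256)
        net = grow_network(p, seed=4)
        assert len(net.nodes) > 0
        out = degrade(net, DegradationConfig(prune_fraction=1.0, seed=0))
        # oracle: iteratively strip leaf segments until a fixpoint
        segs = {i: s for i, s in enumerate(net.segments)}
        while True:
            children = {i: [] for i in segs}
            for i, s in segs.items():
                if s.parent in segs:
                    children[s.parent].append(i)
            leaves = [i for i, s in segs.items()
                      if s.parent is not None and not children[i]]
            if not leaves:
                break
            for i in leaves:
                del segs[i]
        assert len(out.segments) == len(segs)
        assert len(out.nodes) == 0

    def test_degrade_deterministic(self, net_256):
        cfg = DegradationConfig(prune_fraction=0.3, n_fragments=5, seed=13)
        a, b = degrade(net_256, cfg), degrade(net_256, cfg)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            DegradationConfig(prune_fraction=1.5)
        with pytest.raises(ConfigurationError):
            DegradationConfig(n_fragments=-1)


class TestRasterize:
    def test_horizontal_line_band(self):
        net = line_network(length=40)
        ras = rasterize(net)
        rows = np.unique(np.nonzero(ras.vessel_mask)[0])
        assert set(rows) == {99, 100, 101}  # 3-px band for width 3

    def test_empty_network_black_image(self):
        net = GroundTruthNetwork(segments=[], size_px=128,
                                 faz_center_px=(63.5, 63.5))
        ras = rasterize(net)
        assert not ras.vessel_mask.any()
        assert ras.angiogram.intensity.max() == 0.0

    def test_noise_affects_intensities_only(self, net_256):
        clean = rasterize(net_256, noise_sigma=0.0)
        noisy = rasterize(net_256, noise_sigma=0.1, seed=5)
        np.testing.assert_array_equal(clean.vessel_mask, noisy.vessel_mask)
        np.testing.assert_array_equal(clean.faz_mask, noisy.faz_mask)
        assert not np.array_equal(clean.angiogram.intensity,
                                  noisy.angiogram.intensity)

    def test_support_equals_mask_at_zero_noise(self, raster_256):
        support = raster_256.angiogram.intensity > 0
        np.testing.assert_array_equal(support, raster_256.vessel_mask)

    def test_rasterized_fragments_are_disjoint_components(self, net_256):
        from scipy import ndimage as ndi

        out = degrade(net_256, DegradationConfig(n_fragments=5, seed=3))
        ras = rasterize(out)
        lbl, _ = ndi.label(ras.vessel_mask, structure=np.ones((3, 3)))
        frag_labels = set()
        main_labels = set()
        for i, s in enumerate(out.segments):
            pix = np.round(s.points).astype(int)
            labels = set(lbl[pix[:, 0], pix[:, 1]]) - {0}
            (frag_labels if s.is_fragment else main_labels).update(labels)
        assert frag_labels.isdisjoint(main_labels)

    def test_too_small_raster_rejected(self):
        net = GroundTruthNetwork(segments=[], size_px=32)
        with pytest.raises(ConfigurationError):
            rasterize(net)
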