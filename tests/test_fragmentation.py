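"""Isolated-segment detection, the k x VAD threshold, and the multiplier sweep."""

import numpy as np
import pytest

from octamorph import (
    DegradationConfig,
    classify_skeleton,
    degrade,
    fragmentation_metrics,
    isolated_segments,
    multiplier_sweep,
    rasterize,
    skeletonize,
    radius_weighted_skeleton,
    vessel_length,
)
from octamorph.core import ConfigurationError, DataError
from octamorph.fragmentation import SegmentSet, IsolatedSegment, loo_threshold_accuracy
from octamorph.skeleton import SkeletonMap


def make_skel(sk, pitch=10.0):
    return SkeletonMap(skeleton=sk, radius_px=np.where(sk, 1.0, 0.0),
                       pixel_pitch_um=pitch)


def seg_set(lengths_px, pitch=1.0):
    segs = [IsolatedSegment(pixels=np.zeros((1, 2), int), length_px=l,
                            centroid_px=(0.0, 0.0)) for l in lengths_px]
    return SegmentSet(segments=segs, pixel_pitch_um=pitch)


class TestIsolatedSegments:
    def test_floating_line_beside_tree(self):
        sk = np.zeros((20, 30), dtype=bool)
        sk[2, 3:13] = True          # floating 10-px line
        sk[10, 2:20] = True         # tree stem
        for i in range(1, 6):       # two arms -> stem contains a branch pixel
            sk[10 - i, 19 + i] = True
            sk[10 + i, 19 + i] = True
        skm = make_skel(sk)
        topo = classify_skeleton(skm)
        out = isolated_segments(skm, topo)
        assert len(out.segments) == 1
        assert out.segments[0].length_px == pytest.approx(9.0)

    def test_ring_counts_as_isolated(self):
        rr, cc = np.mgrid[0:21, 0:21]
        d = np.hypot(rr - 10, cc - 10)
        ring = skeletonize((d >= 5) & (d <= 7))
        skm = make_skel(ring)
        out = isolated_segments(skm, classify_skeleton(skm))
        assert len(out.segments) == 1

    def test_strict_mode_returns_every_component(self):
        sk = np.zeros((10, 20), dtype=bool)
        sk[2, 2:8] = True
        sk[6, 2:18] = True
        skm = make_skel(sk)
        topo = classify_skeleton(skm)
        assert len(isolated_segments(skm, topo, strict_components=True).segments) == 2

    def test_planted_fragments_recovered_exactly(self, net_256):
        out = degrade(net_256, DegradationConfig(n_fragments=7, seed=5))
        ras = rasterize(out)
        sk = skeletonize(ras.vessel_mask)
        skm = radius_weighted_skeleton(ras.vessel_mask, sk, out.pixel_pitch_um)
        iso = isolated_segments(skm, classify_skeleton(skm))
        assert len(iso.segments) == 7


class TestFragmentationMetrics:
    def test_short_segment_below_threshold_counted(self):
        segs = seg_set([10.0])  # 10 um at pitch 1
        out = fragmentation_metrics(segs, vad_um=20.0, vl_mm={"image": 1.0},
                                    k=30, region_names=("image",))
        assert out["image"]["FVSC"] == 1

    def test_threshold_below_length_not_counted(self):
        segs = seg_set([10.0])
        out = fragmentation_metrics(segs, vad_um=20.0, vl_mm={"image": 1.0},
                                    k=0.4, region_names=("image",))
        assert out["image"]["FVSC"] == 0

    def test_fvlr_is_length_fraction(self):
        segs = seg_set([100.0, 200.0])  # 300 um of fragments
        out = fragmentation_metrics(segs, vad_um=50.0, vl_mm={"image": 3.0},
                                    k=30, region_names=("image",))
        assert out["image"]["FVLR"] == pytest.approx(300.0 / 3000.0)

    def test_missing_vad_rejected(self):
        with pytest.raises(DataError):
            fragmentation_metrics(seg_set([5.0]), vad_um=float("nan"),
                                  vl_mm={"image": 1.0}, region_names=("image",))

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ConfigurationError):
            fragmentation_metrics(seg_set([5.0]), vad_um=10.0,
                                  vl_mm={"image": 1.0}, k=0.0,
                                  region_names=("image",))

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        segs = seg_set(list(rng.uniform(5, 400, size=30)))
        prev_c, prev_r = -1, -1.0
        for k in range(2, 101, 7):
            out = fragmentation_metrics(segs, vad_um=3.0, vl_mm={"image": 0.01},
                                        k=k, region_names=("image",))
            assert out["image"]["FVSC"] >= prev_c
            assert out["image"]["FVLR"] >= prev_r - 1e-12
            prev_c, prev_r = out["image"]["FVSC"], out["image"]["FVLR"]

    def test_planted_length_fraction_recovered(self, net_256):
        out = degrade(net_256, DegradationConfig(n_fragments=7, seed=8))
        ras = rasterize(out)
        sk = skeletonize(ras.vessel_mask)
        skm = radius_weighted_skeleton(ras.vessel_mask, sk, out.pixel_pitch_um)
        topo = classify_skeleton(skm)
        iso = isolated_segments(skm, topo)
        from octamorph import vessel_average_diameter

        vad = vessel_average_diameter(skm)
        vl = vessel_length(skm, np.ones_like(sk, dtype=bool))
        fm = fragmentation_metrics(iso, vad, {"image": vl}, k=30,
                                   region_names=("image",))
        truth = out.fragment_length_px() / out.total_length_px()
        assert fm["image"]["FVLR"] == pytest.approx(truth, rel=0.05)


class TestSweep:
    def test_identical_groups_near_chance(self):
        rng = np.random.default_rng(1)
        lengths = [list(rng.uniform(5, 80, 6)) for _ in range(12)]
        sets = [seg_set(l) for l in lengths]
        labels = ["A"] * 6 + ["B"] * 6
        # group B has the same length distribution as A
        curve = multiplier_sweep(sets, [3.0] * 12, [0.01] * 12, labels,
                                 ks=np.arange(2, 101, 14))
        assert curve["accuracy"].mean() <= 0.75

    def test_separable_groups_found(self):
        healthy = [seg_set([200.0]) for _ in range(6)]
        sick = [seg_set([10.0, 12.0, 15.0, 200.0]) for _ in range(6)]
        curve = multiplier_sweep(healthy + sick, [3.0] * 12, [0.01] * 12,
                                 ["A"] * 6 + ["B"] * 6,
                                 ks=np.arange(2, 40, 4))
        assert curve["accuracy"].max() == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(DataError):
            multiplier_sweep([seg_set([5.0])] * 4, [3.0] * 4, [1.0] * 4,
                             ["A"] * 4)

    def test_loo_threshold_classifier_on_separated_data(self):
        x = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        y = np.array([0, 0, 0, 1, 1, 1])
        assert loo_threshold_accuracy(x, y) == 1.0
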