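"""Fragmented-vessel metrics: FVSC, FVLR, and the multiplier sweep.

An *isolated segment* is an 8-connected component of the skeleton that
contains no branch pixel — a free-floating unbranched snippet (a closed
ring with no branch pixels also qualifies).  A segment is *fragmented* when
its geodesic length falls below ``k x VAD`` (both in micrometres; the
multiplier k defaults to 30).  FVSC counts fragmented segments per region;
FVLR is their total length divided by the region's vessel length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import ConfigurationError, DataError
from .metrics import vessel_length_px
from .skeleton import SkeletonMap
from .topology import SkeletonTopology

_NEIGH8 = np.ones((3, 3), dtype=bool)

DEFAULT_MULTIPLIER = 30.0


@dataclass
class IsolatedSegment:
    pixels: np.ndarray  # (n, 2) int coordinates
    length_px: float
    centroid_px: tuple[float, float]


@dataclass
class SegmentSet:
    segments: list[IsolatedSegment]
    pixel_pitch_um: float

    def lengths_um(self) -> np.ndarray:
        return np.array([s.length_px for s in self.segments]) * self.pixel_pitch_um


def isolated_segments(
    skel: SkeletonMap,
    topo: SkeletonTopology,
    strict_components: bool = False,
) -> SegmentSet:
    """Find free-floating skeleton segments.

    By default a component qualifies only if it contains no branch pixel;
    ``strict_components=True`` returns every component regardless (in which
    case a whole plexus counts as one segment).
    """
    sk = skel.skeleton
    lbl, n = ndi.label(sk, structure=_NEIGH8)
    segs: list[IsolatedSegment] = []
    branch = topo.branch_pixel_mask
    for i in range(1, n + 1):
        comp = lbl == i
        if not strict_components and (branch & comp).any():
            continue
        pix = np.argwhere(comp)
        segs.append(
            IsolatedSegment(
                pixels=pix,
                length_px=vessel_length_px(comp),
                centroid_px=tuple(pix.mean(axis=0)),
            )
        )
    return SegmentSet(segments=segs, pixel_pitch_um=skel.pixel_pitch_um)


def fragmentation_metrics(
    segs: SegmentSet,
    vad_um: float,
    vl_mm: dict[str, float],
    regions=None,
    k: float = DEFAULT_MULTIPLIER,
    region_names: tuple[str, ...] = ("fovea", "parafovea"),
) -> dict[str, dict[str, float]]:
    """FVSC and FVLR per region.

    A segment belongs to the region containing its centroid pixel.  FVSC
    counts segments with length < ``k x VAD`` (micrometres); FVLR divides
    their total length by the region's VL.  The VAD reference is the
    layer-level VAD of the analyzed image.
    """
    if not np.isfinite(vad_um) or vad_um <= 0:
        raise DataError("VAD reference missing or non-positive")
    if k <= 0:
        raise ConfigurationError("multiplier k must be positive")
    thresh_um = k * vad_um
    out: dict[str, dict[str, float]] = {}
    for name in region_names:
        if regions is None or name == "image":
            in_region = [True] * len(segs.segments)
        else:
            region = regions.region(name)
            in_region = []
            for s in segs.segments:
                r = int(np.clip(round(s.centroid_px[0]), 0, region.shape[0] - 1))
                c = int(np.clip(round(s.centroid_px[1]), 0, region.shape[1] - 1))
                in_region.append(bool(region[r, c]))
        lengths = np.array([s.length_px for s in segs.segments]) * segs.pixel_pitch_um
        sel = np.array(in_region, dtype=bool) if in_region else np.zeros(0, bool)
        frag = sel & (lengths < thresh_um) if len(lengths) else np.zeros(0, bool)
        fvsc = int(frag.sum())
        vl_um = vl_mm[name] * 1000.0
        fvlr = float(lengths[frag].sum() / vl_um) if vl_um > 0 else float("nan")
        out[name] = {"FVSC": fvsc, "FVLR": fvlr}
    return out


# --------------------------------------------------------------------------
# multiplier sweep
# --------------------------------------------------------------------------


def loo_threshold_accuracy(x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out accuracy of a univariate threshold classifier.

    For each held-out sample the threshold (and polarity) maximizing
    training accuracy over midpoints of the sorted training values is
    chosen; the held-out sample is then scored.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(x)
    correct = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        xt, yt = x[tr], y[tr]
        order = np.argsort(xt, kind="stable")
        xs = xt[order]
        cands = np.concatenate([[xs[0] - 1.0], (xs[:-1] + xs[1:]) / 2.0, [xs[-1] + 1.0]])
        best_acc, best_thr, best_pol = -1.0, 0.0, +1
        for thr in cands:
            for pol in (+1, -1):
                pred = (xt * pol) > (thr * pol)
                acc = float((pred == (yt == 1)).mean())
                if acc > best_acc:
                    best_acc, best_thr, best_pol = acc, thr, pol
        pred_i = (x[i] * best_pol) > (best_thr * best_pol)
        correct += int(pred_i == (y[i] == 1))
    return correct / n


def multiplier_sweep(
    seg_sets: list[SegmentSet],
    vad_um: list[float],
    vl_mm: list[float],
    labels: list[str],
    ks: np.ndarray | None = None,
    feature: str = "FVLR",
) -> "pd.DataFrame":
    """Sweep the VAD multiplier k and score how well the fragmentation
    feature separates the groups (pairwise-averaged leave-one-out accuracy
    of a threshold classifier).  Returns a (k, accuracy) table; the optimum
    is the argmax row.
    """
    import pandas as pd

    labels = list(labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise DataError("multiplier sweep needs at least two groups")
    if ks is None:
        ks = np.arange(2, 101)
    vad = np.asarray(vad_um, dtype=float)
    vl_um = np.asarray(vl_mm, dtype=float) * 1000.0
    lengths = [s.lengths_um() for s in seg_sets]

    rows = []
    for k in ks:
        feats = np.empty(len(seg_sets))
        for i, L in enumerate(lengths):
            frag = L[L < k * vad[i]] if len(L) else L
            if feature == "FVSC":
                feats[i] = len(frag)
            else:
                feats[i] = frag.sum() / vl_um[i] if vl_um[i] > 0 else 0.0
        accs = []
        for a in range(len(uniq)):
            for b in range(a + 1, len(uniq)):
                sel = np.array([l in (uniq[a], uniq[b]) for l in labels])
                ybin = np.array([1 if l == uniq[b] else 0 for l in labels])[sel]
                accs.append(loo_threshold_accuracy(feats[sel], ybin))
        rows.append({"k": float(k), "accuracy": float(np.mean(accs))})
    return pd.DataFrame(rows)
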