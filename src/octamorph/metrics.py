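"""Vessel length, average diameter, density, and the local density map.

Length is geodesic over the skeleton graph: each pair of 8-adjacent
skeleton pixels contributes one step of 1 px (lateral) or sqrt(2) px
(diagonal); a diagonal step is skipped when the two pixels share a common
lateral neighbour on the skeleton (the two lateral steps already cover it).
Steps straddling a region boundary are assigned to the region containing
the rounded step midpoint.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import ConfigurationError, DataError, as_bool_mask
from .skeleton import SkeletonMap

SQRT2 = float(np.sqrt(2.0))

# offsets: (dr, dc, step length); each undirected edge counted once
_LATERAL = ((0, 1), (1, 0))
_DIAGONAL = ((1, 1), (1, -1))


def _shift_pair(sk: np.ndarray, dr: int, dc: int):
    """Boolean grid of 'pixel (r, c) and pixel (r+dr, c+dc) both set',
    aligned with (r, c); also returns the slicing needed to index the
    partner pixel."""
    H, W = sk.shape
    a = np.zeros_like(sk)
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a[r0:r1, c0:c1] = sk[r0:r1, c0:c1] & sk[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a


def _edge_masks(sk: np.ndarray):
    """Yield (pair_mask, length, mid_dr, mid_dc) for each edge family.
    ``mid_dr/mid_dc`` locate the rounded midpoint pixel relative to (r, c)."""
    for dr, dc in _LATERAL:
        yield _shift_pair(sk, dr, dc), 1.0, dr, max(dc, 0)
    # diagonal edges, excluding corner shortcuts
    for dr, dc in _DIAGONAL:
        pair = _shift_pair(sk, dr, dc)
        # shortcut if (r, c+dc) or (r+1, c) is on the skeleton
        H, W = sk.shape
        side1 = np.zeros_like(sk)  # (r, c+dc) set
        c0, c1 = max(0, -dc), min(W, W - dc)
        side1[:, c0:c1] = sk[:, c0 + dc:c1 + dc]
        side2 = np.zeros_like(sk)  # (r+1, c) set
        side2[:-1, :] = sk[1:, :]
        pair = pair & ~(side1 | side2)
        # rounded midpoint: (r+0.5, c+dc/2) -> floor(+0.5): (r+1, c+dc if dc>0 else c)
        yield pair, SQRT2, 1, max(dc, 0)


def vessel_length_px(skeleton: np.ndarray, region: np.ndarray | None = None) -> float:
    """Geodesic skeleton length in pixel units inside ``region``."""
    sk = as_bool_mask(skeleton, "skeleton")
    total = 0.0
    for pair, step, mdr, mdc in _edge_masks(sk):
        if region is not None:
            H, W = sk.shape
            memb = np.zeros_like(sk)
            r0, r1 = max(0, -mdr), min(H, H - mdr)
            c0, c1 = max(0, -mdc), min(W, W - mdc)
            memb[r0:r1, c0:c1] = region[r0 + mdr:r1 + mdr, c0 + mdc:c1 + mdc]
            pair = pair & memb
        total += step * int(pair.sum())
    return total


def vessel_length(skel: SkeletonMap, region: np.ndarray | None = None) -> float:
    """VL: geodesic skeleton length inside ``region``, in millimetres."""
    return vessel_length_px(skel.skeleton, region) * skel.pixel_pitch_um / 1000.0


def vessel_average_diameter(skel: SkeletonMap, region: np.ndarray | None = None) -> float:
    """VAD: mean of 2 x radius over in-region skeleton pixels, micrometres.

    Returns NaN (missing) when the region holds no skeleton pixel.
    """
    sel = skel.skeleton if region is None else (skel.skeleton & as_bool_mask(region))
    if not sel.any():
        return float("nan")
    return float(2.0 * skel.radius_px[sel].mean() * skel.pixel_pitch_um)


def vessel_density(mask: np.ndarray, region: np.ndarray) -> float:
    """VD: fraction of vessel pixels inside ``region``."""
    mask = as_bool_mask(mask, "vessel mask")
    region = as_bool_mask(region, "region")
    n = int(region.sum())
    if n == 0:
        raise DataError("empty region: vessel density undefined")
    return float((mask & region).sum() / n)


def local_density_map(mask: np.ndarray, window_px: int = 30) -> np.ndarray:
    """Per-pixel vessel fraction in a ``window_px`` square window.

    An even window spans [-w/2, w/2 - 1] around the center pixel.  At image
    borders the window shrinks to its in-image part, so values stay true
    fractions in [0, 1].
    """
    mask = as_bool_mask(mask, "vessel mask")
    if window_px > min(mask.shape):
        raise ConfigurationError("window larger than the image")
    # scipy's even-size window spans [-w/2, w/2-1] around the center pixel
    ones = np.ones_like(mask, dtype=float)
    num = ndi.uniform_filter(mask.astype(float), size=window_px, mode="constant")
    den = ndi.uniform_filter(ones, size=window_px, mode="constant")
    return np.clip(num / den, 0.0, 1.0)
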