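"""Vessel binarization by local adaptive region growing.

Seeds are the brightest pixels of the angiogram (above a global percentile).
The region then grows breadth-first: at each round every background pixel
8-adjacent to the current foreground is tested against a locally adaptive
criterion — its intensity must reach a fixed fraction of the way from the
local background mean to the local foreground mean, both estimated inside a
square window around the pixel.  Because the criterion tracks local
statistics, faint vessels keep growing where the background is dark while a
bright background does not leak into the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import Angiogram, ConfigurationError, NoContrastError

_NEIGH8 = np.ones((3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    mask: np.ndarray
    n_seeds: int
    n_iterations: int
    params: dict


def binarize_vessels(
    img: Angiogram,
    seed_percentile: float = 95.0,
    window_px: int = 31,
    accept_weight: float = 0.5,
    max_iters: int = 500,
    despeckle_area_px: int = 0,
) -> SegmentationResult:
    """Binarize an angiogram into a vessel mask.

    A frontier pixel with intensity ``I`` is accepted when
    ``I >= mu_bg + accept_weight * (mu_fg - mu_bg)`` where ``mu_fg`` /
    ``mu_bg`` are the means of currently foreground / background pixels in
    the ``window_px`` x ``window_px`` neighbourhood (ties accepted, for
    determinism).  Rounds repeat until a fixpoint or ``max_iters``.

    The returned mask is always a superset of the seed set.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ConfigurationError("window_px must be odd and >= 3")
    I = img.intensity
    if I.max() == I.min():
        raise NoContrastError("no contrast: image is constant")

    thr = np.percentile(I, seed_percentile)
    fg = I >= thr
    n_seeds = int(fg.sum())
    if fg.all():
        warnings.warn("all pixels are seeds; returning all-true mask")
        return SegmentationResult(fg, n_seeds, 0, _params_dict(locals()))

    size = window_px
    it = 0
    for it in range(1, max_iters + 1):
        fgf = fg.astype(float)
        s_fg = ndi.uniform_filter(I * fgf, size=size, mode="constant")
        c_fg = ndi.uniform_filter(fgf, size=size, mode="constant")
        s_bg = ndi.uniform_filter(I * (1.0 - fgf), size=size, mode="constant")
        c_bg = ndi.uniform_filter(1.0 - fgf, size=size, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            mu_fg = np.where(c_fg > 0, s_fg / np.maximum(c_fg, 1e-12), 0.0)
            mu_bg = np.where(c_bg > 0, s_bg / np.maximum(c_bg, 1e-12), 0.0)
        thresh = mu_bg + accept_weight * (mu_fg - mu_bg)
        frontier = ndi.binary_dilation(fg, structure=_NEIGH8) & ~fg
        accept = frontier & ((I >= thresh) | (c_bg <= 0))
        if not accept.any():
            break
        fg = fg | accept

    if despeckle_area_px > 0:
        fg = despeckle(fg, despeckle_area_px)
    params = {
        "seed_percentile": seed_percentile,
        "window_px": window_px,
        "accept_weight": accept_weight,
        "max_iters": max_iters,
        "despeckle_area_px": despeckle_area_px,
    }
    return SegmentationResult(fg, n_seeds, it, params)


def _params_dict(loc: dict) -> dict:
    return {
        k: loc[k]
        for k in ("seed_percentile", "window_px", "accept_weight",
                  "max_iters", "despeckle_area_px")
    }


def despeckle(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    """Remove 8-connected components with area strictly below
    ``min_area_px``.  Idempotent."""
    lbl, n = ndi.label(mask, structure=_NEIGH8)
    if n == 0:
        return mask.copy()
    areas = np.bincount(lbl.ravel())
    keep = areas >= min_area_px
    keep[0] = False
    return keep[lbl]
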