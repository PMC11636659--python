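"""Skeletonization and radius-weighted skeletons.

The binary vessel map is reduced to a one-pixel-wide centerline by
homotopy-preserving iterative thinning (boundary pixels are removed until a
fixpoint while 8-connectivity is maintained).  The Euclidean distance
transform of the vessel mask, restricted pointwise to the skeleton, attaches
the local vessel radius to each centerline pixel; doubling it at metric time
gives the local diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import thin

from .core import DataError, as_bool_mask

_NEIGH8 = np.ones((3, 3), dtype=bool)


@dataclass
class SkeletonMap:
    """One-pixel-wide skeleton with per-pixel vessel radius (px)."""

    skeleton: np.ndarray
    radius_px: np.ndarray
    pixel_pitch_um: float


def has_thick_block(skel: np.ndarray) -> bool:
    """True if any 2x2 block of the skeleton is fully set."""
    s = skel
    return bool((s[:-1, :-1] & s[1:, :-1] & s[:-1, 1:] & s[1:, 1:]).any())


def _break_blocks(skel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Remove one pixel from each fully set 2x2 block without changing the
    connectivity.  Iterative thinning very rarely leaves such blocks (the
    typical culprit is an even-width X crossing); when no block pixel can be
    dropped safely, one corner is removed and a lateral bridge pixel (inside
    the vessel mask) re-attaches its diagonal arm."""
    sk = skel.copy()
    H, W = sk.shape
    for _ in range(8):
        blocks = sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]
        if not blocks.any():
            return sk
        for r, c in zip(*np.nonzero(blocks)):
            corners = [(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)]
            if not all(sk[p] for p in corners):
                continue  # already resolved by an earlier repair
            done = False
            for pr, pc in corners:
                if _removable(sk, pr, pc):
                    sk[pr, pc] = False
                    done = True
                    break
            if done:
                continue
            # remove + bridge repair
            for pr, pc in corners:
                ext = [
                    (pr + dr, pc + dc)
                    for dr in (-1, 1) for dc in (-1, 1)
                    if 0 <= pr + dr < H and 0 <= pc + dc < W
                    and sk[pr + dr, pc + dc] and (pr + dr, pc + dc) not in corners
                ]
                if len(ext) != 1:
                    continue
                dr_, dc_ = ext[0][0] - pr, ext[0][1] - pc
                for br, bc in ((pr, pc + dc_), (pr + dr_, pc)):
                    if 0 <= br < H and 0 <= bc < W and mask[br, bc]:
                        sk[pr, pc] = False
                        sk[br, bc] = True
                        done = True
                        break
                if done:
                    break
    return sk


def _removable(sk: np.ndarray, r: int, c: int) -> bool:
    """A pixel may be deleted if its punctured 3x3 neighbourhood stays
    8-connected and it is not an endpoint."""
    r0, r1 = max(r - 1, 0), min(r + 2, sk.shape[0])
    c0, c1 = max(c - 1, 0), min(c + 2, sk.shape[1])
    patch = sk[r0:r1, c0:c1].copy()
    patch[r - r0, c - c0] = False
    n = int(patch.sum())
    if n < 2:
        return False
    _, k = ndi.label(patch, structure=_NEIGH8)
    return k == 1


def _neighbor_counts(sk: np.ndarray) -> np.ndarray:
    kernel = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)
    return ndi.convolve(sk.astype(int), kernel, mode="constant", cval=0) * sk


def _prune_spurs(sk: np.ndarray, max_len: int = 2) -> np.ndarray:
    """Remove junction twigs of at most ``max_len`` pixels: endpoint chains
    that run into a branch pixel.  Such twigs are thinning artifacts of
    wide-vessel junctions, too short to represent a vessel at any
    supported calibre; removal keeps the component count unchanged."""
    sk = sk.copy()
    H, W = sk.shape
    for _ in range(16):  # to fixpoint; converges in a couple of passes
        counts = _neighbor_counts(sk)
        removed = []
        for r, c in np.argwhere(counts == 1):
            chain = [(r, c)]
            prev, cur = None, (int(r), int(c))
            hit = False
            for _step in range(max_len):
                nbrs = [
                    (cur[0] + dr, cur[1] + dc)
                    for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                    if (dr or dc)
                    and 0 <= cur[0] + dr < H and 0 <= cur[1] + dc < W
                    and sk[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbrs) != 1:
                    break
                nxt = nbrs[0]
                if counts[nxt] >= 3:
                    hit = True
                    break
                chain.append(nxt)
                prev, cur = cur, nxt
            if hit:
                removed.extend(chain)
        if not removed:
            break
        for r, c in removed:
            sk[r, c] = False
    return sk


def skeletonize(mask: np.ndarray, spur_px: int = 2) -> np.ndarray:
    """Thin a binary vessel mask to a one-pixel-wide skeleton.

    Junction twigs up to ``spur_px`` pixels (thinning artifacts at wide
    junctions) are pruned; pass 0 to keep the raw thinning result.
    Idempotent; preserves the number of 8-connected components; the result
    is a subset of the mask with no fully set 2x2 block.
    """
    mask = as_bool_mask(mask, "vessel mask")
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    sk = mask
    for _ in range(8):  # thin + prune to a joint fixpoint (idempotence)
        nxt = thin(sk)
        if has_thick_block(nxt):
            nxt = _break_blocks(nxt, mask)
        if spur_px > 0:
            nxt = _prune_spurs(nxt, max_len=spur_px)
        if np.array_equal(nxt, sk):
            break
        sk = nxt
    return sk


def radius_weighted_skeleton(
    mask: np.ndarray, skeleton: np.ndarray, pixel_pitch_um: float = 1.0
) -> SkeletonMap:
    """Attach the Euclidean distance-to-boundary (vessel radius, px) to each
    skeleton pixel by pointwise multiplication of the distance transform of
    the vessel mask with the skeleton."""
    mask = as_bool_mask(mask, "vessel mask")
    skeleton = as_bool_mask(skeleton, "skeleton")
    if (skeleton & ~mask).any():
        raise DataError("skeleton pixel outside the vessel mask")
    edt = ndi.distance_transform_edt(mask)
    return SkeletonMap(
        skeleton=skeleton,
        radius_px=edt * skeleton,
        pixel_pitch_um=pixel_pitch_um,
    )


def skeletonize_vessels(mask: np.ndarray, pixel_pitch_um: float) -> SkeletonMap:
    """Convenience composition: thin, then radius-weight."""
    sk = skeletonize(mask)
    return radius_weighted_skeleton(mask, sk, pixel_pitch_um)
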