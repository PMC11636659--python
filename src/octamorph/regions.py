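"""Fovea / parafovea analysis regions.

Two concentric circles of 1.5 mm and 2.5 mm diameter are centered on the
fovea midpoint (taken as the FAZ centroid).  The fovea region is the inner
disc minus the FAZ; the parafovea is the annulus between the circles (FAZ
pixels, if any fall there, are excluded as well).  Pixel membership uses the
pixel-center distance, inclusive of the radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, as_bool_mask
from .faz import FAZMask

#: inner / outer analysis radii in mm (1.5 mm and 2.5 mm diameter circles)
INNER_RADIUS_MM = 0.75
OUTER_RADIUS_MM = 1.25


@dataclass
class RegionPartition:
    fovea_mask: np.ndarray
    parafovea_mask: np.ndarray
    center_px: tuple[float, float]
    radii_mm: tuple[float, float] = (INNER_RADIUS_MM, OUTER_RADIUS_MM)

    def region(self, name: str) -> np.ndarray:
        if name == "fovea":
            return self.fovea_mask
        if name == "parafovea":
            return self.parafovea_mask
        if name == "image":
            return np.ones_like(self.fovea_mask, dtype=bool)
        raise ConfigurationError(f"unknown region {name!r}")


def disc_mask(shape: tuple[int, int], center_px, radius_px: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center_px[0]) ** 2 + (cc - center_px[1]) ** 2 <= radius_px**2


def partition_regions(
    faz: FAZMask | np.ndarray,
    pixel_pitch_um: float,
    center_px: tuple[float, float] | None = None,
) -> RegionPartition:
    """Build fovea and parafovea masks around the FAZ.

    ``faz`` may be a :class:`FAZMask` (its centroid becomes the center) or a
    bare boolean mask (possibly empty, in which case ``center_px`` must be
    given; an empty FAZ degenerates to fovea = full inner disc).
    """
    if isinstance(faz, FAZMask):
        faz_mask = as_bool_mask(faz.mask, "FAZ")
        center = center_px or faz.centroid_px
    else:
        faz_mask = as_bool_mask(faz, "FAZ")
        if center_px is not None:
            center = center_px
        elif faz_mask.any():
            from scipy import ndimage as ndi

            center = ndi.center_of_mass(faz_mask)
        else:
            raise ConfigurationError("empty FAZ mask requires an explicit center")

    shape = faz_mask.shape
    pitch = pixel_pitch_um
    r_in = INNER_RADIUS_MM * 1000.0 / pitch
    r_out = OUTER_RADIUS_MM * 1000.0 / pitch
    half_width = min(shape) / 2.0
    if r_out > half_width + 1e-9:
        raise ConfigurationError(
            "outer 1.25 mm circle does not fit inside the imaged field"
        )
    inner = disc_mask(shape, center, r_in)
    outer = disc_mask(shape, center, r_out)
    if (faz_mask & ~inner).any():
        warnings.warn("FAZ extends beyond the inner 0.75 mm circle")
    fovea = inner & ~faz_mask
    parafovea = outer & ~inner & ~faz_mask
    return RegionPartition(
        fovea_mask=fovea,
        parafovea_mask=parafovea,
        center_px=(float(center[0]), float(center[1])),
    )
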