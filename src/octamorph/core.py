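"""Shared containers and error types for OCTA morphometry.

Conventions used throughout the package:

* images are 2-D numpy arrays indexed (row, col), 0-based, pixel centers;
* intensities are floats normalized to [0, 1];
* physical scale is carried as ``pixel_pitch_um`` (micrometres per pixel);
  the default scanner geometry is a 3 x 3 mm field sampled at 512 x 512
  (pitch 3000/512 ~= 5.859 um/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: physical field width of the standard macular scan, millimetres
DEFAULT_FIELD_MM = 3.0
#: standard en-face sampling of that field, pixels
DEFAULT_SIZE_PX = 512


def pitch_for(size_px: int, field_mm: float = DEFAULT_FIELD_MM) -> float:
    """Pixel pitch in um/px for a square field of ``field_mm`` mm."""
    return field_mm * 1000.0 / size_px


class OctamorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OctamorphError):
    """Invalid parameters or unsatisfiable geometry (CLI exit code 1)."""


class DataError(OctamorphError):
    """Invalid or degenerate input data (CLI exit code 2)."""


class NoContrastError(DataError):
    """Raised when an image is constant and cannot be binarized."""


@dataclass
class Angiogram:
    """A single-layer en-face OCTA angiogram.

    Parameters
    ----------
    intensity : ndarray of float
        2-D flow-signal image, normalized to [0, 1].
    pixel_pitch_um : float
        Physical pixel pitch, micrometres per pixel.
    layer : str
        Retinal plexus the image belongs to, ``"SVP"`` or ``"DVP"``.
    eye_id, group : str
        Cohort metadata carried through to the metrics report.
    """

    intensity: np.ndarray
    pixel_pitch_um: float
    layer: str = "SVP"
    eye_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise DataError("angiogram must be a 2-D grayscale image")
        if self.pixel_pitch_um <= 0:
            raise ConfigurationError("pixel pitch must be positive")
        lo, hi = float(self.intensity.min()), float(self.intensity.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise DataError(
                f"intensities must be normalized to [0, 1], got [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    @property
    def pitch_mm(self) -> float:
        return self.pixel_pitch_um / 1000.0


def as_bool_mask(mask: np.ndarray, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise DataError(f"{name} must be 2-D")
    return arr.astype(bool)
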