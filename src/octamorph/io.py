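"""Image and table I/O.

Angiograms are read from 8/16-bit grayscale PNG or TIFF and normalized to
[0, 1] by the dtype range (floats are clipped).  Masks are written as 0/255
PNG, radius maps as 32-bit float TIFF, and cohort manifests as CSV with
columns path, eye_id, group, layer (optional truth).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Angiogram, DataError, pitch_for


def load_angiogram(
    path: str | Path,
    pixel_pitch_um: float | None = None,
    layer: str = "SVP",
    eye_id: str = "",
    group: str = "",
) -> Angiogram:
    import imageio.v3 as iio

    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - exercised via CLI error path
        raise DataError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise DataError(f"{path}: expected a 2-D grayscale image")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(float), 0.0, 1.0)
    if pixel_pitch_um is None:
        pixel_pitch_um = pitch_for(arr.shape[0])
    return Angiogram(intensity=arr, pixel_pitch_um=pixel_pitch_um,
                     layer=layer, eye_id=eye_id, group=group)


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def save_radius_map(path: str | Path, radius_px: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(Path(path), radius_px.astype(np.float32))


def save_overlay(path: str | Path, base: np.ndarray,
                 red: np.ndarray | None = None,
                 green: np.ndarray | None = None,
                 blue: np.ndarray | None = None) -> None:
    """Write an RGB QC overlay: grayscale base with colored masks burned in."""
    import imageio.v3 as iio

    g = np.clip(np.asarray(base, float), 0, 1)
    rgb = np.stack([g, g, g], axis=-1)
    for ch, m in enumerate((red, green, blue)):
        if m is not None:
            m = np.asarray(m, bool)
            rgb[m] = 0.0
            rgb[..., ch][m] = 1.0
    iio.imwrite(Path(path), (rgb * 255).astype(np.uint8))


def load_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"path", "eye_id", "group", "layer"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"manifest missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise DataError("empty manifest")
    return df


def write_provenance(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
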