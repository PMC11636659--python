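"""End-to-end analysis: single angiograms and cohort batches.

The per-image flow mirrors the processing chain: binarize -> FAZ
extraction -> region partition -> skeletonize + radius weighting ->
topology -> length/diameter/density -> fragmentation.  Each analyzed image
yields one metrics row per region; a cohort run concatenates rows and a
group comparison applies the unpaired two-tailed Student t-test per
(layer, region, metric) cell.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fragmentation as frag
from . import metrics as vm
from .core import Angiogram, DataError, OctamorphError
from .faz import extract_faz
from .io import load_angiogram, save_mask, save_overlay, save_radius_map, write_provenance
from .regions import partition_regions
from .segmentation import binarize_vessels
from .skeleton import skeletonize_vessels
from .stats import compare_groups  # re-exported pipeline surface
from .topology import branching_metrics, classify_skeleton

__all__ = ["AnalysisConfig", "analyze_image", "analyze_angiogram",
           "analyze_cohort", "compare_groups"]

log = logging.getLogger("octamorph")


@dataclass
class AnalysisConfig:
    """Every tunable of the per-image pipeline, embedded in outputs for
    provenance.  Defaults follow the standard 3 x 3 mm / 512 px protocol."""

    pixel_pitch_um: float | None = None  # None: derived from image width
    seed_percentile: float = 95.0
    window_px: int = 31
    accept_weight: float = 0.5
    max_iters: int = 500
    despeckle_area_px: int = 0
    merge_depth_frac: float = 0.3
    faz_iterations: int = 50
    faz_smoothing: int = 2
    fragmentation_k: float = frag.DEFAULT_MULTIPLIER
    count_mode: str = "cluster"
    regions: tuple[str, ...] = ("fovea", "parafovea")
    local_density_window_px: int = 30
    save_artifacts: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImageAnalysis:
    """Full result of one angiogram analysis."""

    rows: pd.DataFrame
    vessel_mask: np.ndarray
    faz_mask: np.ndarray
    skeleton: np.ndarray
    radius_px: np.ndarray
    segments: frag.SegmentSet
    vad_um_image: float
    config: AnalysisConfig


def analyze_angiogram(angio: Angiogram, config: AnalysisConfig | None = None,
                      out_dir: str | Path | None = None) -> ImageAnalysis:
    """Analyze an in-memory angiogram; returns per-region metric rows and
    all intermediate maps.  Deterministic for a fixed config."""
    cfg = config or AnalysisConfig()
    seg = binarize_vessels(
        angio,
        seed_percentile=cfg.seed_percentile,
        window_px=cfg.window_px,
        accept_weight=cfg.accept_weight,
        max_iters=cfg.max_iters,
        despeckle_area_px=cfg.despeckle_area_px,
    )
    fazm = extract_faz(
        seg.mask,
        pixel_pitch_um=angio.pixel_pitch_um,
        merge_depth_frac=cfg.merge_depth_frac,
        iterations=cfg.faz_iterations,
        smoothing=cfg.faz_smoothing,
    )
    parts = partition_regions(fazm, angio.pixel_pitch_um)
    skel = skeletonize_vessels(seg.mask, angio.pixel_pitch_um)
    topo = classify_skeleton(skel)
    vad_image = vm.vessel_average_diameter(skel)

    vl = {name: vm.vessel_length(skel, parts.region(name)) for name in cfg.regions}
    branching = branching_metrics(topo, parts, vl, region_names=tuple(cfg.regions),
                                  count_mode=cfg.count_mode)
    segset = frag.isolated_segments(skel, topo)
    fragm = frag.fragmentation_metrics(
        segset, vad_image, vl, regions=parts, k=cfg.fragmentation_k,
        region_names=tuple(cfg.regions),
    )

    rows = []
    for name in cfg.regions:
        region = parts.region(name)
        rows.append({
            "eye_id": angio.eye_id,
            "group": angio.group,
            "layer": angio.layer,
            "region": name,
            "VL_mm": vl[name],
            "VAD_um": vm.vessel_average_diameter(skel, region),
            "VD_fraction": vm.vessel_density(seg.mask, region),
            **branching[name],
            **fragm[name],
            "FAZ_area_mm2": fazm.area_mm2,
        })
    table = pd.DataFrame(rows)

    result = ImageAnalysis(
        rows=table,
        vessel_mask=seg.mask,
        faz_mask=fazm.mask,
        skeleton=skel.skeleton,
        radius_px=skel.radius_px,
        segments=segset,
        vad_um_image=vad_image,
        config=cfg,
    )
    if out_dir is not None and cfg.save_artifacts:
        _save_artifacts(result, angio, out_dir, cfg)
    return result


def _save_artifacts(res: ImageAnalysis, angio: Angiogram,
                    out_dir: str | Path, cfg: AnalysisConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{angio.eye_id or 'image'}_{angio.layer}"
    save_mask(out / f"{stem}_vessels.png", res.vessel_mask)
    save_mask(out / f"{stem}_faz.png", res.faz_mask)
    save_mask(out / f"{stem}_skeleton.png", res.skeleton)
    save_radius_map(out / f"{stem}_radius.tif", res.radius_px)
    dmap = vm.local_density_map(res.vessel_mask, cfg.local_density_window_px)
    import imageio.v3 as iio

    iio.imwrite(out / f"{stem}_density.png", (dmap * 255).astype(np.uint8))
    topo = classify_skeleton(res.skeleton)
    nodes = np.zeros_like(res.skeleton)
    for r, c in np.rint(topo.node_centroids).astype(int):
        nodes[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = True
    eps = np.zeros_like(res.skeleton)
    for r, c in topo.endpoints:
        eps[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2] = True
    save_overlay(out / f"{stem}_topology.png", res.skeleton.astype(float),
                 red=nodes, blue=eps)
    write_provenance(out / f"{stem}_provenance.json", {
        "config": cfg.to_dict(),
        "eye_id": angio.eye_id, "layer": angio.layer, "group": angio.group,
        "vad_um_image": res.vad_um_image,
    })


def analyze_image(path: str | Path, config: AnalysisConfig | None = None,
                  out_dir: str | Path | None = None, **metadata) -> ImageAnalysis:
    """Load an angiogram from disk and analyze it."""
    cfg = config or AnalysisConfig()
    angio = load_angiogram(path, pixel_pitch_um=cfg.pixel_pitch_um, **metadata)
    return analyze_angiogram(angio, cfg, out_dir=out_dir)


def analyze_cohort(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    config: AnalysisConfig | None = None,
    resume_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Batch-analyze a cohort manifest.

    Returns (table, failures): one metric row per (eye, layer, region) for
    every successfully analyzed image, and a failure record per image that
    raised.  With ``resume_table`` rows already computed are skipped and
    carried over unchanged.
    """
    if len(manifest) == 0:
        raise DataError("empty manifest")
    cfg = config or AnalysisConfig()
    base = Path(base_dir)
    done: set[tuple[str, str]] = set()
    tables: list[pd.DataFrame] = []
    if resume_table is not None and len(resume_table):
        done = set(zip(resume_table["eye_id"], resume_table["layer"]))
        tables.append(resume_table)
    failures: list[dict] = []
    for rec in manifest.itertuples(index=False):
        key = (rec.eye_id, rec.layer)
        if key in done:
            continue
        try:
            res = analyze_image(
                base / rec.path, cfg,
                eye_id=rec.eye_id, group=rec.group, layer=rec.layer,
            )
            tables.append(res.rows)
        except OctamorphError as exc:
            log.warning("image %s failed: %s", rec.path, exc)
            failures.append({"path": rec.path, "eye_id": rec.eye_id,
                             "layer": rec.layer, "error": str(exc)})
    if not tables:
        return pd.DataFrame(), failures
    table = pd.concat(tables, ignore_index=True)
    dup = table.duplicated(subset=["eye_id", "layer", "region"])
    if dup.any():
        raise DataError("duplicate (eye, layer, region) rows in cohort table")
    return table, failures
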