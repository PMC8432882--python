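"""End-to-end driver: image pair in, tables/maps/overlays out."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

from .correlation import CorrelationConfig, CorrelationResult, correlate, export_correlation
from .fa_segmentation import FocalAdhesion, characterize_all, label_objects
from .filament_detection import (
    Filament,
    FilamentFilterSpec,
    filament_table,
    trace_filaments,
)
from .images import BinaryMask, GrayImage
from .io_formats import (
    ProjectConfig,
    pair_inputs,
    read_image,
    write_fa_table,
    write_mask,
)
from .preprocessing import binarize, run_queue

logger = logging.getLogger(__name__)

__all__ = ["segment_adhesions", "detect_filaments", "run_pair", "run_batch"]


def segment_adhesions(
    img: GrayImage, cfg: ProjectConfig
) -> tuple[BinaryMask, list[FocalAdhesion]]:
    """Filter queue -> threshold -> morphology -> size-filtered objects."""
    pre = run_queue(img, cfg.filter_queue)
    level = cfg.threshold.resolve(pre)
    mask = binarize(pre, level, closing=cfg.closing, fill_holes=cfg.fill_holes)
    comps = label_objects(
        mask,
        min_px=cfg.fa_limits.get("min_px", 1),
        max_px=cfg.fa_limits.get("max_px", 10**9),
        max_clusters=cfg.fa_limits.get("max_clusters", 10**9),
    )
    scale = img.scale if img.scale is not None else cfg.scale_um_per_px
    return mask, characterize_all(comps, scale=scale)


def detect_filaments(img: GrayImage, cfg: ProjectConfig) -> list[Filament]:
    """Trace stress fibers on the actin channel per the project config."""
    filters = FilamentFilterSpec(**cfg.filament_filters)
    if img.scale is None and cfg.scale_um_per_px is not None:
        img = GrayImage(img.pixels, scale=cfg.scale_um_per_px, frame_index=img.frame_index)
    return trace_filaments(img, threshold=cfg.filament_threshold, filters=filters)


def run_pair(
    fa_path,
    actin_path,
    cfg: ProjectConfig,
    out_dir,
    frame: Optional[int] = None,
) -> dict:
    """Process one adhesion/actin image pair and write all outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fa_img = read_image(fa_path, frame=frame, scale=cfg.scale_um_per_px)
    actin_img = read_image(actin_path, frame=frame, scale=cfg.scale_um_per_px)
    mask, fas = segment_adhesions(fa_img, cfg)
    filaments = detect_filaments(actin_img, cfg)
    result = correlate(fas, filaments, CorrelationConfig(**cfg.correlation))

    stem = Path(fa_path).stem
    paths = {
        "fa_mask": write_mask(mask, out_dir / f"{stem}_fa_mask.tif"),
        "fa_table": write_fa_table(fas, out_dir / f"{stem}_adhesions.csv"),
    }
    tab, summ = filament_table(filaments, out_dir / f"{stem}_filaments.csv")
    paths["filament_table"], paths["filament_summary"] = tab, summ
    paths.update(
        export_correlation(result, fas, filaments, out_dir / f"{stem}_correlation",
                           image_shape=fa_img.shape)
    )
    logger.info(
        "%s: %d adhesions, %d filaments, %d pairs",
        stem,
        len(fas),
        len(filaments),
        len(result.pairs),
    )
    return {"paths": paths, "fas": fas, "filaments": filaments, "result": result}


def run_batch(fa_paths: Sequence, filament_paths: Sequence, cfg: ProjectConfig, out_dir) -> list[dict]:
    """Pair inputs by stem and process every matched pair."""
    outputs = []
    for fa_path, actin_path in pair_inputs(fa_paths, filament_paths):
        outputs.append(run_pair(fa_path, actin_path, cfg, Path(out_dir) / Path(fa_path).stem))
    return outputs
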