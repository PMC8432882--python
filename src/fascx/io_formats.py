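"""Reading and writing images, masks, result tables and project config.

Images and masks travel as TIFF / OME-TIFF / PNG; result tables as CSV;
project configuration as a documented YAML (or JSON) schema.  Multi-frame
stacks are supported by frame index; frames of one stack are processed
independently under a shared :class:`ProjectConfig`.

Conventions: coordinates are 0-based (row, col); exported ``center_x`` /
``center_y`` are column / row in pixel units with sub-pixel (centroid)
precision.  The micrometer scale comes from the config or from OME
metadata; on conflict the config wins with a logged warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fa_segmentation import FocalAdhesion
from .images import BinaryMask, GrayImage
from .preprocessing import FilterSpec, ThresholdSpec

__all__ = [
    "ProjectConfig",
    "read_image",
    "read_mask",
    "write_image",
    "write_mask",
    "write_fa_table",
    "pair_inputs",
]

logger = logging.getLogger(__name__)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}

# ITU-R 601 luminance weights for color inputs
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageFormatError(ValueError):
    """Unreadable or unsupported image file."""


@dataclass
class ProjectConfig:
    """Whole-pipeline configuration with a YAML/JSON round trip.

    Sections mirror the processing stages: the pre-processing filter
    queue, thresholding, adhesion size limits, post-threshold morphology,
    the correlation options and the evaluation options.
    """

    filter_queue: list[FilterSpec] = field(default_factory=list)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    fa_limits: dict = field(
        default_factory=lambda: {"min_px": 10, "max_px": 1000, "max_clusters": 10_000}
    )
    closing: bool = False
    fill_holes: bool = False
    correlation: dict = field(
        default_factory=lambda: {"representation": "ellipse", "neighborhood": 1, "validation": "single"}
    )
    evaluation: dict = field(default_factory=lambda: {"min_overlap_pct": 1.0, "thicken_px": 0})
    filament_threshold: ThresholdSpec = field(default_factory=lambda: ThresholdSpec("otsu"))
    filament_filters: dict = field(default_factory=lambda: {"min_length": 10.0})
    scale_um_per_px: Optional[float] = None

    def __post_init__(self) -> None:
        if self.fa_limits["min_px"] > self.fa_limits["max_px"]:
            raise ValueError("fa_limits: min_px must be <= max_px")
        if self.correlation.get("neighborhood", 0) < 0:
            raise ValueError("correlation neighborhood must be >= 0")
        if not self.evaluation.get("min_overlap_pct", 1.0) > 0:
            raise ValueError("evaluation min_overlap_pct must be > 0")

    def to_dict(self) -> dict:
        return {
            "filter_queue": [f.to_dict() for f in self.filter_queue],
            "threshold": self.threshold.to_dict(),
            "fa_limits": dict(self.fa_limits),
            "closing": self.closing,
            "fill_holes": self.fill_holes,
            "correlation": dict(self.correlation),
            "evaluation": dict(self.evaluation),
            "filament_threshold": self.filament_threshold.to_dict(),
            "filament_filters": dict(self.filament_filters),
            "scale_um_per_px": self.scale_um_per_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectConfig":
        kwargs = dict(d)
        kwargs["filter_queue"] = [FilterSpec.from_dict(f) for f in d.get("filter_queue", [])]
        if "threshold" in d:
            kwargs["threshold"] = ThresholdSpec.from_dict(d["threshold"])
        if "filament_threshold" in d:
            kwargs["filament_threshold"] = ThresholdSpec.from_dict(d["filament_threshold"])
        return cls(**kwargs)

    def save(self, path) -> Path:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path

    @classmethod
    def load(cls, path) -> "ProjectConfig":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(payload)


# ---------------------------------------------------------------------------
# images


def _to_gray(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        logger.warning("%s: color input converted to luminance", path.name)
        return (arr[..., :3].astype(float) @ _LUMA).astype(arr.dtype)
    return arr


def _ome_scale(tf: "tifffile.TiffFile") -> Optional[float]:
    try:
        if tf.ome_metadata:
            import re

            m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
            if m:
                return float(m.group(1))
    except Exception:  # pragma: no cover - metadata best-effort
        pass
    return None


def read_image(path, frame: Optional[int] = None, scale: Optional[float] = None) -> GrayImage:
    """Read one grayscale plane from a TIFF/OME-TIFF/PNG file.

    Multi-frame files yield the requested ``frame`` (default 0); color
    inputs are converted to luminance with a logged warning.  ``scale``
    (um/px) overrides any OME pixel-size metadata, with a warning on
    conflict.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    meta_scale = None
    try:
        if suffix in _TIFF_SUFFIXES:
            with tifffile.TiffFile(path) as tf:
                meta_scale = _ome_scale(tf)
                arr = tf.asarray()
        elif suffix in _PNG_SUFFIXES:
            import imageio.v3 as iio

            arr = iio.imread(path)
        else:
            raise ImageFormatError(f"unsupported image format: {path.suffix}")
    except ImageFormatError:
        raise
    except Exception as exc:
        raise ImageFormatError(f"could not read {path}: {exc}") from exc

    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = _to_gray(arr, path)
    idx = 0 if frame is None else int(frame)
    if arr.ndim == 3:  # stack of planes
        if not 0 <= idx < arr.shape[0]:
            raise IndexError(f"frame {idx} out of range for stack of {arr.shape[0]} planes")
        arr = arr[idx]
    elif idx != 0:
        raise IndexError(f"frame {idx} out of range for single-plane image")

    if scale is not None and meta_scale is not None and not np.isclose(scale, meta_scale):
        logger.warning(
            "%s: config scale %.4g um/px overrides OME metadata %.4g um/px",
            path.name,
            scale,
            meta_scale,
        )
    eff_scale = scale if scale is not None else meta_scale
    return GrayImage(arr, scale=eff_scale, frame_index=idx)


def read_mask(path, frame: Optional[int] = None) -> BinaryMask:
    """Read a binary mask (any nonzero pixel is foreground)."""
    img = read_image(path, frame=frame)
    return BinaryMask(img.pixels > 0)


def write_image(img: GrayImage, path) -> Path:
    """Write an intensity image; OME pixel-size metadata is embedded for
    ``.ome.tif(f)`` paths when a scale is known."""
    path = Path(path)
    if path.suffix.lower() in _PNG_SUFFIXES:
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(img.pixels))
    else:
        kwargs = {}
        if img.scale is not None and path.name.lower().endswith((".ome.tif", ".ome.tiff")):
            kwargs = {
                "metadata": {"axes": "YX", "PhysicalSizeX": img.scale, "PhysicalSizeY": img.scale},
                "ome": True,
            }
        tifffile.imwrite(path, np.asarray(img.pixels), **kwargs)
    return path


def write_mask(mask: BinaryMask, path) -> Path:
    """Write a binary mask as 0/255 uint8."""
    path = Path(path)
    arr = mask.pixels.astype(np.uint8) * 255
    if path.suffix.lower() in _PNG_SUFFIXES:
        import imageio.v3 as iio

        iio.imwrite(path, arr)
    else:
        tifffile.imwrite(path, arr)
    return path


def write_stack(planes: Sequence[np.ndarray], path) -> Path:
    """Write a multi-frame TIFF stack (one plane per frame)."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack([np.asarray(p) for p in planes], axis=0),
        photometric="minisblack",
    )
    return path


# ---------------------------------------------------------------------------
# tables


_FA_COLUMNS = [
    "id",
    "center_x",
    "center_y",
    "main_axis_len",
    "side_axis_len",
    "angle_deg",
    "area_px",
    "area_um2",
    "ellipse_area",
    "aspect_ratio",
]


def fa_frame(fas: Sequence[FocalAdhesion]) -> pd.DataFrame:
    """Descriptor table, one row per adhesion, ordered by id."""
    rows = []
    for f in sorted(fas, key=lambda f: f.id):
        rows.append(
            {
                "id": f.id,
                "center_x": f.center[0],
                "center_y": f.center[1],
                "main_axis_len": f.main_axis_len,
                "side_axis_len": f.side_axis_len,
                "angle_deg": f.angle_deg,
                "area_px": f.area_px,
                "area_um2": f.area_um2 if f.area_um2 is not None else np.nan,
                "ellipse_area": f.ellipse_area,
                "aspect_ratio": f.aspect_ratio,
            }
        )
    return pd.DataFrame(rows, columns=_FA_COLUMNS)


def write_fa_table(fas: Sequence[FocalAdhesion], path) -> Path:
    """Export the adhesion descriptor table as CSV (header-only if empty)."""
    path = Path(path)
    fa_frame(fas).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# input pairing

# tokens stripped from file stems to find the shared cell identifier
_FA_TOKENS = ("_fa", "_fas", "_pax", "_paxillin", "_adh", "_adhesion", "_adhesions")
_ACTIN_TOKENS = ("_actin", "_sf", "_phalloidin", "_phal", "_fibers", "_filaments")


def _stem_key(path: Path, tokens: tuple[str, ...]) -> str:
    stem = path.name
    for suf in (".ome.tif", ".ome.tiff"):
        if stem.lower().endswith(suf):
            stem = stem[: -len(suf)]
            break
    else:
        stem = path.stem
    low = stem.lower()
    for tok in tokens:
        if low.endswith(tok):
            return stem[: -len(tok)]
    return stem


def pair_inputs(
    fa_paths: Sequence, filament_paths: Sequence
) -> list[tuple[Path, Path]]:
    """Match adhesion and actin files by shared stem.

    The stem is the file name without extension, with a recognized channel
    token (``_fa``, ``_pax``, ... / ``_actin``, ``_sf``, ...) stripped.
    Files without a partner are reported as warnings and excluded; they
    never abort the run.
    """
    fa_map = {_stem_key(Path(p), _FA_TOKENS): Path(p) for p in fa_paths}
    fil_map = {_stem_key(Path(p), _ACTIN_TOKENS): Path(p) for p in filament_paths}
    common = sorted(set(fa_map) & set(fil_map))
    for stem in sorted(set(fa_map) - set(fil_map)):
        warnings.warn(f"no actin partner for {fa_map[stem].name}; skipped", stacklevel=2)
    for stem in sorted(set(fil_map) - set(fa_map)):
        warnings.warn(f"no adhesion partner for {fil_map[stem].name}; skipped", stacklevel=2)
    return [(fa_map[s], fil_map[s]) for s in common]
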