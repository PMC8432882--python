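"""Core raster types shared by every stage of the pipeline.

A fluorescence micrograph is represented as a :class:`GrayImage` — a 2-D
array of non-negative intensities with an optional physical pixel size in
micrometers per pixel.  Binary segmentations (thresholded output, expert
annotations) are :class:`BinaryMask` objects with the same shape contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GrayImage", "BinaryMask"]


@dataclass
class GrayImage:
    """Single-channel intensity raster.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (integer or float).
    scale
        Physical pixel side length in micrometers per pixel, if known.
        Areas in px convert to um^2 as ``area_px * scale ** 2``.
    frame_index
        Position of this plane within its source stack (0 for single
        images).
    """

    pixels: np.ndarray
    scale: Optional[float] = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have height >= 1 and width >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.scale is not None:
            self.scale = float(self.scale)
            if not self.scale > 0:
                raise ValueError("scale (um/px) must be positive")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Return a copy carrying ``pixels`` but the same scale/frame."""
        return GrayImage(pixels=pixels, scale=self.scale, frame_index=self.frame_index)


@dataclass
class BinaryMask:
    """Strictly two-valued raster (foreground = True)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got ndim={arr.ndim}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be two-valued")
            arr = arr.astype(bool)
        self.pixels = arr

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def foreground_px(self) -> int:
        return int(self.pixels.sum())
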