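"""Filter queue and thresholding: from raw micrograph to binary mask.

The segmentation front end mirrors the classic point-structure workflow:
an ordered queue of optional intensity filters improves the signal-to-noise
ratio, an automatic (or manual) histogram threshold binarizes the result,
and optional morphological closing / hole filling merge seemingly disparate
pieces of one adhesion plaque into a single object.

Filters
-------
``gauss``
    Isotropic Gaussian smoothing (sigma in px, reflective borders).
``laplace``
    Discrete Laplacian with a 4- or 8-neighbor stencil, scaled by a
    ``strength`` gain, then offset/rescaled back to the input intensity
    range.  The raw stencil response is available as
    :func:`laplace_response`.
``line_gauss``
    Anisotropic Gaussian ridge enhancement: an elongated Gaussian kernel is
    rotated over a bank of orientations and the maximum response is kept.
``cross_correlation``
    Matched filtering against a bank of rotated 1-px-wide line templates
    (zero-mean), max-pooled over orientation.
``enhance_contrast``
    Percentile-based linear contrast stretch with a configurable saturated
    pixel fraction.

Thresholding methods: ``intermodes`` (iterative histogram smoothing until
bimodal, cut at the mode midpoint), ``otsu`` (between-class variance
maximization), ``mean``, ``triangle``, ``li``, and ``manual``.  Histogram
methods always operate on a 256-bin histogram of the min-max rescaled
image, so reported levels live on the familiar 0-255 convention for 8-bit
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import filters as _skfilters
from skimage import morphology as _skmorph

from .images import BinaryMask, GrayImage

__all__ = [
    "FilterSpec",
    "ThresholdSpec",
    "apply_filter",
    "run_queue",
    "auto_threshold",
    "binarize",
    "laplace_response",
    "intermodes_level",
    "otsu_level",
    "FILTER_KINDS",
    "THRESHOLD_METHODS",
]

FILTER_KINDS = ("gauss", "laplace", "line_gauss", "cross_correlation", "enhance_contrast")
THRESHOLD_METHODS = ("intermodes", "otsu", "mean", "triangle", "li", "manual")


class ConfigError(ValueError):
    """Invalid filter/threshold parameterization."""


@dataclass
class FilterSpec:
    """One entry of the pre-processing queue.

    ``params`` is kind-specific:

    - gauss: ``sigma`` (px, > 0)
    - laplace: ``strength`` (gain, float), ``neighborhood`` (4 or 8)
    - line_gauss: ``sigma`` (px, along-line), ``half_width`` (px, across),
      optional ``orientations`` (default 12)
    - cross_correlation: ``width`` (template length, px), optional
      ``orientations`` (default 12)
    - enhance_contrast: ``saturated`` (fraction in [0, 0.5))
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ConfigError(f"unknown filter kind {self.kind!r}")
        p = dict(self.params)
        if self.kind == "gauss":
            if not p.get("sigma", 0) > 0:
                raise ConfigError("gauss filter requires sigma > 0")
        elif self.kind == "laplace":
            if int(p.get("neighborhood", 4)) not in (4, 8):
                raise ConfigError("laplace neighborhood must be 4 or 8")
        elif self.kind == "line_gauss":
            if not p.get("sigma", 0) > 0:
                raise ConfigError("line_gauss requires sigma > 0")
            if not p.get("half_width", 0) > 0:
                raise ConfigError("line_gauss requires half_width > 0")
        elif self.kind == "cross_correlation":
            if not int(p.get("width", 0)) >= 3:
                raise ConfigError("cross_correlation requires width >= 3")
        elif self.kind == "enhance_contrast":
            sat = float(p.get("saturated", 0.0))
            if not (0.0 <= sat < 0.5):
                raise ConfigError("saturated fraction must lie in [0, 0.5)")
        self.params = p

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(kind=d["kind"], params=dict(d.get("params", {})))


@dataclass
class ThresholdSpec:
    """Threshold method plus (for ``manual``) the chosen level."""

    method: str = "otsu"
    level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in THRESHOLD_METHODS:
            raise ConfigError(f"unknown threshold method {self.method!r}")
        if self.method == "manual" and self.level is None:
            raise ConfigError("manual thresholding requires an explicit level")

    def resolve(self, img: GrayImage) -> int:
        """Return the level to apply to ``img`` (computing it if automatic)."""
        if self.method == "manual":
            return int(self.level)
        return auto_threshold(img, self.method)

    def to_dict(self) -> dict:
        return {"method": self.method, "level": self.level}

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSpec":
        return cls(method=d.get("method", "otsu"), level=d.get("level"))


# ---------------------------------------------------------------------------
# filters


def laplace_response(img: GrayImage, strength: float = 1.0, neighborhood: int = 4) -> np.ndarray:
    """Raw Laplacian stencil response (no offset/rescale), scaled by gain."""
    if neighborhood == 4:
        stencil = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
    elif neighborhood == 8:
        stencil = np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=float)
    else:
        raise ConfigError("laplace neighborhood must be 4 or 8")
    return float(strength) * ndimage.convolve(
        img.pixels.astype(float), stencil, mode="reflect"
    )


def _rescale_to_range(arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
    amin, amax = float(arr.min()), float(arr.max())
    if amax == amin:
        return np.full_like(arr, lo, dtype=float)
    return (arr - amin) / (amax - amin) * (hi - lo) + lo


def _rotated_kernel(sigma_along: float, sigma_across: float, theta: float) -> np.ndarray:
    half = max(int(np.ceil(3 * max(sigma_along, sigma_across))), 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    v = -xx * np.sin(theta) + yy * np.cos(theta)
    k = np.exp(-0.5 * ((u / sigma_along) ** 2 + (v / sigma_across) ** 2))
    return k / k.sum()


def _line_template(width: int, theta: float) -> np.ndarray:
    half = width // 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    v = -xx * np.sin(theta) + yy * np.cos(theta)
    k = ((np.abs(v) <= 0.5) & (np.abs(u) <= half)).astype(float)
    k -= k.mean()
    norm = np.sqrt((k**2).sum())
    return k / norm if norm > 0 else k


def apply_filter(img: GrayImage, spec: FilterSpec) -> GrayImage:
    """Apply one filter of the pre-processing queue; shape is preserved."""
    px = img.pixels.astype(float)
    lo, hi = float(px.min()), float(px.max())
    p = spec.params
    if spec.kind == "gauss":
        out = ndimage.gaussian_filter(px, sigma=float(p["sigma"]), mode="reflect")
    elif spec.kind == "laplace":
        raw = laplace_response(img, float(p.get("strength", 1.0)), int(p.get("neighborhood", 4)))
        out = _rescale_to_range(raw, lo, hi)
    elif spec.kind == "line_gauss":
        sigma = float(p["sigma"])
        across = max(float(p["half_width"]) / 2.0, 0.5)
        n_or = int(p.get("orientations", 12))
        out = np.full_like(px, -np.inf)
        for theta in np.pi * np.arange(n_or) / n_or:
            k = _rotated_kernel(sigma, across, theta)
            np.maximum(out, ndimage.convolve(px, k, mode="reflect"), out=out)
    elif spec.kind == "cross_correlation":
        width = int(p["width"])
        n_or = int(p.get("orientations", 12))
        out = np.full_like(px, -np.inf)
        for theta in np.pi * np.arange(n_or) / n_or:
            k = _line_template(width, theta)
            np.maximum(out, ndimage.correlate(px, k, mode="reflect"), out=out)
        out = _rescale_to_range(out, lo, hi)
    elif spec.kind == "enhance_contrast":
        sat = float(p.get("saturated", 0.0))
        plo = np.percentile(px, 100.0 * sat / 2.0)
        phi = np.percentile(px, 100.0 - 100.0 * sat / 2.0)
        if phi == plo:
            out = px.copy()
        else:
            tlo, thi = _dtype_range(img.pixels.dtype)
            out = np.clip((px - plo) / (phi - plo), 0.0, 1.0) * (thi - tlo) + tlo
    else:  # pragma: no cover - guarded by FilterSpec
        raise ConfigError(f"unknown filter kind {spec.kind!r}")
    return img.with_pixels(out)


def _dtype_range(dtype: np.dtype) -> tuple[float, float]:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return float(info.min), float(info.max)
    return 0.0, 1.0


def run_queue(img: GrayImage, queue: list[FilterSpec]) -> GrayImage:
    """Apply the filters in order; an empty queue returns the input unchanged."""
    out = img
    for i, spec in enumerate(queue):
        try:
            out = apply_filter(out, spec)
        except ConfigError as exc:
            raise ConfigError(f"filter queue position {i} ({spec.kind}): {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# thresholding


def _histogram256(px: np.ndarray) -> tuple[np.ndarray, float, float]:
    """256-bin histogram of the min-max rescaled image.

    Returns (counts, lo, hi) where bin b spans intensities
    lo + b/256*(hi-lo) .. lo + (b+1)/256*(hi-lo).
    """
    px = px.astype(float)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        raise ValueError("degenerate (constant) image: histogram thresholding undefined")
    bins = np.clip(((px - lo) / (hi - lo) * 256.0).astype(int), 0, 255)
    counts = np.bincount(bins.ravel(), minlength=256).astype(float)
    return counts, lo, hi


def _n_modes(h: np.ndarray) -> int:
    return int(np.sum((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:])))


def intermodes_level(hist: np.ndarray, max_iter: int = 10_000) -> int:
    """Intermodes cut point of a histogram (bin index).

    The histogram is repeatedly smoothed with a 3-point moving average
    until exactly two local maxima remain; the returned level is the
    midpoint between the two modes.
    """
    h = np.asarray(hist, dtype=float).copy()
    nz = np.nonzero(h)[0]
    if nz.size == 2:
        # two-valued histogram: the midpoint between the spikes
        return int(round(nz.mean()))
    for _ in range(max_iter):
        modes = _n_modes(h)
        if modes == 2:
            idx = np.nonzero((h[1:-1] > h[:-2]) & (h[1:-1] > h[2:]))[0] + 1
            return int(round((idx[0] + idx[1]) / 2.0))
        if modes < 2:
            raise ValueError("histogram is not bimodal; intermodes thresholding failed")
        h = np.convolve(h, np.ones(3) / 3.0, mode="same")
    raise ValueError("intermodes smoothing did not converge to a bimodal histogram")


def otsu_level(hist: np.ndarray) -> int:
    """Bin index maximizing between-class variance of a histogram."""
    h = np.asarray(hist, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = h / total
    bins = np.arange(h.size, dtype=float)
    omega = np.cumsum(p)
    mu = np.cumsum(p * bins)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))


def auto_threshold(img: GrayImage, method: str) -> int:
    """Automatic threshold level on the image's own intensity scale.

    Histogram methods (intermodes, otsu, triangle) work on a 256-bin
    histogram of the min-max rescaled image; the chosen bin is mapped back
    to an intensity and rounded to int.  For full-range 8-bit input the
    returned level therefore coincides with the conventional 0-255 level.
    """
    px = img.pixels
    if method == "manual":
        raise ConfigError("manual method carries its own level; nothing to compute")
    if method == "mean":
        return int(round(float(px.mean())))
    if method == "li":
        if px.max() == px.min():
            raise ValueError("degenerate (constant) image: li thresholding undefined")
        return int(round(float(_skfilters.threshold_li(px.astype(float)))))
    counts, lo, hi = _histogram256(px)
    if method == "intermodes":
        b = intermodes_level(counts)
    elif method == "otsu":
        b = otsu_level(counts)
    elif method == "triangle":
        t = float(_skfilters.threshold_triangle(px.astype(float), nbins=256))
        b = int(np.clip(round((t - lo) / (hi - lo) * 256.0), 0, 255))
    else:
        raise ConfigError(f"unknown threshold method {method!r}")
    level = lo + (b + 0.5) / 256.0 * (hi - lo)
    return int(round(level))


def binarize(
    img: GrayImage, level: int, closing: bool = False, fill_holes: bool = False
) -> BinaryMask:
    """Foreground = intensity strictly above ``level``.

    Optional post-threshold morphology: closing with a 3x3 square (one
    iteration) bridges 1-px gaps between fragments of one plaque;
    hole filling floods background regions not connected to the border.
    Neither operation removes foreground pixels.
    """
    fg = img.pixels > level
    if closing:
        fg |= _skmorph.closing(fg, footprint=np.ones((3, 3), dtype=bool))
    if fill_holes:
        fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(fg)
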