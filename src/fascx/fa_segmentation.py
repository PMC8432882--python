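"""Focal-adhesion object extraction and shape descriptors.

From a thresholded mask, 8-connected components within a size window are
turned into :class:`FocalAdhesion` objects.  For each object the convex
hull of its pixel centers is computed; the *main axis* is the hull vertex
pair at maximum Euclidean distance (the hull diameter), the *side axis* is
the total extent orthogonal to the main axis (maximum perpendicular
distance above the main-axis line plus the maximum below it), and the
fitted ellipse takes those two lengths as its full axes
(area = pi/4 * a * b).  Objects that the threshold fused can be split by
rasterizing user-drawn polylines into the mask; objects can be removed by
id.

Conventions (documented, since several are genuinely open choices):

- coordinates are 0-based (row, col); exported centers are (x=col, y=row)
  with sub-pixel centroid precision;
- orientation is measured counter-clockwise from the image x-axis in
  degrees, folded into [0, 180) (y points up, i.e. against the row axis);
- degenerate objects (singleton or collinear pixel sets) get a 1-px floor
  on the side axis so the aspect ratio stays finite;
- ties for the farthest hull pair break by smallest angle, then
  lexicographically smallest endpoint pair, making output deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import draw as _skdraw
from skimage import measure as _skmeasure
from skimage import segmentation as _skseg

from .images import BinaryMask

__all__ = [
    "FocalAdhesion",
    "SplitLine",
    "label_objects",
    "characterize",
    "split_objects",
    "remove_object",
    "render_fa_outlines",
]

logger = logging.getLogger(__name__)


@dataclass
class FocalAdhesion:
    """One segmented adhesion with its geometry descriptors."""

    id: int
    pixel_set: np.ndarray  # (n, 2) int array of (row, col)
    area_px: int
    center: tuple[float, float]  # (x, y) sub-pixel centroid
    hull: np.ndarray  # (k, 2) ordered hull vertices as (row, col)
    main_axis: tuple[tuple[float, float], tuple[float, float]]  # endpoints (row, col)
    main_axis_len: float
    side_axis_len: float
    angle_deg: float
    aspect_ratio: float
    ellipse_area: float
    area_um2: Optional[float] = None


@dataclass
class SplitLine:
    """User-drawn polyline that severs fused objects (>= 2 distinct points)."""

    points: np.ndarray  # (n, 2) array of (row, col)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("a split line needs >= 2 (row, col) points")
        if np.unique(pts, axis=0).shape[0] < 2:
            raise ValueError("a split line needs >= 2 distinct points")
        self.points = pts


def label_objects(
    mask: BinaryMask, min_px: int = 1, max_px: int = 10**9, max_clusters: int = 10**9
) -> list[np.ndarray]:
    """8-connected components within [min_px, max_px], largest first.

    If more than ``max_clusters`` components survive the size window, only
    the largest ``max_clusters`` are kept (logged).
    """
    if min_px < 1:
        raise ValueError("min_px must be >= 1")
    if min_px > max_px:
        raise ValueError(f"min_px ({min_px}) must be <= max_px ({max_px})")
    labels = _skmeasure.label(mask.pixels, connectivity=2)
    comps: list[np.ndarray] = []
    for region in _skmeasure.regionprops(labels):
        if min_px <= region.area <= max_px:
            comps.append(region.coords)
    comps.sort(key=lambda c: (-len(c), c[0, 0], c[0, 1]))
    if len(comps) > max_clusters:
        logger.warning(
            "image has %d objects after size filtering; keeping the %d largest",
            len(comps),
            max_clusters,
        )
        comps = comps[:max_clusters]
    return comps


def _hull_vertices(coords: np.ndarray) -> np.ndarray:
    """Ordered convex-hull vertices of pixel centers; degenerates fall back
    to the unique point set."""
    pts = np.unique(coords.astype(float), axis=0)
    if pts.shape[0] < 3:
        return pts
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear
        return pts
    return pts[hull.vertices]


def _axis_angle_deg(p: np.ndarray, q: np.ndarray) -> float:
    """CCW angle from x-axis of segment p->q, in [0, 180).  y is up (-row)."""
    dx = q[1] - p[1]
    dy = -(q[0] - p[0])
    ang = np.degrees(np.arctan2(dy, dx)) % 180.0
    return float(ang)


def characterize(
    pixel_set: np.ndarray, scale: Optional[float] = None, fa_id: int = 1
) -> FocalAdhesion:
    """Compute the descriptor set of one adhesion object.

    The main axis is the farthest hull-vertex pair; the side axis is the
    maximum perpendicular distance of hull vertices on one side of the
    main-axis line plus the maximum on the other side (an alternative
    reading — twice the single largest distance — is not used).
    """
    coords = np.asarray(pixel_set)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 1:
        raise ValueError("pixel_set must be a non-empty (n, 2) array of (row, col)")
    area_px = int(coords.shape[0])
    center = (float(coords[:, 1].mean()), float(coords[:, 0].mean()))  # (x, y)

    hull = _hull_vertices(coords)
    # farthest pair among hull vertices = diameter of the whole pixel set
    best: tuple[float, float, tuple, tuple] | None = None
    n = hull.shape[0]
    for i in range(n):
        for j in range(i + 1, n) if n > 1 else ():
            d = float(np.hypot(*(hull[j] - hull[i])))
            ang = _axis_angle_deg(hull[i], hull[j])
            key = (-d, ang, tuple(hull[i]), tuple(hull[j]))
            if best is None or key < (-best[0], best[1], best[2], best[3]):
                best = (d, ang, tuple(hull[i]), tuple(hull[j]))
    if best is None:  # singleton
        p = tuple(hull[0])
        main_len, angle, e1, e2 = 0.0, 0.0, p, p
    else:
        main_len, angle, e1, e2 = best

    # side axis: total orthogonal extent relative to the main-axis line
    if main_len > 0:
        a = np.asarray(e1, dtype=float)
        u = (np.asarray(e2, dtype=float) - a) / main_len
        perp = np.array([-u[1], u[0]])
        d = (hull - a) @ perp
        side_len = float(np.maximum(d, 0.0).max() + np.maximum(-d, 0.0).max())
    else:
        side_len = 0.0
    # 1-px floors keep degenerate (singleton/collinear) objects finite
    side_len = max(side_len, 1.0)
    if main_len < side_len:
        main_len = max(main_len, 1.0)
    aspect = main_len / side_len
    ellipse_area = float(np.pi / 4.0 * main_len * side_len)
    area_um2 = area_px * scale**2 if scale is not None else None
    return FocalAdhesion(
        id=int(fa_id),
        pixel_set=coords,
        area_px=area_px,
        center=center,
        hull=hull,
        main_axis=(e1, e2),
        main_axis_len=float(main_len),
        side_axis_len=float(side_len),
        angle_deg=float(angle),
        aspect_ratio=float(aspect),
        ellipse_area=ellipse_area,
        area_um2=area_um2,
    )


def characterize_all(
    components: Iterable[np.ndarray], scale: Optional[float] = None
) -> list[FocalAdhesion]:
    """Characterize a component list, assigning ids 1..n in list order."""
    return [characterize(c, scale=scale, fa_id=i + 1) for i, c in enumerate(components)]


def split_objects(mask: BinaryMask, lines: Sequence[SplitLine]) -> BinaryMask:
    """Erase 1-px-wide rasterized polylines from the foreground.

    Out-of-bounds segments are clipped with a warning.  Relabelling the
    returned mask yields the split objects.
    """
    out = mask.pixels.copy()
    h, w = out.shape
    for line in lines:
        pts = np.rint(line.points).astype(int)
        if (pts[:, 0].min() < 0 or pts[:, 0].max() >= h
                or pts[:, 1].min() < 0 or pts[:, 1].max() >= w):
            warnings.warn("split line extends outside the image; clipping", stacklevel=2)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = _skdraw.line(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            out[rr[keep], cc[keep]] = False
    return BinaryMask(out)


def remove_object(fas: list[FocalAdhesion], fa_id: int) -> list[FocalAdhesion]:
    """Drop the adhesion with the given id; other descriptors untouched."""
    if not any(f.id == fa_id for f in fas):
        raise KeyError(f"no focal adhesion with id {fa_id}")
    return [f for f in fas if f.id != fa_id]


def render_fa_outlines(fas: Sequence[FocalAdhesion], shape: tuple[int, int]) -> np.ndarray:
    """RGB uint8 image with each object's outline drawn in green."""
    canvas = np.zeros(shape, dtype=bool)
    for f in fas:
        canvas[f.pixel_set[:, 0], f.pixel_set[:, 1]] = True
    edges = _skseg.find_boundaries(canvas, mode="inner")
    rgb = np.zeros((*shape, 3), dtype=np.uint8)
    rgb[edges] = (0, 255, 0)
    return rgb
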