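"""Cross-correlation of focal adhesions with stress fibers.

Each fiber is tested against the adhesions whose main axis is shorter than
the fiber's total length (an adhesion is assumed never to outsize its
fiber).  Walking the fiber polyline, an adhesion is associated with the
fiber when any polyline point falls within a square neighborhood of the
adhesion's chosen spatial representation — its raw pixel set, its convex
hull, or its fitted ellipse — dilated by the configured neighborhood
half-width.  Each (filament, adhesion) pair is recorded at most once.

From the association counts both populations are classified:

- filaments: NAAF / SAAF / MAAF = associated with 0 / 1 / >= 2 adhesions
  (the transverse-arc / dorsal / ventral stress-fiber proxy classes);
- adhesions: AANF / AASF / AAMF = associated with 0 / 1 / >= 2 fibers.

A filament is *verified* when it reaches at least one adhesion
(``validation="single"``) or at least two (``validation="multiple"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import LineString, Point, Polygon

from .fa_segmentation import FocalAdhesion
from .filament_detection import Filament

__all__ = [
    "CorrelationConfig",
    "CorrelationResult",
    "correlate",
    "export_correlation",
    "FILAMENT_CLASSES",
    "FA_CLASSES",
]

REPRESENTATIONS = ("hull", "ellipse", "pixels")
VALIDATIONS = ("single", "multiple")
FILAMENT_CLASSES = ("NAAF", "SAAF", "MAAF")
FA_CLASSES = ("AANF", "AASF", "AAMF")


@dataclass
class CorrelationConfig:
    """Pairing options: FA representation, search half-width, validation rule."""

    representation: str = "ellipse"
    neighborhood: int = 1
    validation: str = "single"

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        if self.neighborhood < 0:
            raise ValueError("neighborhood must be >= 0")
        if self.validation not in VALIDATIONS:
            raise ValueError(f"validation must be one of {VALIDATIONS}")


@dataclass
class CorrelationResult:
    pairs: list[tuple[int, int]]  # (filament_id, fa_id)
    filament_class: dict[int, str]
    fa_class: dict[int, str]
    verified: dict[int, bool]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in FILAMENT_CLASSES + FA_CLASSES}
        for c in self.filament_class.values():
            counts[c] += 1
        for c in self.fa_class.values():
            counts[c] += 1
        return counts


# ---------------------------------------------------------------------------
# FA spatial representations


def _fa_polygon(fa: FocalAdhesion, representation: str) -> Optional[Polygon]:
    """Shapely geometry of the hull or fitted ellipse, in (x, y) = (col, row)."""
    if representation == "hull":
        pts = [(float(c), float(r)) for r, c in fa.hull]
        if len(pts) >= 3:
            return Polygon(pts).convex_hull
        if len(pts) == 2:
            return LineString(pts).buffer(0.5)
        return Point(pts[0]).buffer(0.5)
    # fitted ellipse: main axis between the farthest hull points, side axis
    # orthogonal with the total orthogonal extent as full length
    (r1, c1), (r2, c2) = fa.main_axis
    cx, cy = (c1 + c2) / 2.0, (r1 + r2) / 2.0
    a = max(fa.main_axis_len / 2.0, 0.5)
    b = max(fa.side_axis_len / 2.0, 0.5)
    circ = Point(cx, cy).buffer(1.0, quad_segs=32)
    ell = shapely.affinity.scale(circ, a, b)
    # angle_deg is CCW with y up; image y (row) points down -> negate
    return shapely.affinity.rotate(ell, -fa.angle_deg, origin=(cx, cy))


def _dilate_square(poly: Polygon, n: float) -> Polygon:
    """Minkowski sum of a convex geometry with a centered square of
    half-width n (matches the square search neighborhood exactly)."""
    if n <= 0:
        return poly
    coords = np.asarray(poly.exterior.coords)
    shifted = [coords + np.array([dx, dy]) for dx in (-n, n) for dy in (-n, n)]
    return shapely.MultiPoint(np.concatenate(shifted)).convex_hull


def _associated(fa: FocalAdhesion, fil: Filament, cfg: CorrelationConfig) -> bool:
    """True when any polyline point lies within the dilated representation."""
    pts = fil.points
    n = cfg.neighborhood
    # walk from both ends inward (pure traversal order; the pair set is
    # independent of it, but lets us stop at the first hit)
    order = np.empty(len(pts), dtype=int)
    half = (len(pts) + 1) // 2
    order[0::2] = np.arange(half)
    order[1::2] = len(pts) - 1 - np.arange(len(pts) - half)
    if cfg.representation == "pixels":
        fa_pts = fa.pixel_set
        rmin, cmin = fa_pts.min(axis=0)
        rmax, cmax = fa_pts.max(axis=0)
        for i in order:
            r, c = pts[i]
            if rmin - n <= r <= rmax + n and cmin - n <= c <= cmax + n:
                # Chebyshev distance to the nearest FA pixel
                d = np.max(np.abs(fa_pts - np.array([r, c])), axis=1).min()
                if d <= n:
                    return True
        return False
    poly = _fa_polygon(fa, cfg.representation)
    dil = _dilate_square(poly, n)
    for i in order:
        r, c = pts[i]
        if dil.covers(Point(float(c), float(r))):
            return True
    return False


def correlate(
    fas: Sequence[FocalAdhesion],
    filaments: Sequence[Filament],
    cfg: Optional[CorrelationConfig] = None,
) -> CorrelationResult:
    """Pair adhesions with fibers and classify both populations.

    Fibers are processed longest-first and adhesions largest-first, but the
    resulting pair set, classes and flags are independent of input order.
    Only adhesions with ``main_axis_len < filament length`` are candidates.
    """
    cfg = cfg or CorrelationConfig()
    fils = sorted(filaments, key=lambda f: (-f.length_px, f.id))
    fas_sorted = sorted(fas, key=lambda a: (-a.main_axis_len, a.id))

    pairs: list[tuple[int, int]] = []
    fa_count: dict[int, int] = {a.id: 0 for a in fas}
    fil_count: dict[int, int] = {f.id: 0 for f in filaments}
    for fil in fils:
        for fa in fas_sorted:
            if not fa.main_axis_len < fil.length_px:
                continue
            if _associated(fa, fil, cfg):
                pairs.append((fil.id, fa.id))
                fil_count[fil.id] += 1
                fa_count[fa.id] += 1
    pairs.sort()

    def _cls(count: int, names: tuple[str, str, str]) -> str:
        return names[0] if count == 0 else names[1] if count == 1 else names[2]

    filament_class = {fid: _cls(c, FILAMENT_CLASSES) for fid, c in fil_count.items()}
    fa_class = {aid: _cls(c, FA_CLASSES) for aid, c in fa_count.items()}
    need = 1 if cfg.validation == "single" else 2
    verified = {fid: c >= need for fid, c in fil_count.items()}
    for f in filaments:
        f.verified = verified[f.id]
    return CorrelationResult(
        pairs=pairs, filament_class=filament_class, fa_class=fa_class, verified=verified
    )


# ---------------------------------------------------------------------------
# export

# overlay colors per class (RGB); chosen for this implementation's maps
_FIL_COLORS = {"MAAF": (0, 255, 0), "SAAF": (0, 160, 255), "NAAF": (255, 0, 255)}
_FA_COLORS = {"AAMF": (255, 255, 0), "AASF": (255, 128, 0), "AANF": (255, 0, 0)}


def export_correlation(
    result: CorrelationResult,
    fas: Sequence[FocalAdhesion],
    filaments: Sequence[Filament],
    out_dir,
    image_shape: Optional[tuple[int, int]] = None,
) -> dict[str, Path]:
    """Write pair table, per-population class tables and the class overlay.

    Returns a dict of the written paths.  The overlay is a color-coded map:
    filaments and adhesions are drawn in their class colors (see
    ``_FIL_COLORS`` / ``_FA_COLORS``).
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["pairs"] = out_dir / "pairs.csv"
    pd.DataFrame(result.pairs, columns=["filament_id", "fa_id"]).to_csv(
        paths["pairs"], index=False
    )

    paths["filaments"] = out_dir / "filaments_by_association.csv"
    fil_rows = [
        {
            "id": f.id,
            "class": result.filament_class[f.id],
            "length_px": f.length_px,
            "length_um": f.length_um,
            "angle_deg": f.angle_deg,
            "verified": result.verified[f.id],
        }
        for f in filaments
    ]
    pd.DataFrame(
        fil_rows, columns=["id", "class", "length_px", "length_um", "angle_deg", "verified"]
    ).to_csv(paths["filaments"], index=False)

    paths["fas"] = out_dir / "adhesions_by_association.csv"
    fa_rows = [
        {
            "id": a.id,
            "class": result.fa_class[a.id],
            "area_px": a.area_px,
            "area_um2": a.area_um2,
            "main_axis_len": a.main_axis_len,
        }
        for a in fas
    ]
    pd.DataFrame(
        fa_rows, columns=["id", "class", "area_px", "area_um2", "main_axis_len"]
    ).to_csv(paths["fas"], index=False)

    if image_shape is None:
        h = w = 1
        for a in fas:
            h = max(h, int(a.pixel_set[:, 0].max()) + 1)
            w = max(w, int(a.pixel_set[:, 1].max()) + 1)
        for f in filaments:
            h = max(h, int(np.ceil(f.points[:, 0].max())) + 1)
            w = max(w, int(np.ceil(f.points[:, 1].max())) + 1)
        image_shape = (h, w)
    rgb = np.zeros((*image_shape, 3), dtype=np.uint8)
    for a in fas:
        rgb[a.pixel_set[:, 0], a.pixel_set[:, 1]] = _FA_COLORS[result.fa_class[a.id]]
    for f in filaments:
        pts = np.rint(f.points).astype(int)
        ok = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] < image_shape[0])
            & (pts[:, 1] >= 0)
            & (pts[:, 1] < image_shape[1])
        )
        rgb[pts[ok, 0], pts[ok, 1]] = _FIL_COLORS[result.filament_class[f.id]]
    paths["overlay"] = out_dir / "correlation_overlay.png"
    iio.imwrite(paths["overlay"], rgb)
    return paths
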