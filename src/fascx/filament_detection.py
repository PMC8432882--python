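"""Stress-fiber tracing on the actin channel.

The tracer produces filament polylines with the descriptor set used
downstream (length, width, curvature, orientation, verification flag).
Pipeline: binarize the actin image, skeletonize to a 1-px medial axis,
split the skeleton at branch points, trace every branch-free arc into an
ordered polyline, then resolve crossings by re-joining arcs across a
junction when they continue each other within an angular tolerance
(default 20 degrees).  Two straight fibers crossing in an 'X' therefore
come out as two filaments, not four stubs radiating from the junction.

Descriptors:

- length: polyline arc length in px (and um when a scale is known);
- width: twice the mean distance-transform value sampled along the
  skeleton (local half-thickness of the binarized fiber);
- curvature: mean absolute tangent-angle change per px of arc length,
  measured on a 5-px smoothed copy of the polyline (rad/px, >= 0);
- angle: end-to-end orientation, CCW from the x-axis, in [0, 180).

External filament sets (manual annotations, other software) can be
imported from a documented CSV or JSON polyline format so the correlation
stage can run on third-party detections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph

from .images import BinaryMask, GrayImage
from .preprocessing import ThresholdSpec, binarize

__all__ = [
    "Filament",
    "FilamentFilterSpec",
    "trace_filaments",
    "trace_filaments_from_mask",
    "filament_table",
    "filament_from_points",
    "read_filaments",
]

_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Filament:
    """One traced fiber as an ordered polyline with descriptors."""

    id: int
    points: np.ndarray  # (n, 2) float array of (row, col)
    length_px: float
    width_px: float
    curvature: float  # mean |d theta| per px of arc, rad/px
    angle_deg: float
    length_um: Optional[float] = None
    verified: bool = False

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid of the polyline vertices."""
        return (float(self.points[:, 1].mean()), float(self.points[:, 0].mean()))


@dataclass
class FilamentFilterSpec:
    """Acceptance window applied to traced filaments."""

    min_length: float = 10.0
    max_length: float = float("inf")
    max_curvature: float = float("inf")
    max_width: float = float("inf")
    cell_mask: Optional[BinaryMask] = None

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


# ---------------------------------------------------------------------------
# geometry helpers


def _arc_length(pts: np.ndarray) -> float:
    if pts.shape[0] < 2:
        return 0.0
    return float(np.hypot(*np.diff(pts.astype(float), axis=0).T).sum())


def _smoothed_length(pts: np.ndarray, window: int = 5) -> float:
    """Arc length of the lightly smoothed polyline.

    Raw 8-connected pixel chains overestimate the length of oblique lines
    by up to ~8% (chain-code bias); a small moving average on the
    coordinates largely removes it.
    """
    pts = pts.astype(float)
    if pts.shape[0] >= window:
        sm = ndimage.uniform_filter1d(pts, size=window, axis=0, mode="nearest")
        # pin the endpoints so the length never drops below the chord
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    return _arc_length(pts)


def _orientation_deg(p: np.ndarray, q: np.ndarray) -> float:
    dx = q[1] - p[1]
    dy = -(q[0] - p[0])  # y points up
    return float(np.degrees(np.arctan2(dy, dx)) % 180.0)


def _mean_abs_curvature(pts: np.ndarray, window: int = 5) -> float:
    pts = pts.astype(float)
    if pts.shape[0] < 3:
        return 0.0
    if pts.shape[0] >= window:
        sm = ndimage.uniform_filter1d(pts, size=window, axis=0, mode="nearest")
    else:
        sm = pts
    d = np.diff(sm, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    keep = seg > 1e-9
    d, seg = d[keep], seg[keep]
    if d.shape[0] < 2:
        return 0.0
    theta = np.arctan2(d[:, 0], d[:, 1])
    dtheta = np.diff(theta)
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    total = _arc_length(sm)
    if total <= 0:
        return 0.0
    return float(np.abs(dtheta).sum() / total)


def filament_from_points(
    points: np.ndarray,
    fil_id: int = 1,
    width_px: float = 1.0,
    scale: Optional[float] = None,
) -> Filament:
    """Build a Filament from an ordered (row, col) polyline, computing the
    derived descriptors."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("a filament needs >= 2 (row, col) points")
    length = _arc_length(pts)
    return Filament(
        id=int(fil_id),
        points=pts,
        length_px=length,
        width_px=max(float(width_px), 1.0),
        curvature=_mean_abs_curvature(pts),
        angle_deg=_orientation_deg(pts[0], pts[-1]),
        length_um=length * scale if scale is not None else None,
    )


# ---------------------------------------------------------------------------
# skeleton graph tracing


def _skeleton_arcs(sk: np.ndarray) -> tuple[list[dict], np.ndarray]:
    """Split a skeleton into branch-free arcs.

    Returns (arcs, cluster_labels).  Each arc is
    ``{"points": (n,2) int array, "clusters": (start_cluster, end_cluster)}``
    where clusters are labels of 8-connected groups of skeleton pixels
    whose neighbor count differs from 2 (endpoints and junctions); -1
    marks an arc end inside a pure cycle.
    """
    deg = ndimage.convolve(sk.astype(np.uint8), np.ones((3, 3), np.uint8), mode="constant") - sk
    node_mask = sk & (deg != 2)
    clusters = _skmeasure.label(node_mask, connectivity=2)

    sk_set = sk
    h, w = sk.shape

    def neighbors(r: int, c: int):
        for dr, dc in _NBRS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and sk_set[rr, cc]:
                yield rr, cc

    visited_edges: set[frozenset] = set()
    visited_px = np.zeros_like(sk, dtype=bool)
    arcs: list[dict] = []

    node_pixels = np.argwhere(node_mask)
    for r0, c0 in node_pixels:
        for r1, c1 in neighbors(r0, c0):
            edge = frozenset(((r0, c0), (r1, c1)))
            if edge in visited_edges:
                continue
            visited_edges.add(edge)
            if node_mask[r1, c1]:
                # two adjacent nodes: a 2-px arc (possibly within one cluster)
                if clusters[r0, c0] != clusters[r1, c1]:
                    arcs.append(
                        {
                            "points": np.array([[r0, c0], [r1, c1]]),
                            "clusters": (int(clusters[r0, c0]), int(clusters[r1, c1])),
                        }
                    )
                continue
            path = [(int(r0), int(c0)), (int(r1), int(c1))]
            prev, cur = (int(r0), int(c0)), (int(r1), int(c1))
            visited_px[cur] = True
            while not node_mask[cur]:
                # a degree-2 pixel has exactly two neighbors: prev and next
                nxt = None
                for nb in neighbors(*cur):
                    if nb != prev:
                        nxt = nb
                        break
                if nxt is None:
                    break
                visited_edges.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
                if not node_mask[cur]:
                    visited_px[cur] = True
            start_cl = int(clusters[path[0]])
            end_cl = int(clusters[path[-1]]) if node_mask[path[-1]] else -1
            arcs.append({"points": np.array(path), "clusters": (start_cl, end_cl)})

    # pure cycles: degree-2 pixels never reached from any node
    rest = sk & ~visited_px & ~node_mask
    for region in _skmeasure.regionprops(_skmeasure.label(rest, connectivity=2)):
        coords = [tuple(p) for p in region.coords]
        start = coords[0]
        path = [start]
        prev, cur = None, start
        while True:
            nxt = None
            for nb in neighbors(*cur):
                if nb != prev and nb in set(coords):
                    nxt = nb
                    break
            if nxt is None or nxt == start:
                break
            path.append(nxt)
            prev, cur = cur, nxt
            if len(path) > len(coords):
                break
        if len(path) >= 2:
            arcs.append({"points": np.array(path), "clusters": (-1, -1)})
    return arcs, clusters


def _end_direction(points: np.ndarray, end: int, span: int = 5) -> np.ndarray:
    """Unit vector pointing from the given end *into* the arc."""
    pts = points.astype(float)
    if end == 0:
        seg = pts[: min(span, len(pts))]
        v = seg[-1] - seg[0]
    else:
        seg = pts[-min(span, len(pts)) :]
        v = seg[0] - seg[-1]
    n = np.hypot(*v)
    return v / n if n > 0 else np.array([0.0, 0.0])


def _merge_arcs(arcs: list[dict], merge_tol_deg: float) -> list[np.ndarray]:
    """Join arcs across junctions when they continue each other within
    ``merge_tol_deg`` of a straight pass-through; return merged polylines."""
    # incident arc-ends per junction cluster
    incident: dict[int, list[tuple[int, int]]] = {}
    for i, arc in enumerate(arcs):
        for end in (0, 1):
            cl = arc["clusters"][end]
            if cl > 0:
                incident.setdefault(cl, []).append((i, end))

    partner: dict[tuple[int, int], tuple[int, int]] = {}
    for cl, ends in incident.items():
        if len(ends) < 2:
            continue
        cands = []
        for a in range(len(ends)):
            for b in range(a + 1, len(ends)):
                ia, ea = ends[a]
                ib, eb = ends[b]
                if ia == ib:
                    continue
                va = _end_direction(arcs[ia]["points"], ea)
                vb = _end_direction(arcs[ib]["points"], eb)
                cos = float(np.clip(-(va @ vb), -1.0, 1.0))
                dev = float(np.degrees(np.arccos(cos)))  # 0 = perfect continuation
                if dev <= merge_tol_deg:
                    cands.append((dev, ends[a], ends[b]))
        cands.sort(key=lambda t: t[0])
        used: set[tuple[int, int]] = set()
        for dev, ea, eb in cands:
            if ea in used or eb in used or ea in partner or eb in partner:
                continue
            partner[ea] = eb
            partner[eb] = ea
            used.add(ea)
            used.add(eb)

    # assemble chains of arcs linked by partner relations
    consumed = [False] * len(arcs)
    polylines: list[np.ndarray] = []

    def arc_points(i: int, enter_end: int) -> np.ndarray:
        pts = arcs[i]["points"]
        return pts if enter_end == 0 else pts[::-1]

    for i, arc in enumerate(arcs):
        if consumed[i]:
            continue
        # find a free end to start from (unpaired); cycles start anywhere
        start_end = None
        for end in (0, 1):
            if (i, end) not in partner:
                start_end = end
                break
        if start_end is None:
            start_end = 0
        chain = []
        cur: Optional[tuple[int, int]] = (i, start_end)
        while cur is not None:
            ci, ce = cur
            if consumed[ci]:
                break
            consumed[ci] = True
            chain.append(arc_points(ci, ce))
            exit_end = 1 - ce
            cur = partner.get((ci, exit_end))
        pts = chain[0]
        for nxt in chain[1:]:
            if np.array_equal(pts[-1], nxt[0]):
                nxt = nxt[1:]
            pts = np.vstack([pts, nxt])
        if pts.shape[0] >= 2:
            polylines.append(pts)
    return polylines


def _extend_tips(pts: np.ndarray, fg: np.ndarray, sk: np.ndarray) -> np.ndarray:
    """Walk each polyline end outward along its tangent while still on the
    fiber mask.

    Skeletonization retracts fiber tips — on oblique, tapering tips by
    well over the half-width — which matters when an adhesion sits exactly
    at the fiber end.  From each polyline end a greedy walk follows the
    foreground, always stepping to the 8-neighbor best aligned with the
    running tangent (within 60 degrees), so it tracks staircase wedges to
    their apex.  The walk stops on meeting another skeleton pixel (an end
    abutting a junction must not run along the crossing fiber) or after
    ``max_steps``.
    """
    pts = pts.astype(float)
    if pts.shape[0] < 3:
        return pts
    h, w = fg.shape
    span = min(5, pts.shape[0])
    max_steps = 15
    nbrs = np.array(_NBRS, dtype=float)
    nbr_units = nbrs / np.hypot(nbrs[:, 0], nbrs[:, 1])[:, None]
    prepend: list[np.ndarray] = []
    append: list[np.ndarray] = []
    for end in (0, 1):
        p = pts[0] if end == 0 else pts[-1]
        ref = pts[span - 1] if end == 0 else pts[-span]
        tang = p - ref
        n = float(np.hypot(*tang))
        if n == 0:
            continue
        tang = tang / n
        cur = np.rint(p).astype(int)
        chain_tail = pts[:span] if end == 0 else pts[-span:]
        visited = {tuple(np.rint(q).astype(int)) for q in chain_tail}
        visited.add(tuple(cur))
        ext: list[np.ndarray] = []
        for _ in range(max_steps):
            best_i, best_dot = -1, 0.5  # cos(60 deg) alignment floor
            for i, (dr, dc) in enumerate(_NBRS):
                r, c = cur[0] + dr, cur[1] + dc
                if (r, c) in visited or not (0 <= r < h and 0 <= c < w) or not fg[r, c]:
                    continue
                dot = float(nbr_units[i] @ tang)
                if dot > best_dot:
                    best_i, best_dot = i, dot
            if best_i < 0:
                break
            step = np.array(_NBRS[best_i])
            nxt = cur + step
            if sk[nxt[0], nxt[1]]:
                break  # reached another skeleton structure (junction side)
            ext.append(nxt.astype(float))
            visited.add(tuple(nxt))
            tang = 0.7 * tang + 0.3 * nbr_units[best_i]
            tang = tang / float(np.hypot(*tang))
            cur = nxt
        if ext:
            (prepend if end == 0 else append).extend(ext)
    if prepend:
        pts = np.vstack([np.array(prepend[::-1]), pts])
    if append:
        pts = np.vstack([pts, np.array(append)])
    return pts


def trace_filaments_from_mask(
    mask: BinaryMask,
    filters: Optional[FilamentFilterSpec] = None,
    scale: Optional[float] = None,
    merge_tol_deg: float = 20.0,
) -> list[Filament]:
    """Trace filaments on an already-binarized fiber mask."""
    filters = filters or FilamentFilterSpec()
    fg = mask.pixels
    if filters.cell_mask is not None:
        fg = fg & filters.cell_mask.pixels
    sk = _skmorph.skeletonize(fg)
    if not sk.any():
        return []
    arcs, _ = _skeleton_arcs(sk)
    edt = ndimage.distance_transform_edt(fg)
    polylines = [_extend_tips(p, fg, sk) for p in _merge_arcs(arcs, merge_tol_deg)]

    out: list[Filament] = []
    for pts in polylines:
        length = _smoothed_length(pts)
        ridge = edt[np.rint(pts[:, 0]).astype(int), np.rint(pts[:, 1]).astype(int)]
        width = max(2.0 * float(ridge.mean()), 1.0)
        fil = Filament(
            id=0,
            points=pts.astype(float),
            length_px=length,
            width_px=width,
            curvature=_mean_abs_curvature(pts),
            angle_deg=_orientation_deg(pts[0], pts[-1]),
            length_um=length * scale if scale is not None else None,
        )
        if (
            filters.min_length <= fil.length_px <= filters.max_length
            and fil.curvature <= filters.max_curvature
            and fil.width_px <= filters.max_width
        ):
            out.append(fil)
    out.sort(key=lambda f: (-f.length_px, f.points[0, 0], f.points[0, 1]))
    for i, f in enumerate(out):
        f.id = i + 1
    return out


def trace_filaments(
    img: GrayImage,
    threshold: Optional[ThresholdSpec] = None,
    filters: Optional[FilamentFilterSpec] = None,
    merge_tol_deg: float = 20.0,
) -> list[Filament]:
    """Binarize the actin image and trace fiber polylines.

    Result is sorted by length descending with ids assigned in that order.
    An empty result is valid (e.g. a blank image).
    """
    threshold = threshold or ThresholdSpec(method="otsu")
    level = threshold.resolve(img)
    mask = binarize(img, level)
    return trace_filaments_from_mask(
        mask, filters=filters, scale=img.scale, merge_tol_deg=merge_tol_deg
    )


# ---------------------------------------------------------------------------
# tables and external import


def filament_table(filaments: Sequence[Filament], path) -> tuple[Path, Path]:
    """Write the per-filament CSV and a cell-level summary CSV.

    Returns (table_path, summary_path).  The summary holds the filament
    count and the circular mean orientation (axial statistics: angles are
    doubled before averaging so 179 deg and 1 deg average near 0).
    """
    path = Path(path)
    rows = []
    for f in filaments:
        x, y = f.centroid
        rows.append(
            {
                "id": f.id,
                "x": x,
                "y": y,
                "length_px": f.length_px,
                "length_um": f.length_um if f.length_um is not None else np.nan,
                "width_px": f.width_px,
                "curvature": f.curvature,
                "angle_deg": f.angle_deg,
                "verified": bool(f.verified),
            }
        )
    cols = ["id", "x", "y", "length_px", "length_um", "width_px", "curvature", "angle_deg", "verified"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)

    if filaments:
        ang = np.radians([f.angle_deg for f in filaments]) * 2.0
        mean_angle = float(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) / 2.0) % 180.0
        mean_len = float(np.mean([f.length_px for f in filaments]))
    else:
        mean_angle, mean_len = np.nan, np.nan
    summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    pd.DataFrame(
        [{"filament_count": len(filaments), "mean_length_px": mean_len, "mean_angle_deg": mean_angle}]
    ).to_csv(summary_path, index=False)
    return path, summary_path


def read_filaments(path, scale: Optional[float] = None) -> list[Filament]:
    """Import an external filament set.

    CSV format: columns ``filament_id, row, col`` (points in order, one row
    per vertex; optional ``width_px`` column).  JSON format:
    ``{"filaments": [{"id": 1, "points": [[r, c], ...], "width_px": 2.0}]}``.
    """
    path = Path(path)
    fils: list[Filament] = []
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for rec in payload["filaments"]:
            fils.append(
                filament_from_points(
                    np.asarray(rec["points"], dtype=float),
                    fil_id=int(rec.get("id", len(fils) + 1)),
                    width_px=float(rec.get("width_px", 1.0)),
                    scale=scale,
                )
            )
    else:
        df = pd.read_csv(path)
        for fid, grp in df.groupby("filament_id", sort=True):
            width = float(grp["width_px"].iloc[0]) if "width_px" in grp else 1.0
            fils.append(
                filament_from_points(
                    grp[["row", "col"]].to_numpy(dtype=float),
                    fil_id=int(fid),
                    width_px=width,
                    scale=scale,
                )
            )
    return fils
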