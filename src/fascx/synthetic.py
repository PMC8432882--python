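"""Ground-truthed synthetic FA / actin image pairs.

The generator emulates two-channel confocal data of a fibroblast-like
cell: the adhesion channel holds bright elliptical blobs (paxillin-like
puncta), the actin channel holds bright curvilinear fibers
(phalloidin-like stress fibers).  A fraction of the fibers carry an
adhesion at both ends (ventral-fiber analog), a fraction at one end
(dorsal analog) and the rest none (transverse-arc analog); the remaining
adhesions are placed free of any fiber.  Gaussian blur emulates opening
the confocal pinhole (``blur_sigma`` 0 / 2 / 4 px are the in-focus, mild
and severe out-of-focus analogs) and additive Gaussian noise emulates
detection noise.

Every scene ships with machine-readable ground truth — the planted
geometry, its rasterized "expert" masks for both channels, and the
fiber-to-adhesion attachment map — so segmentation, tracing, correlation
and evaluation can all be scored without any external data.

Layout guarantees (by rejection sampling with bounded retries):
fibers keep a Chebyshev clearance from each other, attached adhesions sit
within 2 px of their fiber's endpoint, and free adhesions keep a clearance
from every fiber, so the planted attachment map is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import draw as _skdraw

from .images import BinaryMask, GrayImage

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "truth_to_masks", "SceneGenerationError"]


class SceneGenerationError(RuntimeError):
    """Raised when the requested objects cannot be packed into the canvas."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic two-channel scene.

    Defaults describe a plausible ventral-plane field of view at
    0.12 um/px: a handful of long fibers (60-150 px = 7-18 um), adhesions
    with main axes of 6-13 px (0.7-1.6 um) and peak intensities spread
    over a wide range so that dim adhesions exist, on a dark noisy
    background.
    """

    image_size: tuple[int, int] = (384, 384)
    n_filaments: int = 6
    n_fas: int = 12
    fa_axis_range: tuple[float, float] = (6.0, 13.0)
    filament_length_range: tuple[float, float] = (60.0, 150.0)
    attach_fraction_both_ends: float = 1.0 / 3.0
    attach_fraction_one_end: float = 1.0 / 3.0
    blur_sigma: float = 0.0
    noise_sd: float = 0.0
    background: float = 20.0
    fa_amplitude_range: tuple[float, float] = (40.0, 170.0)
    fiber_amplitude_range: tuple[float, float] = (80.0, 160.0)
    fiber_half_width: int = 1  # drawn fiber thickness = 2*half_width + 1 px
    fiber_clearance: float = 20.0  # min Chebyshev distance between fibers, px
    fa_clearance: float = 16.0  # free FA center to any fiber point, px
    scale_um_per_px: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.attach_fraction_both_ends + self.attach_fraction_one_end > 1.0 + 1e-9:
            raise ValueError("attachment fractions must sum to <= 1")
        for rng_ in (self.fa_axis_range, self.filament_length_range):
            if rng_[0] > rng_[1]:
                raise ValueError("ranges must be ordered (min, max)")
        if self.image_size[0] < 32 or self.image_size[1] < 32:
            raise ValueError("image size too small")
        n_attached = 2 * self.n_both_ends + self.n_one_end
        if n_attached > self.n_fas:
            raise ValueError(
                f"attachment plan needs {n_attached} adhesions but n_fas={self.n_fas}"
            )

    @property
    def n_both_ends(self) -> int:
        return int(round(self.attach_fraction_both_ends * self.n_filaments))

    @property
    def n_one_end(self) -> int:
        return int(round(self.attach_fraction_one_end * self.n_filaments))


@dataclass
class GroundTruth:
    """Planted geometry plus rasterized truth masks."""

    fa_records: list[dict]  # center (row, col), axes (a, b) full lengths, angle_deg, attached_to
    filament_records: list[np.ndarray]  # dense (n, 2) polylines, (row, col)
    attachment_map: dict[int, set[int]]  # filament index -> set of FA indices
    fa_mask: BinaryMask
    filament_mask: BinaryMask

    @property
    def planted_filament_classes(self) -> dict[str, int]:
        """NAAF/SAAF/MAAF counts implied by the planted attachments."""
        counts = {"NAAF": 0, "SAAF": 0, "MAAF": 0}
        for i in range(len(self.filament_records)):
            n = len(self.attachment_map.get(i, ()))
            counts["NAAF" if n == 0 else "SAAF" if n == 1 else "MAAF"] += 1
        return counts


# ---------------------------------------------------------------------------
# geometry sampling


def _sample_fiber(rng: np.random.Generator, spec: SceneSpec) -> Optional[np.ndarray]:
    """Dense polyline of a gently curved fiber, or None if out of bounds."""
    h, w = spec.image_size
    margin = 12.0
    length = rng.uniform(*spec.filament_length_range)
    p0 = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
    theta = rng.uniform(0, np.pi)
    direction = np.array([np.sin(theta), np.cos(theta)])
    p2 = p0 + length * direction
    perp = np.array([-direction[1], direction[0]])
    bow = rng.uniform(-0.08, 0.08) * length
    p1 = (p0 + p2) / 2.0 + bow * perp
    t = np.linspace(0.0, 1.0, max(int(3 * length), 16))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
    if (
        pts[:, 0].min() < margin
        or pts[:, 0].max() > h - margin
        or pts[:, 1].min() < margin
        or pts[:, 1].max() > w - margin
    ):
        return None
    return pts


def _chebyshev_min(tree: Optional[cKDTree], pts: np.ndarray) -> float:
    if tree is None:
        return np.inf
    d, _ = tree.query(pts, k=1, p=np.inf)
    return float(np.min(d))


def generate_scene(spec: SceneSpec) -> tuple[GrayImage, GrayImage, GroundTruth]:
    """Render one (fa_image, actin_image, truth) triple.

    Deterministic: the same spec (including seed) yields bit-identical
    images and truth.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size

    # --- fibers ------------------------------------------------------------
    fibers: list[np.ndarray] = []
    all_pts: list[np.ndarray] = []
    tree: Optional[cKDTree] = None
    for _ in range(spec.n_filaments):
        placed = False
        for _attempt in range(300):
            pts = _sample_fiber(rng, spec)
            if pts is None:
                continue
            if _chebyshev_min(tree, pts) < spec.fiber_clearance:
                continue
            fibers.append(pts)
            all_pts.append(pts)
            tree = cKDTree(np.vstack(all_pts))
            placed = True
            break
        if not placed:
            raise SceneGenerationError(
                f"could not place fiber {len(fibers) + 1}/{spec.n_filaments}; "
                "canvas too crowded for the requested clearance"
            )

    # --- attachment plan ---------------------------------------------------
    n_both, n_one = spec.n_both_ends, spec.n_one_end
    fiber_order = rng.permutation(spec.n_filaments)
    attachment_map: dict[int, set[int]] = {i: set() for i in range(spec.n_filaments)}
    fa_records: list[dict] = []

    def _plant_fa(center: np.ndarray, along: Optional[np.ndarray], attached_to) -> None:
        a = rng.uniform(*spec.fa_axis_range)
        b = a / rng.uniform(1.6, 2.6)
        if along is not None:
            angle = float(np.degrees(np.arctan2(-along[0], along[1])) % 180.0)
            angle += rng.uniform(-10, 10)
        else:
            angle = rng.uniform(0, 180)
        fa_records.append(
            {
                "center": (float(center[0]), float(center[1])),
                "axes": (float(a), float(b)),
                "angle_deg": float(angle % 180.0),
                "amplitude": float(rng.uniform(*spec.fa_amplitude_range)),
                "attached_to": attached_to,
            }
        )

    for k, fi in enumerate(fiber_order):
        pts = fibers[fi]
        ends = []
        if k < n_both:
            ends = [pts[0], pts[-1]]
        elif k < n_both + n_one:
            ends = [pts[0] if rng.random() < 0.5 else pts[-1]]
        for end in ends:
            tangent = pts[-1] - pts[0]
            center = end + rng.uniform(-1.0, 1.0, size=2)  # within 2 px of the endpoint
            _plant_fa(center, tangent, attached_to=int(fi))
            attachment_map[int(fi)].add(len(fa_records) - 1)

    # --- free adhesions ----------------------------------------------------
    n_free = spec.n_fas - len(fa_records)
    fa_centers = [np.array(r["center"]) for r in fa_records]
    margin = 10.0
    max_axis = spec.fa_axis_range[1]
    for _ in range(n_free):
        placed = False
        for _attempt in range(500):
            c = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
            if tree is not None:
                d, _ = tree.query(c[None, :], k=1, p=np.inf)
                if float(d[0]) < spec.fa_clearance + max_axis / 2.0:
                    continue
            if fa_centers and np.min(np.max(np.abs(np.array(fa_centers) - c), axis=1)) < 1.8 * max_axis:
                continue
            _plant_fa(c, None, attached_to=None)
            fa_centers.append(c)
            placed = True
            break
        if not placed:
            raise SceneGenerationError("could not place a free adhesion; canvas too crowded")

    # --- rasterize ---------------------------------------------------------
    fa_img = np.full((h, w), float(spec.background))
    actin_img = np.full((h, w), float(spec.background))

    fil_mask = np.zeros((h, w), dtype=bool)
    for pts in fibers:
        amp = rng.uniform(*spec.fiber_amplitude_range)
        one = np.zeros((h, w), dtype=bool)
        ipts = np.rint(pts).astype(int)
        for (r0, c0), (r1, c1) in zip(ipts[:-1], ipts[1:]):
            rr, cc = _skdraw.line(r0, c0, r1, c1)
            one[rr, cc] = True
        if spec.fiber_half_width > 0:
            one = ndimage.binary_dilation(
                one, structure=ndimage.generate_binary_structure(2, 2),
                iterations=spec.fiber_half_width,
            )
        actin_img[one] = np.maximum(actin_img[one], spec.background + amp)
        fil_mask |= one

    fa_mask = np.zeros((h, w), dtype=bool)
    for rec in fa_records:
        rr, cc = _skdraw.ellipse(
            rec["center"][0],
            rec["center"][1],
            rec["axes"][0] / 2.0,
            rec["axes"][1] / 2.0,
            shape=(h, w),
            rotation=np.radians(rec["angle_deg"]),
        )
        fa_img[rr, cc] = np.maximum(fa_img[rr, cc], spec.background + rec["amplitude"])
        fa_mask[rr, cc] = True

    def _finish(arr: np.ndarray) -> np.ndarray:
        if spec.blur_sigma > 0:
            arr = ndimage.gaussian_filter(arr, sigma=spec.blur_sigma, mode="reflect")
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)

    fa_image = GrayImage(_finish(fa_img), scale=spec.scale_um_per_px)
    actin_image = GrayImage(_finish(actin_img), scale=spec.scale_um_per_px)
    truth = GroundTruth(
        fa_records=fa_records,
        filament_records=fibers,
        attachment_map=attachment_map,
        fa_mask=BinaryMask(fa_mask),
        filament_mask=BinaryMask(fil_mask),
    )
    return fa_image, actin_image, truth


def truth_to_masks(truth: GroundTruth) -> tuple[BinaryMask, BinaryMask]:
    """Expert-mask analogs rasterized from the planted geometry."""
    return truth.fa_mask, truth.filament_mask
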