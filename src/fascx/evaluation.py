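"""Segmentation evaluation against expert masks.

Any two binary segmentations can be compared: the "truth" mask (typically
a human expert's annotation) and the "eval" mask (typically software
output).  The comparison runs two ways at once:

- **object-wise** — 8-connected objects are labeled on both masks and a
  (truth, eval) pair counts as a match when their pixel overlap reaches a
  configurable percentage of the smaller object.  Matching is
  many-to-many; the ``multi_one_to_n`` / ``multi_n_to_one`` counters
  summarize truth objects split across several eval objects and eval
  objects spanning several truth objects.
- **pixel-wise** — plain true-positive / false-positive / false-negative
  pixel counts, independent of the object bookkeeping.

The similarity coefficient condenses the object-wise result into one
number::

    SC = found_area / (missed_area + false_positive_area)

where found/missed areas are truth-mask pixels of matched/unmatched truth
objects and the false-positive area is eval-mask pixels of unmatched eval
objects.  Higher is more similar; a perfect segmentation (zero
denominator with nonzero found area) reports ``inf``.

:func:`threshold_finder` selects, from a handful of annotated examples,
the thresholding method and level that best reproduce the expert masks
(pixel F1 over an exhaustive 256-level scan), and reports alongside the
level each method would pick without mask input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as _skmeasure

from .images import BinaryMask, GrayImage
from .preprocessing import THRESHOLD_METHODS, auto_threshold, binarize

__all__ = [
    "EvaluationReport",
    "SCInputs",
    "evaluate_masks",
    "similarity_coefficient",
    "sc_inputs_from_report",
    "render_eval_map",
    "threshold_finder",
]


@dataclass
class EvaluationReport:
    """Object-wise and pixel-wise bookkeeping of one mask comparison."""

    matches: list[tuple[int, int, int]]  # (truth_id, eval_id, overlap_px)
    truth_not_matched: list[int]
    eval_not_matched: list[int]
    multi_one_to_n: int
    multi_n_to_one: int
    pixel_counts: dict[str, int]  # true_pos / false_pos / false_neg
    truth_sizes: dict[int, int]
    eval_sizes: dict[int, int]

    @property
    def matched_truth_ids(self) -> set[int]:
        return {t for t, _, _ in self.matches}

    @property
    def matched_eval_ids(self) -> set[int]:
        return {e for _, e, _ in self.matches}


@dataclass
class SCInputs:
    """Areas feeding the similarity coefficient (all in truth/eval px)."""

    found_area: float
    missed_area: float
    fp_area: float

    def __post_init__(self) -> None:
        if self.found_area < 0 or self.missed_area < 0 or self.fp_area < 0:
            raise ValueError("SC input areas must be >= 0")


def evaluate_masks(
    truth: BinaryMask,
    eval_mask: BinaryMask,
    min_overlap_pct: float = 1.0,
    thicken_px: int = 0,
    overlap_base: str = "min",
) -> EvaluationReport:
    """Compare an output mask against a truth mask object- and pixel-wise.

    A (truth, eval) object pair matches when their overlap is at least
    ``min_overlap_pct`` percent of the reference size, where the reference
    is the smaller object (``overlap_base="min"``), the truth object
    (``"truth"``) or the eval object (``"eval"``).  ``thicken_px`` dilates
    both masks before comparison (square structuring element, one px per
    iteration).
    """
    if truth.shape != eval_mask.shape:
        raise ValueError(f"mask shapes differ: {truth.shape} vs {eval_mask.shape}")
    if not min_overlap_pct > 0:
        raise ValueError("min_overlap_pct must be > 0")
    if overlap_base not in ("min", "truth", "eval"):
        raise ValueError("overlap_base must be 'min', 'truth' or 'eval'")

    t = truth.pixels
    e = eval_mask.pixels
    if thicken_px > 0:
        se = np.ones((3, 3), dtype=bool)
        t = ndimage.binary_dilation(t, structure=se, iterations=thicken_px)
        e = ndimage.binary_dilation(e, structure=se, iterations=thicken_px)

    t_lab = _skmeasure.label(t, connectivity=2)
    e_lab = _skmeasure.label(e, connectivity=2)
    t_n, e_n = int(t_lab.max()), int(e_lab.max())
    truth_sizes = {i: int(s) for i, s in enumerate(np.bincount(t_lab.ravel())[1:], start=1)}
    eval_sizes = {i: int(s) for i, s in enumerate(np.bincount(e_lab.ravel())[1:], start=1)}

    # joint histogram of overlapping labels
    both = t & e
    pair_idx = t_lab[both].astype(np.int64) * (e_n + 1) + e_lab[both].astype(np.int64)
    overlap = np.bincount(pair_idx, minlength=0)

    matches: list[tuple[int, int, int]] = []
    for idx in np.nonzero(overlap)[0]:
        ti, ei = divmod(int(idx), e_n + 1)
        if ti == 0 or ei == 0:
            continue
        ov = int(overlap[idx])
        if overlap_base == "min":
            ref = min(truth_sizes[ti], eval_sizes[ei])
        elif overlap_base == "truth":
            ref = truth_sizes[ti]
        else:
            ref = eval_sizes[ei]
        if ov >= min_overlap_pct / 100.0 * ref:
            matches.append((ti, ei, ov))
    matches.sort()

    matched_t = {m[0] for m in matches}
    matched_e = {m[1] for m in matches}
    truth_not_matched = sorted(set(range(1, t_n + 1)) - matched_t)
    eval_not_matched = sorted(set(range(1, e_n + 1)) - matched_e)

    t_counts: dict[int, int] = {}
    e_counts: dict[int, int] = {}
    for ti, ei, _ in matches:
        t_counts[ti] = t_counts.get(ti, 0) + 1
        e_counts[ei] = e_counts.get(ei, 0) + 1
    multi_one_to_n = sum(1 for c in t_counts.values() if c >= 2)
    multi_n_to_one = sum(1 for c in e_counts.values() if c >= 2)

    pixel_counts = {
        "true_pos": int((t & e).sum()),
        "false_pos": int((e & ~t).sum()),
        "false_neg": int((t & ~e).sum()),
    }
    return EvaluationReport(
        matches=matches,
        truth_not_matched=truth_not_matched,
        eval_not_matched=eval_not_matched,
        multi_one_to_n=multi_one_to_n,
        multi_n_to_one=multi_n_to_one,
        pixel_counts=pixel_counts,
        truth_sizes=truth_sizes,
        eval_sizes=eval_sizes,
    )


def sc_inputs_from_report(report: EvaluationReport) -> SCInputs:
    """Derive SC areas from an object-wise report.

    Found/missed areas come from the truth mask's object sizes; the
    false-positive area from the eval mask's unmatched object sizes.
    """
    matched = report.matched_truth_ids
    found = sum(s for i, s in report.truth_sizes.items() if i in matched)
    missed = sum(s for i, s in report.truth_sizes.items() if i not in matched)
    fp = sum(report.eval_sizes[i] for i in report.eval_not_matched)
    return SCInputs(found_area=float(found), missed_area=float(missed), fp_area=float(fp))


def similarity_coefficient(inp: SCInputs) -> float:
    """SC = found / (missed + false positive); inf for a perfect match."""
    denom = inp.missed_area + inp.fp_area
    if inp.found_area == 0:
        return 0.0
    if denom == 0:
        return math.inf
    return inp.found_area / denom


# evaluation map colors: found blue, missed yellow, false positive red
_FOUND = (0, 0, 255)
_MISSED = (255, 255, 0)
_FALSE_POS = (255, 0, 0)


def render_eval_map(
    truth: BinaryMask, eval_mask: BinaryMask, report: EvaluationReport
) -> np.ndarray:
    """Color map of the comparison: truth objects blue (found) or yellow
    (missed); unmatched eval objects superimposed in red."""
    t_lab = _skmeasure.label(truth.pixels, connectivity=2)
    e_lab = _skmeasure.label(eval_mask.pixels, connectivity=2)
    rgb = np.zeros((*truth.shape, 3), dtype=np.uint8)
    matched = report.matched_truth_ids
    for i in range(1, int(t_lab.max()) + 1):
        rgb[t_lab == i] = _FOUND if i in matched else _MISSED
    for i in report.eval_not_matched:
        rgb[e_lab == i] = _FALSE_POS
    return rgb


def threshold_finder(
    images: Sequence[GrayImage],
    masks: Sequence[BinaryMask],
    methods: Sequence[str] = ("intermodes", "otsu", "mean", "triangle", "li"),
) -> pd.DataFrame:
    """Rank thresholding methods against annotated example masks.

    For each method, an exhaustive scan over all 256 candidate levels (on
    the pooled rescaled intensity range) finds the level maximizing the
    pixel F1 score against the masks; the returned table reports that
    level, the found / false-positive / false-negative pixel rates of the
    whole images processed at it, and the level the method would pick on
    its own (no mask input).  Rows are sorted best-first by F1.
    """
    if len(images) == 0 or len(images) != len(masks):
        raise ValueError("need equally many images and masks (>= 1)")
    for img, m in zip(images, masks):
        if img.shape != m.shape:
            raise ValueError("image/mask shape mismatch")

    px_all = np.concatenate([img.pixels.ravel().astype(float) for img in images])
    truth_all = np.concatenate([m.pixels.ravel() for m in masks])
    lo, hi = float(px_all.min()), float(px_all.max())
    levels = np.unique(np.rint(lo + (np.arange(256) + 0.5) / 256.0 * (hi - lo)).astype(int)) if hi > lo else np.array([int(lo)])

    total_truth = int(truth_all.sum())
    best_level, best_f1, best_stats = None, -1.0, None
    for level in levels:
        pred = px_all > level
        tp = int((pred & truth_all).sum())
        fp = int((pred & ~truth_all).sum())
        fn = total_truth - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        if f1 > best_f1:
            best_level, best_f1 = int(level), f1
            best_stats = (tp, fp, fn)

    n_px = px_all.size
    tp_b, fp_b, fn_b = best_stats
    rows = []
    for method in methods:
        if method not in THRESHOLD_METHODS or method == "manual":
            raise ValueError(f"unsupported method {method!r}")
        auto_levels = []
        for img in images:
            try:
                auto_levels.append(auto_threshold(img, method))
            except ValueError:
                auto_levels.append(None)
        valid = [l for l in auto_levels if l is not None]
        auto_level = float(np.mean(valid)) if valid else np.nan
        # F1 the method's own (mask-free) level reaches, used for ranking
        if valid:
            pred = px_all > auto_level
            tp = int((pred & truth_all).sum())
            fp = int((pred & ~truth_all).sum())
            fn = total_truth - tp
            f1_auto = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        else:
            f1_auto = np.nan
        rows.append(
            {
                "method": method,
                "auto_level": auto_level,
                "auto_f1": f1_auto,
                "best_level": best_level,
                "best_f1": best_f1,
                # whole-image pixel rates at the F1-optimal level
                "found_rate": tp_b / n_px,
                "false_pos_rate": fp_b / n_px,
                "false_neg_rate": fn_b / n_px,
            }
        )
    df = pd.DataFrame(rows).sort_values("auto_f1", ascending=False, na_position="last")
    return df.reset_index(drop=True)
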