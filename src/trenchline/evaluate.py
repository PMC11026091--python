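"""Segmentation and tracking quality metrics.

Cell-level evaluation matches predicted regions to ground-truth regions
one-to-one by intersection-over-union (IoU ≥ 0.6 by default, greedy in
descending IoU) and reports true positives, false positives, false
negatives and the Jaccard index TP/(TP+FP+FN).  A threshold-bias sweep
re-runs segmentation and tracking across a range of Otsu scale factors to
expose how a thresholding choice systematically shifts extracted cell
sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import Calibration, PipelineParams
from .segment import segment_stack
from .stats import physiology_table
from .track import build_lineages, extract_regions

__all__ = [
    "EvaluationReport",
    "mask_iou",
    "match_and_count",
    "jaccard_index",
    "evaluate_stacks",
    "threshold_bias_curve",
    "lineage_agreement",
]


@dataclass
class EvaluationReport:
    tp: int  # correctly identified cells
    fp: int  # identified cells not present in the ground truth
    fn: int  # ground-truth cells not identified
    ji: float  # Jaccard index TP/(TP+FP+FN)
    iou_min: float
    frames: pd.DataFrame  # per-frame detail


def mask_iou(region_a: np.ndarray, region_b: np.ndarray) -> float:
    """Intersection-over-union of two boolean masks of the same geometry."""
    a = np.asarray(region_a, dtype=bool)
    b = np.asarray(region_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("regions must share frame geometry")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both regions are empty")
    return float(np.logical_and(a, b).sum() / union)


def _pair_ious(pred: np.ndarray, gt: np.ndarray):
    """IoU for every overlapping (pred label, gt label) pair of one frame."""
    pred = np.asarray(pred).astype(np.int64)
    gt = np.asarray(gt).astype(np.int64)
    pred_areas = dict(zip(*np.unique(pred[pred > 0], return_counts=True)))
    gt_areas = dict(zip(*np.unique(gt[gt > 0], return_counts=True)))
    both = (pred > 0) & (gt > 0)
    pairs, counts = np.unique(
        np.stack([pred[both], gt[both]]), axis=1, return_counts=True
    ) if both.any() else (np.empty((2, 0), dtype=np.int64), np.empty(0, dtype=np.int64))
    ious = {}
    for (p, g), inter in zip(pairs.T, counts):
        ious[(int(p), int(g))] = inter / (pred_areas[p] + gt_areas[g] - inter)
    return ious, set(pred_areas), set(gt_areas)


def match_frame(pred: np.ndarray, gt: np.ndarray, iou_min: float = 0.6,
                strict: bool = False) -> tuple[int, int, int]:
    """One-to-one greedy IoU matching for a single frame.

    Candidate pairs at IoU ≥ iou_min (or > iou_min with ``strict``) are
    accepted in descending IoU, each region used at most once.
    """
    ious, pred_labels, gt_labels = _pair_ious(pred, gt)
    admissible = [(v, p, g) for (p, g), v in ious.items()
                  if (v > iou_min if strict else v >= iou_min)]
    admissible.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_g = set(), set()
    tp = 0
    for v, p, g in admissible:
        if p in used_p or g in used_g:
            continue
        used_p.add(p)
        used_g.add(g)
        tp += 1
    return tp, len(pred_labels) - tp, len(gt_labels) - tp


def match_and_count(pred_masks: np.ndarray, gt_masks: np.ndarray,
                    iou_min: float = 0.6, strict: bool = False) -> tuple[int, int, int]:
    """(TP, FP, FN) summed over all frames of two labeled-mask stacks."""
    pred_masks = np.asarray(pred_masks)
    gt_masks = np.asarray(gt_masks)
    if pred_masks.shape != gt_masks.shape:
        raise ValueError("stacks must share geometry")
    if pred_masks.ndim == 2:
        pred_masks, gt_masks = pred_masks[None], gt_masks[None]
    if not 0 < iou_min < 1:
        raise ValueError("iou_min must be in (0, 1)")
    tp = fp = fn = 0
    for t in range(pred_masks.shape[0]):
        a, b, c = match_frame(pred_masks[t], gt_masks[t], iou_min, strict)
        tp, fp, fn = tp + a, fp + b, fn + c
    return tp, fp, fn


def jaccard_index(tp: int, fp: int, fn: int) -> float:
    """Cell-level Jaccard index TP/(TP+FP+FN)."""
    denom = tp + fp + fn
    if denom <= 0:
        raise ValueError("TP+FP+FN must be > 0")
    return tp / denom


def evaluate_stacks(pred_masks: np.ndarray, gt_masks: np.ndarray,
                    iou_min: float = 0.6, strict: bool = False) -> EvaluationReport:
    """Full evaluation report with per-frame detail rows."""
    pred_masks = np.asarray(pred_masks)
    gt_masks = np.asarray(gt_masks)
    if pred_masks.shape != gt_masks.shape:
        raise ValueError("stacks must share geometry")
    rows = []
    for t in range(pred_masks.shape[0]):
        tp, fp, fn = match_frame(pred_masks[t], gt_masks[t], iou_min, strict)
        rows.append({"frame": t, "tp": tp, "fp": fp, "fn": fn})
    frames = pd.DataFrame(rows)
    tp, fp, fn = int(frames.tp.sum()), int(frames.fp.sum()), int(frames.fn.sum())
    ji = jaccard_index(tp, fp, fn) if tp + fp + fn > 0 else float("nan")
    return EvaluationReport(tp=tp, fp=fp, fn=fn, ji=ji, iou_min=iou_min, frames=frames)


def optimal_match_count(pred: np.ndarray, gt: np.ndarray, iou_min: float = 0.6,
                        strict: bool = False) -> int:
    """Maximum-cardinality one-to-one matching (exhaustive; small frames only).

    Independent reference for the greedy matcher: enumerates every
    assignment of predicted to ground-truth regions over the admissible
    pairs and returns the largest number of matches.
    """
    ious, pred_labels, _ = _pair_ious(pred, gt)
    admissible = {pg: v for pg, v in ious.items()
                  if (v > iou_min if strict else v >= iou_min)}
    pred_list = sorted(pred_labels)
    if len(pred_list) > 8:
        raise ValueError("exhaustive matcher is for frames with few regions")

    def best(i: int, used_g: frozenset) -> int:
        if i == len(pred_list):
            return 0
        score = best(i + 1, used_g)  # leave pred i unmatched
        for (p, g) in admissible:
            if p == pred_list[i] and g not in used_g:
                score = max(score, 1 + best(i + 1, used_g | {g}))
        return score

    return best(0, frozenset())


def threshold_bias_curve(sub_stack: np.ndarray, params: PipelineParams,
                         scales, calibration: Calibration | None = None) -> pd.DataFrame:
    """Re-run segmentation and tracking across an Otsu-scale sweep.

    Returns one row per scale with the mean segmented cell area (px²) and
    the mean birth/division lengths of the tracked cells — the desk-scale
    demonstration that a thresholding choice systematically shifts every
    extracted size statistic.
    """
    scales = list(scales)
    if any(b < a for a, b in itertools.pairwise(scales)):
        raise ValueError("scales must be non-decreasing")
    rows = []
    for scale in scales:
        p = params.replace(**{"segment.otsu_scale": float(scale)})
        masks = segment_stack(sub_stack, p)
        areas = [f.area for t in range(masks.shape[0])
                 for f in extract_regions(masks[t], frame=t)]
        cells = build_lineages(masks, p)
        table = physiology_table(cells, calibration or p.calibration,
                                 complete_only=False)
        done = table[table.complete]
        rows.append({
            "otsu_scale": float(scale),
            "n_regions": len(areas),
            "mean_cell_area_px2": float(np.mean(areas)) if areas else float("nan"),
            "mean_sb": float(done.sb_um.mean()) if len(done) else float("nan"),
            "mean_sd": float(done.sd_um.mean()) if len(done) else float("nan"),
        })
    return pd.DataFrame(rows)


def lineage_agreement(cells, gt_table: pd.DataFrame, pixel_size: float,
                      frame_tol: int = 1, y_tol_px: float = 10.0) -> float:
    """Fraction of ground-truth complete cycles recovered by tracking.

    A ground-truth complete cycle (observed birth and division, tracked
    parent, both daughters observed) counts as recovered if some tracked
    cell in the same channel is born within ``frame_tol`` frames and
    ``y_tol_px`` pixels of it, divides within ``frame_tol`` frames of it,
    and has two tracked daughters — i.e. the local tree around the cell is
    reproduced.
    """
    gt = gt_table[(gt_table.division_frame >= 0) & (gt_table.parent_id >= 0)]
    if "daughters_observed" in gt:
        gt = gt[gt.daughters_observed]
    if len(gt) == 0:
        raise ValueError("ground truth contains no complete cycles")
    by_channel: dict[int, list] = {}
    for c in cells:
        if c.division_frame is not None and c.daughters is not None:
            by_channel.setdefault(c.channel, []).append(c)
    hits = 0
    for row in gt.itertuples():
        for c in by_channel.get(row.channel, ()):
            if (abs(c.birth_frame - row.birth_frame) <= frame_tol
                    and abs(c.features[0].centroid_y - row.birth_y_px) <= y_tol_px
                    and abs(c.division_frame - row.division_frame) <= frame_tol):
                hits += 1
                break
    return hits / len(gt)
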