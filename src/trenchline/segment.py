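"""Classical cell segmentation: scaled Otsu threshold, distance transform,
morphological cleanup, and random-walker boundary refinement.

Input frames come from background subtraction (cells bright on near-zero
background).  The pipeline per frame:

1. binarize at ``otsu_scale`` x the Otsu threshold;
2. morphological opening (disk, radius ``first_opening``) to sever thin
   links between regions;
3. Euclidean distance transform of the binary mask;
4. cut the EDT at ``distance_threshold`` (erodes each region toward its
   ridge, separating touching cells);
5. second opening (disk, radius ``second_opening``);
6. drop regions smaller than ``min_object_size`` px² or touching the
   image border;
7. label the survivors;
8. use the labels to seed a random walker on the subtracted frame, which
   grows the eroded seeds back to the intensity boundaries.

Raising ``otsu_scale`` makes the binarization stricter, so the segmented
cell area is non-increasing in it — the mechanism by which a thresholding
choice propagates into every downstream size statistic.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.morphology import disk
from skimage.segmentation import random_walker

from .config import PipelineParams

__all__ = ["NoContrastError", "otsu_threshold", "seed_labels", "segment_frame",
           "segment_stack"]

log = logging.getLogger(__name__)


class NoContrastError(ValueError):
    """Raised when an image has no intensity contrast to threshold."""


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: the cut maximizing between-class variance.

    For integer images the histogram is taken over the integer values and
    the returned threshold is an intensity value t such that foreground =
    pixels > t; this is exactly the exhaustive scan over all possible
    integer cuts.  Float images are binned to ``nbins`` levels first.
    """
    image = np.asarray(image)
    flat = image.ravel()
    if flat.min() == flat.max():
        raise NoContrastError("no contrast: image is constant")
    if np.issubdtype(image.dtype, np.integer):
        lo, hi = int(flat.min()), int(flat.max())
        counts = np.bincount((flat - lo).astype(np.int64), minlength=hi - lo + 1)
        values = np.arange(lo, hi + 1, dtype=float)
    else:
        counts, edges = np.histogram(flat, bins=nbins)
        values = (edges[:-1] + edges[1:]) / 2.0
        counts = counts.astype(np.int64)
    # cumulative class statistics for every cut between bins i and i+1
    w0 = np.cumsum(counts)[:-1].astype(float)
    w1 = counts.sum() - w0
    cum_mean = np.cumsum(counts * values)[:-1]
    mu0 = cum_mean / np.where(w0 > 0, w0, 1)
    mu1 = (cum_mean[-1] + counts[-1] * values[-1] - cum_mean) / np.where(w1 > 0, w1, 1)
    between = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(between))
    return float(values[best])


def seed_labels(sub_frame: np.ndarray, params: PipelineParams) -> np.ndarray:
    """Steps 1-7: thresholded, cleaned, size/border-filtered seed labels."""
    seg = params.segment
    img = np.asarray(sub_frame)
    try:
        t = otsu_threshold(img)
    except NoContrastError:
        return np.zeros(img.shape, dtype=np.int32)
    binary = img > seg.otsu_scale * t
    opened = ndimage.binary_opening(binary, disk(seg.first_opening))
    # interior shot-noise holes would make the EDT carve spurious cuts
    # through cell bodies; the transform's job is severing links *between*
    # regions, so holes are filled first
    opened = ndimage.binary_fill_holes(opened)
    edt = ndimage.distance_transform_edt(opened)
    cut = edt > seg.distance_threshold
    opened2 = ndimage.binary_opening(cut, disk(seg.second_opening))
    labels = sk_label(opened2, connectivity=1)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    border = np.zeros_like(opened2)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for lbl in range(1, labels.max() + 1):
        region = labels == lbl
        if region.sum() >= seg.min_object_size and not (region & border).any():
            keep[lbl] = True
    filtered = np.where(keep[labels], labels, 0)
    # relabel sequentially, preserving top-to-bottom (closed-end-first) order
    out = np.zeros_like(filtered, dtype=np.int32)
    order = sorted(np.unique(filtered[filtered > 0]),
                   key=lambda l: ndimage.center_of_mass(filtered == l)[0])
    for new, old in enumerate(order, start=1):
        out[filtered == old] = new
    return out


def _refine_random_walker(sub_frame: np.ndarray, seeds: np.ndarray,
                          params: PipelineParams) -> np.ndarray:
    """Step 8: grow seed labels to intensity boundaries with a random walker.

    Background is seeded from pixels farther than twice the distance
    threshold from any seed label *and* below the scaled Otsu threshold
    (so blurred cell tails are never seeded as background); the walker
    then only has to decide the contested band around each cell, where
    the intensity gradient pins the boundary.
    """
    seg = params.segment
    img = np.asarray(sub_frame, dtype=float)
    if img.max() > img.min():
        img = (img - img.min()) / (img.max() - img.min())
    try:
        t = otsu_threshold(np.asarray(sub_frame))
    except NoContrastError:
        return np.zeros(img.shape, dtype=np.int32)
    below = np.asarray(sub_frame) <= seg.otsu_scale * t
    dist_to_seed = ndimage.distance_transform_edt(seeds == 0)
    markers = np.where(seeds > 0, seeds + 1, 0).astype(np.int32)
    markers[(dist_to_seed > 2 * seg.distance_threshold) & below & (markers == 0)] = 1
    if not (markers > 1).any():
        return np.zeros(img.shape, dtype=np.int32)
    if not (markers == 1).any():  # no far background; keep the seeds as-is
        return seeds.astype(np.int32)
    walked = random_walker(img, markers, beta=seg.random_walker_beta, mode="bf")
    out = np.where(walked > 1, walked - 1, 0).astype(np.int32)
    return out


def segment_frame(sub_frame: np.ndarray, params: PipelineParams,
                  refine: bool = True) -> np.ndarray:
    """Segment one subtracted frame into an integer-labeled mask.

    Labels are 1..k ordered from the closed channel end; 0 is background.
    An empty result is valid (e.g. a blank frame).  ``refine=False`` stops
    after step 7 (the seed labels), which is useful for diagnostics.
    """
    seeds = seed_labels(sub_frame, params)
    if not refine or seeds.max() == 0:
        return seeds
    return _refine_random_walker(sub_frame, seeds, params)


def segment_stack(sub_stack: np.ndarray, params: PipelineParams,
                  refine: bool = True) -> np.ndarray:
    """Frame-wise segmentation of a subtracted channel stack."""
    sub_stack = np.asarray(sub_stack)
    out = np.zeros(sub_stack.shape, dtype=np.int32)
    for t in range(sub_stack.shape[0]):
        out[t] = segment_frame(sub_stack[t], params, refine=refine)
    counts = [int(out[t].max()) for t in range(out.shape[0])]
    log.info("segmented %d frames; region counts min/median/max = %d/%d/%d",
             len(counts), min(counts), int(np.median(counts)), max(counts))
    return out
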