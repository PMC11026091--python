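"""Empty-channel background subtraction for classical segmentation.

Phase-contrast cells are dark objects inside a dark-walled device, so a
direct threshold would pick up the channel borders.  Subtracting an
aligned empty-channel template removes the device image; the result is
kept as (empty − full) clipped at zero, which simultaneously inverts the
contrast so that cells are the only bright objects on a near-zero
background — the form the Otsu/random-walker segmentation expects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineParams

__all__ = ["SubtractedStack", "align_empty", "subtract_stack", "make_empty_template"]

log = logging.getLogger(__name__)


@dataclass
class SubtractedStack:
    """Background-subtracted channel stack with per-frame alignment info."""

    pixels: np.ndarray  # (T, H, W), same dtype as the input stack
    shifts: np.ndarray  # (T, 2) int, (dy, dx) applied to the empty template
    scores: np.ndarray  # (T,) normalized cross-correlation at the chosen shift


def align_empty(full_frame: np.ndarray, empty_frame: np.ndarray,
                align_pad: int) -> tuple[tuple[int, int], float]:
    """Best integer shift of the empty template onto a full frame.

    Exhaustive search over (dy, dx) in ±align_pad maximizing the
    normalized cross-correlation of the overlapping region.  Exhaustive
    integer search is cheap at channel-crop scale and exactly
    reproducible.  Returns ((dy, dx), score).
    """
    full = np.asarray(full_frame, dtype=float)
    empty = np.asarray(empty_frame, dtype=float)
    if full.shape != empty.shape:
        raise ValueError("frames must share shape")
    if align_pad >= min(full.shape):
        raise ValueError(f"align_pad {align_pad} >= frame dimension {min(full.shape)}")
    h, w = full.shape
    best = ((0, 0), -np.inf)
    for dy in range(-align_pad, align_pad + 1):
        for dx in range(-align_pad, align_pad + 1):
            fy0, fy1 = max(0, dy), min(h, h + dy)
            fx0, fx1 = max(0, dx), min(w, w + dx)
            a = full[fy0:fy1, fx0:fx1]
            b = empty[fy0 - dy:fy1 - dy, fx0 - dx:fx1 - dx]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                score = 1.0 if sa == sb else 0.0
            else:
                score = float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))
            if score > best[1]:
                best = ((dy, dx), score)
    return best


def _shift_with_edge(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate by integer (dy, dx), padding with edge values."""
    pad_y = (max(dy, 0), max(-dy, 0))
    pad_x = (max(dx, 0), max(-dx, 0))
    padded = np.pad(img, (pad_y, pad_x), mode="edge")
    h, w = img.shape
    return padded[pad_y[1]:pad_y[1] + h, pad_x[1]:pad_x[1] + w]


def make_empty_template(empty_stack: np.ndarray) -> np.ndarray:
    """Time-mean empty-channel template (one per FOV); averaging suppresses
    shot noise relative to using a single empty frame."""
    stack = np.asarray(empty_stack, dtype=float)
    if stack.ndim == 2:
        return stack
    return stack.mean(axis=0)


def subtract_stack(full: np.ndarray, empty: np.ndarray,
                   params: PipelineParams) -> SubtractedStack:
    """Subtract an aligned empty template from every frame of a full stack.

    Per frame: align the template within ±align_pad, form
    clip(empty_aligned − full, 0) and cast back to the input dtype, so
    cells (dark in phase) come out as the brightest objects on a near-zero
    background.  Alignment scores below 0.5 are logged — imperfect
    alignment leaves wall artifacts that are the most common failure mode
    of this method.
    """
    if empty is None:
        raise ValueError(
            "no empty-channel template available; classify channels first and "
            "pick an artifact-free empty channel"
        )
    full = np.asarray(full)
    stack = full[None] if full.ndim == 2 else full
    template = make_empty_template(empty)
    if template.shape != stack.shape[1:]:
        raise ValueError("empty template shape does not match the full stack")
    pad = params.subtract.align_pad
    n = stack.shape[0]
    out = np.zeros_like(stack)
    shifts = np.zeros((n, 2), dtype=int)
    scores = np.zeros(n)
    info = np.iinfo(stack.dtype) if np.issubdtype(stack.dtype, np.integer) else None
    for t in range(n):
        (dy, dx), score = align_empty(stack[t], template, pad)
        aligned = _shift_with_edge(template, dy, dx)
        diff = np.clip(aligned - stack[t].astype(float), 0, None)
        if info is not None:
            diff = np.clip(np.round(diff), info.min, info.max)
        out[t] = diff.astype(stack.dtype)
        shifts[t] = (dy, dx)
        scores[t] = score
        # the absolute score drops with cell load (cells decorrelate the
        # overlap); only genuinely poor wall alignment goes much lower
        if score < 0.3:
            log.warning("poor background alignment at frame %d (score %.2f)", t, score)
    if full.ndim == 2:
        return SubtractedStack(out[0], shifts, scores)
    return SubtractedStack(out, shifts, scores)
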