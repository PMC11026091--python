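"""Growth-channel detection, drift correction, cropping and classification.

A mother-machine FOV contains a periodic array of vertical growth
channels.  This stage finds them on the temporal mean image, estimates
integer-pixel stage drift against frame 0, crops one image stack per
channel (with drift compensated), and classifies each channel as full or
empty from the time correlation of its y-profile: an empty channel is a
static scene, so consecutive profiles are nearly perfectly correlated,
while growing and dividing cells continually reshape the profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import PipelineParams

__all__ = [
    "ChannelBox",
    "ChannelClassification",
    "detect_channels",
    "estimate_drift",
    "crop_channel_stacks",
    "classify_channels",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChannelBox:
    """Half-open crop box of one growth channel in FOV coordinates."""

    fov: int
    channel: int  # id, ordered by x-center
    y0: int
    y1: int
    x0: int
    x1: int

    @property
    def center_x(self) -> float:
        return (self.x0 + self.x1 - 1) / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.y1 - self.y0, self.x1 - self.x0


@dataclass(frozen=True)
class ChannelClassification:
    label: str  # "full" | "empty" | "ignored"
    score: float  # mean time-correlation of the y-profile, in [-1, 1]


def _mexican_hat(scale: float) -> np.ndarray:
    """Zero-mean Mexican-hat (negated Laplacian-of-Gaussian) kernel."""
    sigma = scale / 2.0
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    k = (1.0 - (x / sigma) ** 2) * np.exp(-(x**2) / (2 * sigma**2))
    return k - k.mean()


def detect_channels(time_mean_image: np.ndarray, params: PipelineParams,
                    fov: int = 0) -> list[ChannelBox]:
    """Detect channel crop boxes on the temporal mean of one FOV.

    Channel x-centers are maxima of a matched-filter response: the column
    profile of the mean image convolved with a Mexican hat at the expected
    channel width (light interior flanked by dark walls).  Peaks must be
    at least ~0.6 channel separations apart and rise above half the
    strongest response.  The y-extent spans the rows where horizontal
    contrast (the wall/interior intensity split) is present, padded toward
    the trench.  All boxes share a common width and y-extent so the
    resulting stacks are co-registered.
    """
    img = np.asarray(time_mean_image, dtype=float)
    cw = params.compile.channel_width
    sep = params.compile.channel_separation

    # rows containing channel structure: strong horizontal contrast
    row_contrast = np.percentile(img, 95, axis=1) - np.percentile(img, 5, axis=1)
    strong = row_contrast > 0.5 * row_contrast.max() if row_contrast.max() > 0 else None
    if strong is None or not strong.any():
        warnings.warn("no periodic channel structure found (uniform image)")
        return []
    rows = np.flatnonzero(strong)
    y_lo, y_hi = int(rows[0]), int(rows[-1]) + 1

    profile = img[y_lo:y_hi].mean(axis=0)
    response = np.convolve(profile - profile.mean(), _mexican_hat(cw), mode="same")
    from scipy.signal import find_peaks

    peaks, props = find_peaks(response, distance=max(2, int(0.6 * sep)))
    if peaks.size == 0 or response[peaks].max() <= 0:
        warnings.warn("no periodic channel structure found")
        return []
    # empty channels respond more strongly than cell-smeared ones, so the
    # relative cut must be generous
    peaks = peaks[response[peaks] > 0.3 * response[peaks].max()]
    if peaks.size == 0:
        warnings.warn("no periodic channel structure found")
        return []

    bw = int(round(1.4 * cw))
    y0 = max(0, y_lo - 4)
    y1 = min(img.shape[0], y_hi + 10)
    boxes = []
    for i, cx in enumerate(sorted(int(p) for p in peaks)):
        x0 = cx - bw // 2
        x1 = x0 + bw
        if x0 < 0 or x1 > img.shape[1]:
            continue  # partial channel at the image edge
        boxes.append(ChannelBox(fov=fov, channel=i, y0=y0, y1=y1, x0=x0, x1=x1))
    log.info("detected %d channels (fov %d)", len(boxes), fov)
    return boxes


def _profile_shift(ref: np.ndarray, mov: np.ndarray, pad: int) -> tuple[int, float]:
    """Integer shift maximizing the normalized correlation of two 1D profiles."""
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    best = (0, -np.inf)
    for d in range(-pad, pad + 1):
        if d >= 0:
            a, b = ref[d:], mov[:mov.size - d]
        else:
            a, b = ref[:d], mov[-d:]
        denom = a.std() * b.std()
        c = float((a * b).mean() / denom) if denom > 0 else -np.inf
        if c > best[1]:
            best = (d, c)
    return best


def estimate_drift(frames: np.ndarray, max_shift: int = 15) -> np.ndarray:
    """Integer (dy, dx) scene shift of each frame relative to frame 0.

    The mother-machine scene is projection-separable (vertical channel
    walls, horizontal closed-end/trench edges), so each axis is estimated
    by maximizing the cross-correlation of the whole-FOV intensity
    projection along that axis against frame 0, searched exhaustively over
    ±``max_shift`` px.  A positive shift means the scene content moved
    down/right.  Ambiguous (flat) profiles yield zero shift with a warning.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) stack")
    n = frames.shape[0]
    shifts = np.zeros((n, 2), dtype=int)
    ref = frames[0].astype(float)
    if np.ptp(ref) == 0:
        warnings.warn("flat reference frame; drift set to zero")
        return shifts
    ref_row, ref_col = ref.mean(axis=1), ref.mean(axis=0)
    pad = min(max_shift, frames.shape[1] // 4, frames.shape[2] // 4)
    for t in range(1, n):
        mov = frames[t].astype(float)
        if np.ptp(mov) == 0:
            warnings.warn(f"flat frame {t}; drift set to zero")
            continue
        dy, cy = _profile_shift(ref_row, mov.mean(axis=1), pad)
        dx, cx = _profile_shift(ref_col, mov.mean(axis=0), pad)
        if not np.isfinite(cy) or not np.isfinite(cx):
            warnings.warn(f"ambiguous correlation at frame {t}; zero shift")
            continue
        # matching ref[d:] against mov[:-d] means the scene moved by -d
        shifts[t] = (-dy, -dx)
    return shifts


def crop_channel_stacks(frames: np.ndarray, boxes: list[ChannelBox],
                        shifts: np.ndarray | None = None) -> dict[int, np.ndarray]:
    """Crop one drift-compensated stack per channel box.

    Each frame is cropped at the box offset by that frame's scene shift,
    so channel walls are stationary in the output.  Crops extending past
    the image are padded with edge values (and logged).
    """
    frames = np.asarray(frames)
    n, h, w = frames.shape
    if shifts is None:
        shifts = np.zeros((n, 2), dtype=int)
    shifts = np.asarray(shifts, dtype=int)
    out: dict[int, np.ndarray] = {}
    for box in boxes:
        stack = np.empty((n, box.y1 - box.y0, box.x1 - box.x0), dtype=frames.dtype)
        for t in range(n):
            dy, dx = shifts[t]
            y0, y1 = box.y0 + dy, box.y1 + dy
            x0, x1 = box.x0 + dx, box.x1 + dx
            if y1 <= 0 or y0 >= h or x1 <= 0 or x0 >= w:
                raise ValueError(
                    f"channel {box.channel} box entirely outside image at frame {t}"
                )
            py0, py1 = max(0, -y0), max(0, y1 - h)
            px0, px1 = max(0, -x0), max(0, x1 - w)
            crop = frames[t, max(0, y0):min(h, y1), max(0, x0):min(w, x1)]
            if py0 or py1 or px0 or px1:
                log.debug("edge-padding channel %d frame %d", box.channel, t)
                crop = np.pad(crop, ((py0, py1), (px0, px1)), mode="edge")
            stack[t] = crop
        out[box.channel] = stack
    return out


def classify_channels(stack: np.ndarray, params: PipelineParams) -> ChannelClassification:
    """Classify one channel stack as full or empty.

    The score is the mean Pearson correlation between y-profiles (row
    means of the channel crop, lightly smoothed along y to suppress shot
    noise) of frame pairs a fixed lag apart (default lag ~T/10, so that
    slow single-file growth accumulates into a visible profile change).
    Pairs where either profile has zero variance contribute 1.0 (a
    perfectly static scene).  Channels scoring at or above
    ``compile.empty_threshold`` are empty.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if n < 2:
        warnings.warn("single-frame stack cannot be classified; assuming full")
        return ChannelClassification("full", 0.0)
    lag = params.compile.correlation_lag or max(1, n // 10)
    lag = min(lag, n - 1)
    profiles = gaussian_filter1d(stack.mean(axis=2), 2.0, axis=1)  # (T, H)
    cors = []
    for t in range(n - lag):
        a, b = profiles[t], profiles[t + lag]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            cors.append(1.0)
        else:
            cors.append(float(np.corrcoef(a, b)[0, 1]))
    score = float(np.mean(cors))
    label = "empty" if score >= params.compile.empty_threshold else "full"
    return ChannelClassification(label, score)
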