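"""Population physiology statistics, fluorescence quantification and
fluorescent-focus detection.

The headline single-cell quantities are birth length S_b, division length
S_d, added length Δ = S_d − S_b (the adder's regulated variable),
generation time τ, elongation rate λ and the septum position.  Their
distributions are summarized by mean, SD and CV over complete cycles, and
correlations (e.g. Δ against S_b, flat for an adder) are shown as binned
means with standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import Calibration
from .track import CellCycleStats, CellRecord, annotate_cycles

__all__ = [
    "DistributionSummary",
    "BinnedCorrelation",
    "Focus",
    "filter_complete",
    "summarize_distributions",
    "physiology_table",
    "binned_means",
    "binned_slope",
    "measure_fluorescence",
    "detect_foci",
    "link_foci",
]

PARAM_COLUMNS = ("sb_um", "sd_um", "delta_um", "tau_min", "lambda_per_min",
                 "septum_ratio")


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    cv: float


@dataclass
class BinnedCorrelation:
    x_name: str
    y_name: str
    centers: np.ndarray  # per-bin mean of x
    means: np.ndarray  # per-bin mean of y
    sems: np.ndarray  # per-bin standard error of the mean of y
    counts: np.ndarray


@dataclass(frozen=True)
class Focus:
    frame: int
    y: int
    x: int
    intensity: float
    cell_label: int | None  # label of the mask region containing the peak


def filter_complete(cells: list[CellRecord]) -> list[CellRecord]:
    """Keep cells with observed birth and division and tracked relatives.

    A cycle enters the statistics only if the cell's birth was observed
    (it has a tracked parent), its division was observed, and both
    daughters were tracked — the filtering that keeps segmentation-edge
    artifacts and truncated first/last generations out of the physiology.
    """
    ids = {c.id for c in cells}
    return [c for c in cells
            if c.parent is not None and c.parent in ids
            and c.division_frame is not None
            and c.daughters is not None
            and all(d in ids for d in c.daughters)]


def summarize_distributions(values: np.ndarray) -> DistributionSummary:
    """Mean, sample SD (n−1 denominator) and CV of one parameter."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return DistributionSummary(n=int(values.size), mean=mean, sd=sd,
                               cv=sd / mean if mean != 0 else math.inf)


def physiology_table(cells: list[CellRecord],
                     calibration: Calibration | None = None,
                     complete_only: bool = True) -> pd.DataFrame:
    """One row of cell-cycle statistics per cell.

    With ``complete_only`` (default), rows are restricted to the
    mother-and-daughters-tracked subset of :func:`filter_complete`.
    """
    kept = filter_complete(cells) if complete_only else cells
    stats = annotate_cycles(cells, calibration)
    rows = []
    for cell in kept:
        if cell.id not in stats:
            continue
        s: CellCycleStats = stats[cell.id]
        rows.append({
            "cell_id": cell.id, "fov": cell.fov, "channel": cell.channel,
            "birth_frame": cell.birth_frame,
            "division_frame": cell.division_frame if cell.division_frame is not None else -1,
            "sb_um": s.sb, "sd_um": s.sd, "delta_um": s.delta, "tau_min": s.tau,
            "lambda_per_min": s.lam, "septum_ratio": s.septum_ratio,
            "complete": s.complete,
        })
    return pd.DataFrame(rows, columns=["cell_id", "fov", "channel", "birth_frame",
                                       "division_frame", *PARAM_COLUMNS, "complete"])


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """n/mean/SD/CV per physiological parameter, from a physiology table."""
    rows = []
    for col in PARAM_COLUMNS:
        vals = table[col].dropna().to_numpy(dtype=float)
        if vals.size >= 2:
            s = summarize_distributions(vals)
            rows.append({"parameter": col, "n": s.n, "mean": s.mean,
                         "sd": s.sd, "cv": s.cv})
    return pd.DataFrame(rows)


def binned_means(x: np.ndarray, y: np.ndarray, n_bins: int = 8,
                 min_per_bin: int = 20, x_name: str = "x",
                 y_name: str = "y") -> BinnedCorrelation:
    """Equal-count (quantile) binned means of y against x, with SEMs.

    Bins with fewer than ``min_per_bin`` points are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if x.size == 0 or np.ptp(x) == 0:
        raise ValueError("x values are all identical")
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    centers, means, sems, counts = [], [], [], []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n < min_per_bin:
            continue
        yy = y[sel]
        centers.append(float(x[sel].mean()))
        means.append(float(yy.mean()))
        sems.append(float(yy.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0)
        counts.append(n)
    return BinnedCorrelation(x_name, y_name, np.array(centers), np.array(means),
                             np.array(sems), np.array(counts))


def binned_slope(bc: BinnedCorrelation) -> tuple[float, float]:
    """Weighted least-squares slope (and its SE) through the binned means.

    Weights are the inverse SEM; with fewer than 3 usable bins the fit is
    unweighted on whatever bins exist.
    """
    if bc.centers.size < 2:
        raise ValueError("need at least 2 bins to fit a slope")
    w = np.where(bc.sems > 0, 1.0 / np.maximum(bc.sems, 1e-12), 1.0)
    coef, cov = np.polyfit(bc.centers, bc.means, 1, w=w, cov="unscaled")
    return float(coef[0]), float(math.sqrt(cov[0, 0]))


def measure_fluorescence(cells: list[CellRecord], mask_stack: np.ndarray,
                         fluor_stack: np.ndarray,
                         calibration: Calibration | None = None) -> pd.DataFrame:
    """Per cell and frame: integrated fluorescence, per-area and per-volume.

    ``integrated`` sums the fluorescence plane over the cell's mask
    pixels; ``per_area`` and ``per_volume`` divide by the region's area
    (px²) and capsule volume (px³).  The fluorescence stack must be
    registered to the mask stack (same crop geometry).
    """
    mask_stack = np.asarray(mask_stack)
    fluor_stack = np.asarray(fluor_stack)
    if mask_stack.shape != fluor_stack.shape:
        raise ValueError("mask and fluorescence stacks must share shape")
    rows = []
    for cell in cells:
        for feat in cell.features:
            if feat.label <= 0:  # interpolated gap frame: no mask region
                continue
            sel = mask_stack[feat.frame] == feat.label
            integrated = float(fluor_stack[feat.frame][sel].sum(dtype=np.float64))
            rows.append({
                "cell_id": cell.id, "frame": feat.frame, "label": feat.label,
                "integrated": integrated,
                "per_area": integrated / feat.area,
                "per_volume": integrated / feat.volume,
            })
    return pd.DataFrame(rows, columns=["cell_id", "frame", "label", "integrated",
                                       "per_area", "per_volume"])


def detect_foci(fluor_frame: np.ndarray, mask_frame: np.ndarray | None = None,
                frame: int = 0, spot_sigma: float = 1.5,
                threshold_sd: float = 5.0) -> list[Focus]:
    """Detect diffraction-limited fluorescent spots with a Laplacian filter.

    The frame is convolved with a (negated) Laplacian of Gaussian at the
    expected spot scale; local maxima whose response exceeds
    ``threshold_sd`` times the response's SD become foci.  Each focus is
    assigned to the cell whose mask contains its peak pixel (or to no cell
    if the peak lies on background).
    """
    img = np.asarray(fluor_frame, dtype=float)
    response = -ndimage.gaussian_laplace(img, sigma=spot_sigma)
    thr = threshold_sd * response.std()
    local_max = response == ndimage.maximum_filter(response, size=3)
    peaks = np.argwhere(local_max & (response > thr))
    foci = []
    for y, x in peaks:
        owner = None
        if mask_frame is not None:
            lbl = int(np.asarray(mask_frame)[y, x])
            owner = lbl if lbl > 0 else None
        foci.append(Focus(frame=frame, y=int(y), x=int(x),
                          intensity=float(img[y, x]), cell_label=owner))
    foci.sort(key=lambda f: f.intensity, reverse=True)
    return foci


def link_foci(foci_by_frame: list[list[Focus]], max_radius: float = 5.0) -> list[list[Focus]]:
    """Link detected foci across frames into tracks by nearest neighbor.

    A focus is appended to the track whose last focus is nearest within
    ``max_radius`` px and belongs to the same cell (by mask label); each
    track extends by at most one focus per frame.  Unclaimed foci start
    new tracks.
    """
    tracks: list[list[Focus]] = []
    for frame_foci in foci_by_frame:
        open_tracks = [t for t in tracks
                       if not frame_foci or t[-1].frame == frame_foci[0].frame - 1]
        claimed = set()
        for focus in frame_foci:
            best, best_d = None, max_radius
            for i, t in enumerate(open_tracks):
                if i in claimed or t[-1].cell_label != focus.cell_label:
                    continue
                d = math.hypot(t[-1].y - focus.y, t[-1].x - focus.x)
                if d <= best_d:
                    best, best_d = i, d
            if best is None:
                tracks.append([focus])
            else:
                open_tracks[best].append(focus)
                claimed.add(best)
    return tracks
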