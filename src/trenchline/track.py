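"""Lineage tracking by an a-priori decision tree, and cell-cycle statistics.

Mother-machine tracking exploits three facts: cells grow by a small
amount between frames, divide into two similarly sized daughters, and
cannot pass each other in the channel.  Regions and active cells are both
ordered from the closed end, and each cell is matched to zero regions
(candidate lost), one region (growth, if the length and area ratios fall
inside the configured bounds) or two adjacent regions (division, if the
combined size grows plausibly and each daughter takes a sensible share).
A cell that goes unmatched is retried for ``lost_cell_time`` frames before
being finalized as lost; regions first appearing beyond
``new_cell_y_cutoff`` from the closed end are never instantiated as new
cells (they must be daughters or debris).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import regionprops

from .config import Calibration, PipelineParams

__all__ = [
    "RegionFeature",
    "CellRecord",
    "CellCycleStats",
    "extract_regions",
    "link_frame",
    "build_lineages",
    "compute_cell_cycle",
    "annotate_cycles",
    "fit_elongation_rate",
]

log = logging.getLogger(__name__)

# each daughter's share of the combined daughter length must be sensible
_DIVISION_SHARE = (0.25, 0.75)


@dataclass(frozen=True)
class RegionFeature:
    """Geometry of one labeled region, in pixels."""

    frame: int
    label: int
    centroid_y: float
    centroid_x: float
    length: float  # px, along the channel axis (or major axis, see extract_regions)
    width: float  # px
    area: float  # px^2
    volume: float  # px^3, capsule model

    @staticmethod
    def capsule_volume(length: float, width: float) -> float:
        """Volume of a sphero-cylinder: cylinder of length l-w plus a sphere."""
        r = width / 2.0
        body = max(length - width, 0.0)
        return math.pi * r * r * body + (4.0 / 3.0) * math.pi * r**3


def extract_regions(mask_frame: np.ndarray, frame: int = 0,
                    length_method: str = "extent") -> list[RegionFeature]:
    """Measure every labeled region, sorted by centroid_y (closed end first).

    ``length_method='extent'`` (default) takes length/width as the
    bounding-box extents along/across the channel axis — appropriate for
    rod-shaped cells confined upright in a growth channel, and an unbiased
    estimate of pole-to-pole length.  ``'major_axis'`` uses the
    ellipse-equivalent major/minor axes instead (robust to tilt, but
    overestimates the pole-to-pole length of a rod).
    """
    feats = []
    for rp in regionprops(np.asarray(mask_frame).astype(np.int32)):
        if length_method == "extent":
            length = float(rp.bbox[2] - rp.bbox[0])
            width = float(rp.bbox[3] - rp.bbox[1])
        elif length_method == "major_axis":
            length = float(rp.axis_major_length)
            width = float(rp.axis_minor_length)
        else:
            raise ValueError(f"unknown length_method {length_method!r}")
        if width > length:
            length, width = width, length
        feats.append(RegionFeature(
            frame=frame, label=int(rp.label),
            centroid_y=float(rp.centroid[0]), centroid_x=float(rp.centroid[1]),
            length=length, width=width, area=float(rp.area),
            volume=RegionFeature.capsule_volume(length, width),
        ))
    feats.sort(key=lambda f: f.centroid_y)
    return feats


@dataclass
class CellRecord:
    """One tracked cell: per-frame geometry plus lineage links."""

    id: str
    fov: int
    channel: int
    birth_frame: int
    rank: int  # y-position rank at birth (0 = closed end)
    features: list[RegionFeature] = field(default_factory=list)
    parent: str | None = None
    daughters: tuple[str, str] | None = None
    division_frame: int | None = None
    status: str = "growing"  # growing | divided | lost | end
    interpolated_frames: list[int] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [f.frame for f in self.features]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.features])

    @property
    def areas(self) -> np.ndarray:
        return np.array([f.area for f in self.features])

    @property
    def last(self) -> RegionFeature:
        return self.features[-1]


@dataclass
class CellCycleStats:
    """Cell-cycle quantities; µm/min when a calibration is supplied."""

    sb: float  # length at birth
    sd: float | None  # length at the last frame before division
    delta: float | None  # sd - sb
    tau: float | None  # generation time
    lam: float | None  # elongation rate, exponential (log-linear) fit
    septum_ratio: float | None  # closed-end daughter's share of summed daughter birth lengths
    complete: bool


def _make_id(fov: int, channel: int, birth_frame: int, rank: int) -> str:
    return f"f{fov:02d}c{channel:02d}t{birth_frame:04d}r{rank}"


@dataclass
class _LinkDecision:
    kind: str  # "growth" | "division" | "lost" | "new" | "discard"
    cell: CellRecord | None
    regions: tuple[RegionFeature, ...]


def _ratio_ok(ratio: float, bounds: tuple[float, float]) -> bool:
    return bounds[0] <= ratio <= bounds[1]


def link_frame(active_cells: list[CellRecord], regions: list[RegionFeature],
               params: PipelineParams) -> list[_LinkDecision]:
    """Match active cells (ordered by y) against one frame's regions.

    Cells and regions are walked in parallel from the closed end, which
    enforces order preservation by construction.  When both a one-region
    (growth) and a two-region (division) hypothesis are admissible, the
    one whose total length ratio is closest to the geometric mean of the
    growth bounds wins.
    """
    tk = params.track
    ideal = math.sqrt(tk.growth_length_ratio[0] * tk.growth_length_ratio[1])
    decisions: list[_LinkDecision] = []
    used = [False] * len(regions)
    j = 0
    for cell in active_cells:
        while j < len(regions) and used[j]:
            j += 1
        prev = cell.last
        growth = division = None
        if j < len(regions):
            r = regions[j]
            lr = r.length / prev.length
            ar = r.area / prev.area
            if _ratio_ok(lr, tk.growth_length_ratio) and _ratio_ok(ar, tk.growth_area_ratio):
                growth = (lr, (r,))
        if j + 1 < len(regions) and not used[j + 1]:
            r1, r2 = regions[j], regions[j + 1]
            lr = (r1.length + r2.length) / prev.length
            ar = (r1.area + r2.area) / prev.area
            shares = (r1.length / (r1.length + r2.length),
                      r2.length / (r1.length + r2.length))
            if (_ratio_ok(lr, tk.growth_length_ratio)
                    and _ratio_ok(ar, tk.growth_area_ratio)
                    and all(_DIVISION_SHARE[0] <= s <= _DIVISION_SHARE[1] for s in shares)):
                division = (lr, (r1, r2))
        if growth and division:
            chosen = min((growth, division), key=lambda h: abs(h[0] - ideal))
        else:
            chosen = growth or division
        if chosen is None:
            decisions.append(_LinkDecision("lost", cell, ()))
        else:
            kind = "growth" if len(chosen[1]) == 1 else "division"
            decisions.append(_LinkDecision(kind, cell, chosen[1]))
            for r in chosen[1]:
                used[regions.index(r)] = True
            j += len(chosen[1])
    for k, r in enumerate(regions):
        if not used[k]:
            kind = "new" if r.centroid_y <= tk.new_cell_y_cutoff else "discard"
            decisions.append(_LinkDecision(kind, None, (r,)))
    return decisions


def build_lineages(mask_stack: np.ndarray, params: PipelineParams,
                   fov: int = 0, channel: int = 0,
                   length_method: str = "extent") -> list[CellRecord]:
    """Track one channel's labeled-mask stack into a lineage forest.

    Every region at frame 0 starts a cell (the initial occupants of the
    channel); thereafter regions enter only through division or, near the
    closed end, as new cells.  Candidate-lost cells are retried for
    ``lost_cell_time`` frames — a cell re-found within the window has its
    missing lengths linearly interpolated (flagged) — then finalized lost.
    """
    mask_stack = np.asarray(mask_stack)
    n_frames = mask_stack.shape[0]
    cells: list[CellRecord] = []
    active: list[CellRecord] = []  # growing or candidate-lost, ordered by y
    missing: dict[str, int] = {}  # cell id -> consecutive unmatched frames

    def new_cell(region: RegionFeature, t: int, rank: int,
                 parent: CellRecord | None = None) -> CellRecord:
        cell = CellRecord(id=_make_id(fov, channel, t, rank), fov=fov, channel=channel,
                          birth_frame=t, rank=rank, parent=parent.id if parent else None)
        cell.features.append(region)
        cells.append(cell)
        return cell

    for t in range(n_frames):
        regions = extract_regions(mask_stack[t], frame=t, length_method=length_method)
        if t == 0:
            for rank, r in enumerate(regions):
                active.append(new_cell(r, 0, rank))
            continue
        decisions = link_frame(active, regions, params)
        next_active: list[CellRecord] = []
        born: list[CellRecord] = []
        for d in decisions:
            if d.kind == "growth":
                cell = d.cell
                if missing.get(cell.id):
                    _interpolate_gap(cell, d.regions[0])
                cell.features.append(d.regions[0])
                missing[cell.id] = 0
                next_active.append(cell)
            elif d.kind == "division":
                mother = d.cell
                mother.division_frame = t
                mother.status = "divided"
                missing.pop(mother.id, None)
                # rank = the region's y-rank within the frame (unique per id)
                d1 = new_cell(d.regions[0], t, regions.index(d.regions[0]), parent=mother)
                d2 = new_cell(d.regions[1], t, regions.index(d.regions[1]), parent=mother)
                mother.daughters = (d1.id, d2.id)
                next_active += [d1, d2]
            elif d.kind == "lost":
                cell = d.cell
                missing[cell.id] = missing.get(cell.id, 0) + 1
                if missing[cell.id] > params.track.lost_cell_time:
                    cell.status = "lost"
                    missing.pop(cell.id)
                else:
                    next_active.append(cell)
            elif d.kind == "new":
                born.append(new_cell(d.regions[0], t, regions.index(d.regions[0])))
            # "discard": debris near the open end, ignored
        next_active += born
        next_active.sort(key=lambda c: c.last.centroid_y)
        active = next_active

    for cell in active:
        if cell.status == "growing":
            cell.status = "end"
    n_div = sum(1 for c in cells if c.status == "divided")
    log.info("channel %d: %d cells tracked, %d divisions, %d lost",
             channel, len(cells), n_div, sum(1 for c in cells if c.status == "lost"))
    return cells


def _interpolate_gap(cell: CellRecord, next_region: RegionFeature) -> None:
    """Fill a lost-window gap with linearly interpolated lengths (flagged)."""
    last = cell.last
    for f in range(last.frame + 1, next_region.frame):
        w = (f - last.frame) / (next_region.frame - last.frame)
        cell.features.append(RegionFeature(
            frame=f, label=-1,
            centroid_y=(1 - w) * last.centroid_y + w * next_region.centroid_y,
            centroid_x=(1 - w) * last.centroid_x + w * next_region.centroid_x,
            length=(1 - w) * last.length + w * next_region.length,
            width=(1 - w) * last.width + w * next_region.width,
            area=(1 - w) * last.area + w * next_region.area,
            volume=(1 - w) * last.volume + w * next_region.volume,
        ))
        cell.interpolated_frames.append(f)


def fit_elongation_rate(times: np.ndarray, lengths: np.ndarray) -> float:
    """Least-squares slope of ln(length) against time."""
    times = np.asarray(times, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 observations")
    return float(np.polyfit(times, np.log(lengths), 1)[0])


def compute_cell_cycle(cell: CellRecord, calibration: Calibration | None = None,
                       forest: dict[str, CellRecord] | None = None) -> CellCycleStats:
    """Cell-cycle statistics of one record.

    S_b is the length at the birth frame and S_d the length at the last
    observation before the daughters appear; τ spans birth to division
    frame; λ is the log-linear fit over all of the cell's observations.
    The septum ratio (requiring the tracked daughters, via ``forest``) is
    the closed-end daughter's share of the summed daughter birth lengths.
    Incomplete cycles get partial statistics (λ is still computed).
    """
    cal = calibration or Calibration()
    if len(cell.features) < 2:
        raise ValueError("record needs >= 2 observations")
    px, dt = cal.pixel_size, cal.frame_interval
    sb = cell.features[0].length * px
    times = np.array(cell.frames, dtype=float) * dt
    lam = fit_elongation_rate(times, cell.lengths * px)
    complete = cell.division_frame is not None
    sd = tau = delta = septum = None
    if complete:
        sd = cell.features[-1].length * px
        delta = sd - sb
        tau = (cell.division_frame - cell.birth_frame) * dt
        if forest is not None and cell.daughters is not None:
            d1, d2 = (forest[d] for d in cell.daughters)
            upper, lower = sorted((d1, d2), key=lambda c: c.features[0].centroid_y)
            s1 = upper.features[0].length
            s2 = lower.features[0].length
            septum = s1 / (s1 + s2)
    return CellCycleStats(sb=sb, sd=sd, delta=delta, tau=tau, lam=lam,
                          septum_ratio=septum, complete=complete)


def annotate_cycles(cells: list[CellRecord],
                    calibration: Calibration | None = None) -> dict[str, CellCycleStats]:
    """Cell-cycle statistics for every record with >= 2 observations."""
    forest = {c.id: c for c in cells}
    out = {}
    for cell in cells:
        if len(cell.features) >= 2:
            out[cell.id] = compute_cell_cycle(cell, calibration, forest)
    return out
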