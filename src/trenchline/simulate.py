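"""Synthetic mother-machine experiments with known ground truth.

The generator produces what a phase-contrast mother-machine movie looks
like at desk scale: a field of view with evenly spaced one-ended vertical
growth channels embedded in a dark device, each holding a single file of
rod-shaped cells.  Cells elongate exponentially and divide by the adder
principle — each cell divides once it has added a (noisy) target length
since birth — with daughters receiving complementary fractions of the
mother's length.  Cells pushed past the open channel end are flushed.

Every experiment carries its full ground truth: per-frame labeled masks,
the lineage forest with per-cell growth parameters, and the scripted
stage-drift trajectory, so each downstream pipeline stage has an oracle.

All biological quantities are in µm and minutes; the rendering geometry
converts to pixels via its ``pixel_size``.  The channel axis runs from
the closed end (y = 0) toward the open end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "SimParams",
    "FovGeometry",
    "SimCell",
    "GroundTruthExperiment",
    "simulate_lineages",
    "render_fov",
    "write_fixture",
]


@dataclass(frozen=True)
class SimParams:
    """Single-cell growth statistics of the simulated population.

    Defaults emulate *E. coli* in a minimal glycerol medium (doubling time
    about 60 min) imaged every 2 min: mean added length Δ ≈ 2.5 µm with
    CV 0.15, elongation rate λ = ln2/60 min⁻¹ with CV 0.08, and a nearly
    symmetric septum (mean 0.5, SD 0.03).  Δ, λ and the septum fraction
    are drawn independently per cell from normals truncated at ±3 SD
    (the septum additionally to (0.1, 0.9)).
    """

    mean_delta: float = 2.5  # µm, mean added length between birth and division
    cv_delta: float = 0.15
    mean_lambda: float = math.log(2) / 60.0  # 1/min, elongation rate
    cv_lambda: float = 0.08
    septum_mean: float = 0.5  # daughter fraction at the closed-end side
    septum_sd: float = 0.03
    cell_width: float = 1.0  # µm
    frame_interval: float = 2.0  # min between frames
    seed: int = 0

    def validate(self) -> None:
        if self.mean_delta <= 0 or self.cell_width <= 0 or self.frame_interval <= 0:
            raise ValueError("mean_delta, cell_width and frame_interval must be > 0")
        if self.mean_lambda < 0:
            raise ValueError("mean_lambda must be >= 0")
        if min(self.cv_delta, self.cv_lambda, self.septum_sd) < 0:
            raise ValueError("CVs must be >= 0")
        if not 0.0 < self.septum_mean < 1.0:
            raise ValueError("septum_mean must be in (0, 1)")
        lam_max = self.mean_lambda * (1.0 + 3.0 * self.cv_lambda)
        if math.exp(lam_max * self.frame_interval) >= 2.0:
            raise ValueError(
                "degenerate parameters: a cell can more than double per frame; "
                "reduce mean_lambda/cv_lambda or frame_interval"
            )


@dataclass(frozen=True)
class FovGeometry:
    """Rendering geometry and contrast model of the synthetic device.

    The channel interior is light, the PDMS device between channels dark,
    and the feeding trench below the open ends bright; cells are dark
    rounded rods.  Contrast between cell and channel interior is 100 grey
    levels against a noise SD of 20 (~5x), the package's definition of an
    'easy contrast' render; lower the contrast or raise ``noise_sd`` to
    stress-test segmentation.
    """

    n_channels: int = 5
    pixel_size: float = 0.065  # µm per px (6.5 µm camera pixel behind 100x optics)
    channel_length_um: float = 25.0
    channel_width_um: float = 1.4
    channel_sep_px: int = 45  # center-to-center spacing
    margin_x_px: int = 25
    closed_end_y_px: int = 18  # FOV row of the closed channel end
    trench_depth_px: int = 40
    cell_gap_um: float = 0.3  # single-file spacing between stacked cells
    closed_end_offset_um: float = 0.2  # gap between closed end and mother pole
    # 8-bit intensity model
    device_intensity: float = 55.0
    interior_intensity: float = 185.0
    trench_intensity: float = 200.0
    cell_intensity: float = 85.0
    fluor_background: float = 8.0
    fluor_cell_intensity: float = 120.0
    noise_sd: float = 20.0
    fluor_noise_sd: float = 3.0
    blur_sigma: float = 1.0
    drift_max_px: int = 4  # |dx|,|dy| bound of the random-walk stage drift
    with_fluorescence: bool = False

    @property
    def channel_length_px(self) -> float:
        return self.channel_length_um / self.pixel_size

    @property
    def channel_width_px(self) -> float:
        return self.channel_width_um / self.pixel_size

    @property
    def centers_x(self) -> np.ndarray:
        return self.margin_x_px + np.arange(self.n_channels) * self.channel_sep_px

    @property
    def shape(self) -> tuple[int, int]:
        h = self.closed_end_y_px + int(round(self.channel_length_px)) + self.trench_depth_px
        w = 2 * self.margin_x_px + (self.n_channels - 1) * self.channel_sep_px
        return h, w

    def channel_box(self, channel: int) -> tuple[int, int, int, int]:
        """Canonical crop box (y0, y1, x0, x1), half-open, FOV coordinates."""
        bw = int(round(1.4 * self.channel_width_px))
        cx = int(self.centers_x[channel])
        y0 = max(0, self.closed_end_y_px - 4)
        y1 = min(self.shape[0], self.closed_end_y_px + int(round(self.channel_length_px)) + 10)
        return y0, y1, cx - bw // 2, cx - bw // 2 + bw


@dataclass
class SimCell:
    """One simulated cell: lineage links, growth law, per-frame geometry."""

    id: int
    channel: int
    parent: int | None
    birth_frame: int
    lam: float  # 1/min, this cell's elongation rate
    delta_target: float  # µm, added length that triggers division
    septum_r: float  # fraction of division length given to the closed-end daughter
    birth_length: float  # µm
    frames: list[int] = field(default_factory=list)
    lengths: list[float] = field(default_factory=list)  # µm, per observed frame
    y_tops: list[float] = field(default_factory=list)  # µm from the closed end
    division_frame: int | None = None
    daughters: tuple[int, int] | None = None
    status: str = "growing"  # growing | divided | flushed | end

    def length_at(self, frame: int) -> float:
        return self.lengths[frame - self.frames[0]]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf) -> float:
    """Normal draw truncated at ±3 SD and clipped to (lo, hi) by rejection."""
    if sd == 0:
        return mean
    a, b = max(lo, mean - 3 * sd), min(hi, mean + 3 * sd)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if a <= x <= b:
            return x
    return min(max(mean, a), b)


@dataclass
class GroundTruthExperiment:
    """A complete simulated experiment with its ground truth attached."""

    params: SimParams
    geometry: FovGeometry
    n_frames: int
    cells: dict[int, SimCell]
    occupied_channels: tuple[int, ...]
    empty_channels: tuple[int, ...]
    drift: np.ndarray  # (n_frames, 2) int array of (dy, dx) scene offsets

    # -- lineage ground truth -------------------------------------------------

    def lineage_table(self) -> pd.DataFrame:
        """One row per cell with frame-quantized cell-cycle statistics.

        ``sb_um`` is the length at the birth frame; ``sd_um`` the length at
        the last frame the mother is observed intact (the frame before its
        daughters appear); ``tau_min`` the quantized generation time;
        ``septum_ratio`` the closed-end daughter's share of the summed
        daughter birth lengths.  ``lambda_per_min`` is the cell's true
        elongation rate.
        """
        g = self.geometry
        rows = []
        for cell in self.cells.values():
            complete = cell.division_frame is not None
            sb = cell.lengths[0]
            sd = cell.lengths[-1] if complete else np.nan
            tau = ((cell.division_frame - cell.birth_frame) * self.params.frame_interval
                   if complete else np.nan)
            septum = np.nan
            if (complete and cell.daughters is not None
                    and all(d in self.cells for d in cell.daughters)):
                d1 = self.cells[cell.daughters[0]]
                d2 = self.cells[cell.daughters[1]]
                septum = d1.birth_length / (d1.birth_length + d2.birth_length)
            box_y0 = g.channel_box(cell.channel)[0]
            birth_y = (g.closed_end_y_px - box_y0) + (
                (cell.y_tops[0] + sb / 2.0) / g.pixel_size
            )
            daughters_observed = bool(
                complete and cell.daughters is not None
                and all(d in self.cells for d in cell.daughters)
            )
            rows.append({
                "cell_id": cell.id,
                "channel": cell.channel,
                "parent_id": -1 if cell.parent is None else cell.parent,
                "birth_frame": cell.birth_frame,
                "division_frame": -1 if cell.division_frame is None else cell.division_frame,
                "status": cell.status,
                "daughters_observed": daughters_observed,
                "n_obs": len(cell.frames),
                "birth_y_px": birth_y,
                "sb_um": sb,
                "sd_um": sd,
                "delta_um": sd - sb if complete else np.nan,
                "tau_min": tau,
                "lambda_per_min": cell.lam,
                "septum_ratio": septum,
            })
        return pd.DataFrame(rows).sort_values("cell_id").reset_index(drop=True)

    def complete_cycles(self) -> pd.DataFrame:
        """The observable complete cycles: observed birth (a tracked parent),
        observed division, and both daughters observed at least once.

        A division whose lower daughter is flushed out of the channel the
        moment it is born is physically real but never imaged as two
        regions, so no tracker could recover it; such cycles are excluded,
        mirroring the mother-and-daughters-tracked filter applied to the
        tracked records.
        """
        t = self.lineage_table()
        return t[(t.division_frame >= 0) & (t.parent_id >= 0)
                 & t.daughters_observed].reset_index(drop=True)

    # -- mask ground truth ----------------------------------------------------

    def channel_masks(self, channel: int) -> np.ndarray:
        """(T, h, w) uint16 labeled masks in channel-local (drift-free) coords."""
        y0, y1, x0, x1 = self.geometry.channel_box(channel)
        shape = (y1 - y0, x1 - x0)
        stack = np.zeros((self.n_frames,) + shape, dtype=np.uint16)
        for cell in self.cells.values():
            if cell.channel != channel:
                continue
            for f, length, y_top in zip(cell.frames, cell.lengths, cell.y_tops):
                self._paint_cell_mask(stack[f], cell, length, y_top,
                                      oy=self.geometry.closed_end_y_px - y0,
                                      ox=self.geometry.centers_x[channel] - x0)
        return stack

    def fov_mask(self, frame: int) -> np.ndarray:
        """Full-FOV uint16 labeled mask for one frame, with drift applied.

        The labels overlay the rendered frame exactly, so cropping the mask
        with the same boxes and shifts used for the images yields
        pixel-registered per-channel ground truth.
        """
        g = self.geometry
        h, w = g.shape
        m = g.drift_max_px + 2
        canvas = np.zeros((h + 2 * m, w + 2 * m), dtype=np.uint16)
        dy, dx = self.drift[frame]
        for cell in self.cells.values():
            if frame not in range(cell.frames[0], cell.frames[-1] + 1):
                continue
            i = frame - cell.frames[0]
            self._paint_cell_mask(canvas, cell, cell.lengths[i], cell.y_tops[i],
                                  oy=m + dy + g.closed_end_y_px,
                                  ox=m + dx + g.centers_x[cell.channel])
        return canvas[m:m + h, m:m + w]

    def _paint_cell_mask(self, canvas, cell, length, y_top, oy, ox) -> None:
        g = self.geometry
        d = _capsule_distance(canvas.shape,
                              cx=float(ox),
                              y_top=oy + y_top / g.pixel_size,
                              y_bot=oy + (y_top + length) / g.pixel_size,
                              width=self.params.cell_width / g.pixel_size)
        if d is not None:
            win, dist = d
            canvas[win][dist <= self.params.cell_width / g.pixel_size / 2.0] = cell.id

    # -- rendering ------------------------------------------------------------

    def render_frame(self, frame: int, plane: str = "phase") -> np.ndarray:
        return render_fov(self, frame, plane)

    def render_stack(self, plane: str = "phase") -> np.ndarray:
        return np.stack([render_fov(self, t, plane) for t in range(self.n_frames)])


def _capsule_distance(shape, cx, y_top, y_bot, width):
    """Distance from pixel centers to a vertical capsule's axis segment.

    Returns ``(window, distances)`` restricted to a bounding window, or
    None if the capsule misses the canvas.  Pixel centers sit at integer
    indices; the capsule spans [y_top, y_bot] pole to pole.
    """
    r = width / 2.0
    a, b = y_top + r, y_bot - r  # axis segment endpoints
    if b < a:
        a = b = (y_top + y_bot) / 2.0
    r0 = max(0, int(math.floor(y_top - 1)))
    r1 = min(shape[0], int(math.ceil(y_bot + 2)))
    c0 = max(0, int(math.floor(cx - r - 1)))
    c1 = min(shape[1], int(math.ceil(cx + r + 2)))
    if r0 >= r1 or c0 >= c1:
        return None
    yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
    dy = np.where(yy < a, a - yy, np.where(yy > b, yy - b, 0.0))
    dist = np.hypot(xx - cx, dy)
    return (slice(r0, r1), slice(c0, c1)), dist


def simulate_lineages(p: SimParams, n_channels: int, n_frames: int,
                      geometry: FovGeometry | None = None,
                      empty_channels: tuple[int, ...] = ()) -> GroundTruthExperiment:
    """Simulate adder-regulated single-file growth in every occupied channel.

    Per cell, length grows as l(t) = l_b·exp(λ(t−t_b)); division fires at
    the first frame where l − l_b ≥ Δ, that frame being both the mother's
    division frame and the daughters' birth frame.  Daughters receive
    fractions r and 1−r of the mother's length (exact conservation), are
    restacked single-file from the closed end, and cells pushed past the
    open end are flushed.  The same seed reproduces the experiment
    bit-identically.
    """
    p.validate()
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if geometry is None:
        geometry = FovGeometry(n_channels=n_channels)
    if geometry.n_channels != n_channels:
        raise ValueError(
            f"geometry declares {geometry.n_channels} channels, requested {n_channels}"
        )
    if any(not 0 <= c < n_channels for c in empty_channels):
        raise ValueError("empty_channels out of range")

    rng = np.random.default_rng(np.random.SeedSequence([int(p.seed) % (2**31), 2310]))
    occupied = tuple(c for c in range(n_channels) if c not in empty_channels)
    cells: dict[int, SimCell] = {}
    next_id = 1
    dt = p.frame_interval

    def draw_cell(channel, parent, birth_frame, birth_length) -> SimCell:
        nonlocal next_id
        cell = SimCell(
            id=next_id, channel=channel, parent=parent, birth_frame=birth_frame,
            lam=_truncated_normal(rng, p.mean_lambda, p.cv_lambda * p.mean_lambda, lo=0.0),
            delta_target=_truncated_normal(rng, p.mean_delta, p.cv_delta * p.mean_delta,
                                           lo=1e-6),
            septum_r=_truncated_normal(rng, p.septum_mean, p.septum_sd, lo=0.1, hi=0.9),
            birth_length=birth_length,
        )
        cells[cell.id] = cell
        next_id += 1
        return cell

    for channel in occupied:
        sb0 = _truncated_normal(rng, p.mean_delta, p.cv_delta * p.mean_delta, lo=1e-6)
        stack = [draw_cell(channel, None, 0, sb0)]  # ordered closed end first
        for t in range(n_frames):
            # grow
            lengths = [c.birth_length * math.exp(c.lam * (t - c.birth_frame) * dt)
                       for c in stack]
            # divisions (resolved at frame resolution)
            new_stack, new_lengths = [], []
            for cell, length in zip(stack, lengths):
                if t > cell.birth_frame and length - cell.birth_length >= cell.delta_target:
                    r = cell.septum_r
                    d1 = draw_cell(channel, cell.id, t, r * length)
                    d2 = draw_cell(channel, cell.id, t, (1.0 - r) * length)
                    cell.division_frame = t
                    cell.daughters = (d1.id, d2.id)
                    cell.status = "divided"
                    new_stack += [d1, d2]
                    new_lengths += [d1.birth_length, d2.birth_length]
                else:
                    new_stack.append(cell)
                    new_lengths.append(length)
            stack, lengths = new_stack, new_lengths
            # restack single-file from the closed end
            y = geometry.closed_end_offset_um
            y_tops = []
            for length in lengths:
                y_tops.append(y)
                y += length + geometry.cell_gap_um
            # flush cells pushed past the open end
            while stack and y_tops[-1] + lengths[-1] > geometry.channel_length_um:
                gone = stack.pop()
                y_tops.pop()
                lengths.pop()
                gone.status = "flushed"
            # record observations
            for cell, length, y_top in zip(stack, lengths, y_tops):
                cell.frames.append(t)
                cell.lengths.append(length)
                cell.y_tops.append(y_top)
        for cell in stack:
            cell.status = "end"

    # drop cells flushed before ever being observed
    cells = {cid: c for cid, c in cells.items() if c.frames}

    # integer random-walk stage drift, clipped to ±drift_max_px
    drift = np.zeros((n_frames, 2), dtype=int)
    if geometry.drift_max_px > 0:
        steps = rng.integers(-1, 2, size=(n_frames - 1, 2))
        drift[1:] = np.clip(np.cumsum(steps, axis=0),
                            -geometry.drift_max_px, geometry.drift_max_px)

    return GroundTruthExperiment(
        params=p, geometry=geometry, n_frames=n_frames, cells=cells,
        occupied_channels=occupied, empty_channels=tuple(empty_channels), drift=drift,
    )


def _static_background(g: FovGeometry, plane: str) -> np.ndarray:
    """Padded static scene (device, channels, trench) without cells."""
    h, w = g.shape
    m = g.drift_max_px + 2
    if plane == "fluor":
        bg = np.full((h + 2 * m, w + 2 * m), g.fluor_background, dtype=float)
        return bg
    bg = np.full((h + 2 * m, w + 2 * m), g.device_intensity, dtype=float)
    ch_len = int(round(g.channel_length_px))
    trench_y = m + g.closed_end_y_px + ch_len
    bg[trench_y:, :] = g.trench_intensity
    half = g.channel_width_px / 2.0
    for cx in g.centers_x:
        x0 = int(round(m + cx - half))
        x1 = int(round(m + cx + half))
        bg[m + g.closed_end_y_px:trench_y, x0:x1] = g.interior_intensity
    return bg


def render_fov(gt: GroundTruthExperiment, frame: int, plane: str = "phase",
               noise: bool = True, blur: bool = True) -> np.ndarray:
    """Render one FOV frame as an 8-bit phase-contrast-like micrograph.

    Cells are painted as anti-aliased dark capsules on the light channel
    interior (or bright rods on the fluorescence plane), the scene is
    shifted by the frame's scripted drift, blurred and corrupted with
    additive Gaussian noise.  ``noise=False``/``blur=False`` give the
    noiseless/unblurred renders used by oracle tests.
    """
    if not 0 <= frame < gt.n_frames:
        raise ValueError(f"frame {frame} outside experiment (n_frames={gt.n_frames})")
    if plane not in ("phase", "fluor"):
        raise ValueError(f"unknown plane {plane!r}")
    g = gt.geometry
    h, w = g.shape
    m = g.drift_max_px + 2
    cache = gt.__dict__.setdefault("_bg_cache", {})
    if plane not in cache:
        cache[plane] = _static_background(g, plane)
    canvas = cache[plane].copy()
    dy, dx = gt.drift[frame]
    cell_value = g.cell_intensity if plane == "phase" else g.fluor_cell_intensity
    w_px = gt.params.cell_width / g.pixel_size
    for cell in gt.cells.values():
        if not cell.frames or not cell.frames[0] <= frame <= cell.frames[-1]:
            continue
        i = frame - cell.frames[0]
        res = _capsule_distance(
            canvas.shape,
            cx=float(m + g.centers_x[cell.channel]),
            y_top=m + g.closed_end_y_px + cell.y_tops[i] / g.pixel_size,
            y_bot=m + g.closed_end_y_px + (cell.y_tops[i] + cell.lengths[i]) / g.pixel_size,
            width=w_px,
        )
        if res is None:
            continue
        win, dist = res
        alpha = np.clip(w_px / 2.0 + 0.5 - dist, 0.0, 1.0)
        canvas[win] = (1.0 - alpha) * canvas[win] + alpha * cell_value
    img = canvas[m - dy:m - dy + h, m - dx:m - dx + w]
    if blur and g.blur_sigma > 0:
        img = gaussian_filter(img, g.blur_sigma)
    if noise:
        sd = g.noise_sd if plane == "phase" else g.fluor_noise_sd
        plane_idx = 0 if plane == "phase" else 1
        rng = np.random.default_rng(
            np.random.SeedSequence([int(gt.params.seed) % (2**31), 911, frame, plane_idx])
        )
        img = img + rng.normal(0.0, sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def write_fixture(gt: GroundTruthExperiment, directory: str | Path,
                  prefix: str = "sim", fov: int = 0) -> dict[str, list[Path]]:
    """Write the experiment to disk in the layout the pipeline consumes.

    Raw frames go to ``raw/`` as single-page TIFFs named
    ``{prefix}_t{time:04d}_xy{fov:02d}_c{plane}.tif`` (plane 1 = phase,
    plane 2 = fluorescence when enabled); ground truth goes to ``gt/`` as
    per-frame labeled-mask TIFFs plus the lineage table and drift
    trajectory as CSV.
    """
    directory = Path(directory)
    raw_dir = directory / "raw"
    gt_dir = directory / "gt"
    raw_dir.mkdir(parents=True, exist_ok=True)
    gt_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {"raw": [], "masks": []}
    planes = ["phase"] + (["fluor"] if gt.geometry.with_fluorescence else [])
    for t in range(gt.n_frames):
        for p_idx, plane in enumerate(planes, start=1):
            path = raw_dir / f"{prefix}_t{t:04d}_xy{fov:02d}_c{p_idx}.tif"
            tifffile.imwrite(path, render_fov(gt, t, plane))
            written["raw"].append(path)
        mpath = gt_dir / f"{prefix}_mask_t{t:04d}_xy{fov:02d}.tif"
        tifffile.imwrite(mpath, gt.fov_mask(t))
        written["masks"].append(mpath)
    gt.lineage_table().to_csv(gt_dir / "lineage.csv", index=False)
    pd.DataFrame(gt.drift, columns=["dy", "dx"]).to_csv(gt_dir / "drift.csv", index=False)
    meta = {
        "n_frames": gt.n_frames,
        "n_channels": gt.geometry.n_channels,
        "empty_channels": list(gt.empty_channels),
        "pixel_size": gt.geometry.pixel_size,
        "frame_interval": gt.params.frame_interval,
    }
    (gt_dir / "experiment.json").write_text(json.dumps(meta, indent=2))
    return written


def default_experiment(seed: int = 0, n_channels: int = 5, n_frames: int = 300,
                       empty_channels: tuple[int, ...] = (2,),
                       **geometry_overrides) -> GroundTruthExperiment:
    """The package's standard desk-scale fixture: 5 channels (one empty,
    reserved as the background-subtraction template) by 300 frames at easy
    contrast."""
    geom = FovGeometry(n_channels=n_channels, **geometry_overrides)
    return simulate_lineages(SimParams(seed=seed), n_channels, n_frames,
                             geometry=geom, empty_channels=empty_channels)
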