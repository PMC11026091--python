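# Methods

This note documents the models, algorithms and numerical choices behind
`trenchline`, in the order the pipeline runs them, followed by the
synthetic-data model that serves as the package's verification oracle.

## Coordinate and unit conventions

Images are row-major and 0-based; crops are half-open intervals. Within a
growth channel the y axis runs from the closed end (y = 0) toward the open
end. All tracking operates in pixels and frames; physical units enter only
through the calibration (`pixel_size` in µm/px, `frame_interval` in min),
which defaults to 1 so an uncalibrated run reports dimensionless
statistics. `effective_pixel_size(camera_pixel, magnification)` gives the
µm/px of an optical train (6.5 µm sensor behind a 100× objective → 0.065
µm/px).

## Channel compilation

**Detection.** Growth channels are a periodic array of light interiors
between dark device walls. The detector convolves the column profile of
the temporal mean image with a zero-mean Mexican-hat kernel whose scale is
the expected channel width — a matched filter for a bright bar of that
width — and takes peaks at least 0.6 channel separations apart and above
0.3× the strongest response. The relative cut is deliberately generous:
empty channels respond roughly twice as strongly as channels whose
interior is smeared by a decade of resident cells. The y-extent spans the
rows with strong horizontal contrast (the wall/interior split), padded 4 px
above the closed end and 10 px into the trench. All boxes share one width
(1.4× the channel width, leaving margins so cells never touch the crop
border) and one y-extent, so stacks are co-registered.

**Drift.** Stage drift is estimated per frame against frame 0. The
mother-machine scene is projection-separable — vertical wall stripes
constrain x, the closed-end and trench edges constrain y — so each axis is
estimated independently by exhaustive integer search (±15 px) maximizing
the normalized correlation of the whole-FOV intensity projection along
that axis. A 2D cross-correlation is *worse* here: the scene's
autocorrelation is nearly flat along y (stripes), so noise pulls the 2D
peak off by several pixels, while the 1D projections average the noise
away. On noiseless renders the scripted drift is recovered exactly; with
noise, to ±1 px. Sub-pixel registration is out of scope: crops are
integer-aligned, and the background-subtraction alignment absorbs the
residual.

**Full/empty classification.** An empty channel is a static scene; a full
one is continuously reshaped by growth and division. The score is the mean
Pearson correlation between y-profiles (row means of the crop, smoothed
along y with σ = 2 px to suppress shot noise) of frame pairs a lag of
~T/10 apart. Adjacent frames are *not* compared: at 2-minute imaging a
cell moves ~1 px per frame, so adjacent-frame profiles are nearly
identical for full channels too, and the score would not separate the
classes. With the T/10 lag, empty channels score ≈ 0.985 and full ones
0.7–0.8 on the standard fixture; the decision threshold defaults to 0.97.
Zero-variance profiles (a truly constant scene) contribute 1.0 by
convention. The classification is written to a CSV the later stages
re-read, so a user can re-designate channels in a text editor.

## Background subtraction

Phase-contrast cells are dark inside a dark-walled device, so direct
thresholding picks up the walls. Each full frame gets the empty-channel
template aligned to it by exhaustive integer search over ±`align_pad`
(default 10 px) maximizing normalized cross-correlation of the overlap —
cheap at crop scale and exactly reproducible — and the output is
`clip(empty_aligned − full, 0)` cast back to the input dtype. This one
operation both removes the device image and inverts contrast: cells become
the only bright objects on a near-zero background, which is the input
contract of the segmenter. The template is the time-mean of the FOV's
empty channels (averaging suppresses noise relative to a single empty
frame). The absolute alignment score falls with cell load, because cells
decorrelate the overlap even when the walls are perfectly registered;
scores below 0.3 are logged as genuine alignment failures.

## Segmentation

Per frame, in order: (1) binarize at `otsu_scale ×` the Otsu threshold —
the histogram cut maximizing between-class variance, computed over integer
intensities so it is exactly the exhaustive scan; (2) morphological
opening with a disk of radius `first_opening` (2 px) to sever thin links
and remove salt noise; (3) fill interior holes — single-pixel shot-noise
holes would otherwise let the distance transform carve spurious cuts
through cell bodies, and the transform's purpose is severing links
*between* regions; (4) Euclidean distance transform, cut at
`distance_threshold` (2 px), which erodes each region toward its ridge
and separates touching cells; (5) opening with radius `second_opening`
(1 px); (6) remove regions under `min_object_size` (25 px²) or touching
the frame border; (7) label what survives, ordered from the closed end.

(8) The labels then seed a random walker on the subtracted frame
(β = 130, exact "bf" solver, intensities normalized to [0, 1]), growing
the eroded seeds back to the intensity boundaries. Background is seeded
from pixels farther than 2×`distance_threshold` from any seed *and* below
the scaled threshold; the intensity condition keeps blurred cell tails
from being seeded as background, and the proximity condition gives every
cell a nearby background competitor so the walker's boundary is pinned by
the gradient rather than by seed geometry. A constant (blank) frame
segments to zero regions; raising `otsu_scale` strictly tightens the
binarization, so segmented area is non-increasing in it — the mechanism by
which a thresholding choice propagates into every downstream size
statistic (see the evaluation sweep below).

Determinism: the walker is a linear solve with fixed configuration;
identical input and parameters give identical masks.

## Tracking

Regions and active cells are both ordered from the closed end and walked
in parallel, which enforces order preservation (confined cells cannot pass
each other) by construction. For each cell, against its last observation:

- one region with length and area ratios inside `growth_length_ratio` /
  `growth_area_ratio` (defaults (0.8, 1.3)) → growth link;
- two adjacent regions whose combined size satisfies the same ratios and
  whose individual shares of the combined length are each in (0.25, 0.75)
  → division;
- when both hypotheses pass, the one whose total length ratio is closest
  to the geometric mean of the growth bounds (≈1.02) wins;
- no admissible region → candidate lost, retried for `lost_cell_time`
  frames (3); a cell re-found within the window has the gap linearly
  interpolated and flagged; otherwise it is finalized lost.

Unmatched regions become new cells only within `new_cell_y_cutoff`
(150 px) of the closed end; deeper ones must be daughters or debris and
are discarded. At frame 0 every region starts a cell (the channel's
initial occupants). Division bookkeeping: the frame where two regions
first appear is the mother's division frame and the daughters' birth
frame; the mother's last observation is the frame before.

**Cell length** defaults to the bounding-box extent along the channel
axis. Channel-confined rods are axis-aligned, and the ellipse-equivalent
major axis (`length_method="major_axis"`, available for tilted cells)
systematically overestimates a rod's pole-to-pole length by ~15%, which
would bias every size statistic. Width is the across-axis extent, and
volume uses the sphero-cylinder model `π(w/2)²(l−w) + (4/3)π(w/2)³`.

**Cell-cycle statistics.** `S_b` is the length at the birth frame; `S_d`
the length at the last frame the mother is observed intact; `Δ = S_d −
S_b`; `τ = (division − birth frame) × frame_interval`; `λ` is the
least-squares slope of ln(length) against time over all of the cell's
observations. The septum ratio is the closed-end daughter's share of the
summed daughter birth lengths — not daughter/mother-`S_d`: with division
resolved on the frame grid, the mother's last length predates the
daughters by one frame, so a daughter/mother ratio would carry a
systematic factor e^{λΔt} (~1.02 at the defaults); the share form has
expectation exactly the septum position on both the tracked and the
ground-truth side.

Population statistics are computed on *complete cycles*: cells with a
tracked parent, an observed division, and both daughters tracked. This
filter removes truncated first/last generations and segmentation-edge
artifacts. Distribution summaries use the n−1 sample SD; binned
correlations use equal-count (quantile) bins with a minimum of 20 points
per bin and report per-bin means with standard errors; slopes through
binned means are inverse-SEM-weighted least squares.

## Fluorescence and foci

Integrated fluorescence sums the registered fluorescence plane over the
cell's mask pixels; per-area and per-volume divide by the region's area
and capsule volume. Focus detection convolves the frame with a negated
Laplacian of Gaussian at the expected spot scale (default σ = 1.5 px) and
keeps local maxima above `threshold_sd` (default 5) times the response SD;
each focus belongs to the cell whose mask contains its peak. The spot
scale and threshold are exposed as parameters; detected focus count is
monotone non-increasing in the threshold.

## Evaluation

Cell-level matching pairs predicted and ground-truth regions one-to-one:
candidate pairs at IoU ≥ 0.6 (inclusive; a strictness flag switches to >)
are accepted greedily in descending IoU, each region used once. TP is the
number of matches, FP the unmatched predictions, FN the unmatched truths,
and `JI = TP/(TP+FP+FN)`. Greedy matching is not guaranteed optimal in
general, but on frames with ≤ 6 regions it agrees exactly with exhaustive
assignment enumeration across hundreds of randomized toys (a standing
test); mother-machine frames are far below any regime where they could
diverge.

The threshold-bias sweep re-runs segmentation *and* tracking across a
range of `otsu_scale` values and tabulates mean cell area and mean
birth/division length per scale. On the standard fixture a 0.8 → 1.2
sweep shifts mean cell area monotonically by ~10% — a systematic,
user-threshold-driven size bias of the same character as the documented
discrepancies between classical and learned segmentation methods. The
monotonicity is asserted by tests; the magnitude is reported, not
asserted, since it depends on contrast and cell geometry.

Lineage recovery is quantified against the simulator's truth: a
ground-truth complete cycle counts as recovered if a tracked cell in the
same channel is born within 1 frame and 10 px of it, divides within 1
frame of it, and has two tracked daughters. Cycles whose lower daughter is
flushed out of the channel in its birth frame are excluded from the
denominator — such a division is never imaged as two regions, so no
tracker could see it; this mirrors the mothers-and-daughters filter
applied to the tracked records.

## The synthetic experiment model

The generator is the package's ground-truth oracle, and its defaults are
the conditions every end-to-end figure in this repository refers to.

**Growth and division.** Each cell carries its own elongation rate λ and
division trigger Δ, drawn at birth from normals truncated at ±3 SD
(defaults: Δ = 2.5 µm CV 0.15; λ = ln2/60 min⁻¹ CV 0.08 — *E. coli* in
minimal glycerol medium, ~60 min doubling). Length grows exponentially;
the first frame at which l − l_b ≥ Δ is the division frame (division is
resolved at frame resolution, as any frame-based tracker would see it).
The daughters receive fractions r and 1−r of the mother's length — exact
conservation — with r truncated-normal around 0.5 (SD 0.03, clipped to
(0.1, 0.9)). Cells stack single file from the closed end with a 0.3 µm
inter-cell gap (the optical constriction between siblings); whenever the
stack outgrows the 25 µm channel the deepest cells are flushed, instantly
and entirely — partially visible cells at the open end are not modeled.
The lineage table records frame-quantized S_b, S_d, Δ, τ (matching the
tracker's definitions exactly), the true per-cell λ, and the septum share.

**Rendering.** The field of view mimics phase contrast at the reference
optics (0.065 µm/px, 2-min frames): dark device (55), light channel
interiors (185), bright trench (200), cells as anti-aliased dark capsules
(85) of width 1 µm; channels 1.4 µm wide, 45 px apart (so a fixture
config sets `compile.channel_width: 21.5`). The scene is shifted by a
±4 px integer random-walk drift, blurred with a Gaussian of σ = 1 px, and
corrupted with additive Gaussian noise of SD 20 — a cell/background
separation of 5 noise SDs, the package's "easy contrast" condition;
`FovGeometry` exposes every intensity and the noise level for stress
tests. Per-frame noise streams are seeded from (experiment seed, frame,
plane), so renders are reproducible regardless of call order. An optional
fluorescence plane paints cells at uniform intensity 120 over background 8
with σ = 3 noise.

**What the generator does not emulate** — and hence what passing tests do
not certify about real data: phase-contrast halos and diffraction rings,
uneven illumination, focus drift, rotation of the device, cell width
variation and filamentation, lysis, partial visibility at the open end,
and any optical PSF beyond a Gaussian blur. The fixture is a verification
harness for the pipeline's logic and numerics, not a claim of photorealism.

**Fixture sizes.** The standard end-to-end fixture is 5 channels (one
left empty as the subtraction template) × 300 frames (10 simulated hours),
yielding ~6000 cell-frame instances and ~130 complete cycles; it runs in
about 80 s on one CPU. The tracking-invariant suite uses ground-truth
masks directly (no rendering) at 16 channels × 600 frames, ~1300 complete
cycles. The threshold sweep runs on a 120-frame prefix of one channel at
five scales. These sizes put 3-SE recovery tests comfortably in the
regime where real biases would be visible while keeping the full suite
around two minutes.

## Known limitations

- Drift handling is integer-pixel and translation-only; rotated devices
  must be pre-rotated.
- The empty-channel template is per-FOV and time-averaged; illumination
  drift *within* an experiment is not corrected.
- The tracker's sequential matcher assumes segmentation rarely drops a
  cell in the middle of the stack; a dropped mid-stack cell costs its
  whole sub-lineage for the lost window rather than being bridged by
  global optimization.
- The greedy IoU matcher is exact only in the tested small-frame regime
  (which covers mother-machine channels); it is not a general-purpose
  optimal assignment.
- Focus *tracking* across frames is nearest-neighbor per cell and
  deliberately simple; focus detection parameters (spot scale, threshold)
  must be tuned per imaging configuration.
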