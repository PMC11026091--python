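# trenchline

Mother-machine time-lapse analysis in Python: from raw multi-FOV TIFF
series to per-cell lineage records and cell-size homeostasis statistics.

The mother machine is a microfluidic device in which bacteria grow in
single file inside one-ended *growth channels* that open into a feeding
trench; the cell at the closed end (the "mother") is imaged for hundreds
of generations while its progeny are flushed away. Extracting physiology
from such movies takes a specialized pipeline, which this package
implements end to end:

1. **compile** — detect the periodic array of growth channels on the
   temporal mean image (Mexican-hat matched filter on the column profile),
   estimate integer-pixel stage drift against frame 0, crop one
   drift-corrected image stack per channel, and classify channels as
   full/empty from the time correlation of their y-intensity profiles;
2. **subtract** — align an empty-channel template to each full channel
   (exhaustive integer search maximizing normalized cross-correlation
   within ±`align_pad`) and form `clip(empty − full, 0)`, removing the
   device image and inverting contrast so cells are the only bright
   objects;
3. **segment** — binarize at `otsu_scale ×` the Otsu threshold, clean with
   a morphological opening and hole filling, cut the Euclidean distance
   transform at `distance_threshold` to sever touching cells, open again,
   drop small or border-touching regions, and grow the surviving seed
   labels back to the intensity boundaries with a random walker;
4. **track** — link regions through time with a decision tree built on
   a-priori knowledge of the device: cells grow by a bounded ratio per
   frame (`growth_length_ratio`, `growth_area_ratio`), divide into two
   similarly sized daughters, and cannot pass each other; vanished cells
   are retried for `lost_cell_time` frames;
5. **stats** — per cell-cycle: birth length `S_b`, division length `S_d`,
   added length `Δ = S_d − S_b`, generation time `τ`, elongation rate `λ`
   (log-linear fit of length vs time), septum position; population
   summaries (mean/SD/CV) and equal-count binned correlations; integrated
   per-cell fluorescence and Laplacian-of-Gaussian focus detection;
6. **evaluate** — cell-level segmentation quality by one-to-one IoU
   matching at a threshold (default 0.6): true/false positives, false
   negatives, and the Jaccard index `JI = TP/(TP+FP+FN)`; plus an
   Otsu-scale sweep that exposes how a thresholding choice systematically
   shifts every extracted size statistic.

Because real annotated movies are scarce, the package ships a
**synthetic-experiment generator** (`trenchline.simulate`) that renders
phase-contrast-like movies of adder-regulated cells — each cell grows
exponentially, `l(t) = l_b·e^{λt}`, and divides on adding a noisy target
length Δ — together with exact ground truth (labeled masks, the lineage
forest, the scripted drift). Every pipeline stage is tested against this
oracle.

## Worked example

```python
import numpy as np
from trenchline import (load_params, detect_channels, estimate_drift,
                        crop_channel_stacks, classify_channels,
                        make_empty_template, subtract_stack, segment_stack,
                        build_lineages, physiology_table)
from trenchline.stats import summary_table
from trenchline.simulate import default_experiment

gt = default_experiment(seed=1, n_frames=300)       # 5 channels, one empty
params = load_params({"compile.channel_width": 21.5,
                      "calibration.pixel_size": 0.065,
                      "calibration.frame_interval": 2.0})

phase = gt.render_stack()
boxes = detect_channels(phase.mean(axis=0), params)
shifts = estimate_drift(phase)
stacks = crop_channel_stacks(phase, boxes, shifts)
empties = [ch for ch, st in stacks.items()
           if classify_channels(st, params).label == "empty"]
template = make_empty_template(np.concatenate([stacks[e] for e in empties]))

cells = []
for ch, stack in stacks.items():
    if ch in empties:
        continue
    sub = subtract_stack(stack, template, params)
    masks = segment_stack(sub.pixels, params)
    cells += build_lineages(masks, params, channel=ch)

table = physiology_table(cells, params.calibration)
print(summary_table(table).to_string(index=False))
```

prints (complete cycles only, i.e. cells whose mothers and daughters were
also tracked):

```
     parameter   n      mean       sd       cv
         sb_um 128  2.548711 0.315458 0.123772
         sd_um 128  4.958789 0.482512 0.097304
      delta_um 128  2.410078 0.350616 0.145479
       tau_min 128 60.640625 9.194088 0.151616
lambda_per_min 128  0.011481 0.000941 0.081918
  septum_ratio 128  0.498279 0.032217 0.064657
```

Birth length averages 2.55 µm with CV 0.12, generation time 60.6 min —
the simulated population's steady state — and the CV hierarchy
(septum < λ < S_b < Δ ≈ τ) matches what is seen in rod-shaped bacteria.
The recovered means agree with the generator's ground truth to well
within sampling error, and the segmentation matches the true masks with
`JI = 1.00` at IoU ≥ 0.6 on this fixture.

The same pipeline is available from the shell over an experiment
directory:

```bash
trenchline simulate --dir exp --seed 1 --channels 5 --frames 300
trenchline compile  --dir exp --config config.yaml
trenchline subtract --dir exp --config config.yaml
trenchline segment  --dir exp --config config.yaml
trenchline track    --dir exp --config config.yaml
trenchline stats    --dir exp --config config.yaml
trenchline evaluate --dir exp --config config.yaml   # vs simulated truth
```

Configuration is a flat YAML file with dotted keys (`segment.otsu_scale:
1.2`); unspecified keys take the documented defaults, and the effective
parameter set is logged to `exp/params.yaml` for provenance.

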