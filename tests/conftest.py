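"""Shared fixtures: parameter sets and the standard synthetic experiment.

The expensive end-to-end pipeline run (5 channels x 300 frames through
compile -> subtract -> segment -> track) is session-scoped and lazily
built, so it is paid for once and only when a test asks for it.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from trenchline import (
    build_lineages,
    classify_channels,
    crop_channel_stacks,
    detect_channels,
    estimate_drift,
    evaluate_stacks,
    lineage_agreement,
    load_params,
    make_empty_template,
    physiology_table,
    segment_stack,
    subtract_stack,
)
from trenchline.simulate import default_experiment

# geometry-dependent overrides for the synthetic device (1.4 µm channels at
# 0.065 µm/px), plus the physical calibration of the simulated microscope
FIXTURE_CONFIG = {
    "compile.channel_width": 21.5,
    "calibration.pixel_size": 0.065,
    "calibration.frame_interval": 2.0,
}


@pytest.fixture()
def params():
    """The default parameter set."""
    return load_params(None)


@pytest.fixture(scope="session")
def fixture_params():
    """Defaults adapted to the synthetic device geometry and calibration."""
    return load_params(dict(FIXTURE_CONFIG))


@pytest.fixture(scope="session")
def small_gt():
    """A small simulated experiment: 3 channels (one empty) x 100 frames."""
    return default_experiment(seed=7, n_channels=3, n_frames=100, empty_channels=(1,))


@pytest.fixture(scope="session")
def pipeline_run(fixture_params):
    """Full pipeline on the standard fixture (5 channels, one empty, 300
    frames, easy contrast), with ground truth cropped identically."""
    params = fixture_params
    gt = default_experiment(seed=1, n_channels=5, n_frames=300, empty_channels=(2,))
    phase = gt.render_stack()
    boxes = detect_channels(phase.mean(axis=0), params)
    assert len(boxes) == gt.geometry.n_channels
    shifts = estimate_drift(phase)
    stacks = crop_channel_stacks(phase, boxes, shifts)
    labels = {ch: classify_channels(st, params) for ch, st in stacks.items()}
    empties = [ch for ch, c in labels.items() if c.label == "empty"]
    template = make_empty_template(
        np.concatenate([stacks[ch] for ch in empties]))
    gt_fov = np.stack([gt.fov_mask(t) for t in range(gt.n_frames)])
    subs, masks, gt_crops, cells = {}, {}, {}, []
    totals = {"tp": 0, "fp": 0, "fn": 0}
    for ch in stacks:
        if ch in empties:
            continue
        subs[ch] = subtract_stack(stacks[ch], template, params)
        masks[ch] = segment_stack(subs[ch].pixels, params)
        gt_crops[ch] = crop_channel_stacks(gt_fov, [b for b in boxes if b.channel == ch],
                                           shifts)[ch]
        rep = evaluate_stacks(masks[ch], gt_crops[ch])
        totals["tp"] += rep.tp
        totals["fp"] += rep.fp
        totals["fn"] += rep.fn
        cells += build_lineages(masks[ch], params, channel=ch)
    table = physiology_table(cells, params.calibration)
    return SimpleNamespace(
        gt=gt, params=params, boxes=boxes, shifts=shifts, labels=labels,
        empties=empties, subs=subs, masks=masks, gt_crops=gt_crops,
        cells=cells, table=table, totals=totals,
        ji=totals["tp"] / max(1, sum(totals.values())),
        agreement=lineage_agreement(cells, gt.lineage_table(),
                                    gt.geometry.pixel_size),
    )
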