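"""Population physiology: filtering, summaries, binned correlations,
fluorescence quantification and focus detection."""

import math

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from trenchline import (
    binned_means,
    binned_slope,
    build_lineages,
    detect_foci,
    filter_complete,
    measure_fluorescence,
    summarize_distributions,
)
from trenchline.config import load_params
from trenchline.simulate import FovGeometry, SimParams, simulate_lineages
from trenchline.track import CellRecord, RegionFeature


@pytest.fixture(scope="module")
def tracked_forest():
    """Tracking on ground-truth masks of a mid-sized simulation."""
    gt = simulate_lineages(SimParams(seed=31), 4, 300,
                           geometry=FovGeometry(n_channels=4, drift_max_px=0))
    params = load_params({"compile.channel_width": 21.5,
                          "calibration.pixel_size": 0.065,
                          "calibration.frame_interval": 2.0})
    cells = []
    for ch in range(4):
        cells += build_lineages(gt.channel_masks(ch), params, channel=ch)
    return gt, cells


class TestFilterComplete:
    def test_keeps_only_cells_with_tracked_relatives(self, tracked_forest):
        gt, cells = tracked_forest
        kept = filter_complete(cells)
        ids = {c.id for c in cells}
        for c in kept:
            assert c.parent in ids
            assert c.division_frame is not None
            assert all(d in ids for d in c.daughters)
        # first-generation cells (no parent) are excluded
        assert all(c not in kept for c in cells if c.parent is None)

    def test_matches_brute_force_predicate_on_the_lineage_table(self, tracked_forest):
        """The kept set equals a brute-force scan of the ground-truth lineage
        for the same predicate (birth, division and both daughters observed)."""
        gt, cells = tracked_forest
        kept = {(c.channel, c.birth_frame, c.division_frame)
                for c in filter_complete(cells)}
        table = gt.lineage_table()
        oracle = set()
        for row in table.itertuples():
            if row.parent_id >= 0 and row.division_frame >= 0 and row.daughters_observed:
                oracle.add((row.channel, row.birth_frame, row.division_frame))
        assert kept == oracle


class TestSummaries:
    def test_constant_values_have_zero_cv(self):
        s = summarize_distributions(np.full(10, 3.5))
        assert (s.mean, s.sd, s.cv) == (3.5, 0.0, 0.0)

    def test_lognormal_cv_matches_closed_form(self):
        """CV of lognormal(µ, σ) is sqrt(e^{σ²}−1), independent of µ."""
        rng = np.random.default_rng(19)
        sigma = 0.2
        x = rng.lognormal(mean=1.0, sigma=sigma, size=20000)
        s = summarize_distributions(x)
        expected = math.sqrt(math.exp(sigma**2) - 1)
        se = expected / math.sqrt(2 * (len(x) - 1))  # delta-method SE of the CV
        assert abs(s.cv - expected) < 4 * max(se, 0.002)

    def test_sample_sd_uses_n_minus_one(self):
        s = summarize_distributions(np.array([1.0, 3.0]))
        assert s.sd == pytest.approx(math.sqrt(2.0))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_distributions(np.array([1.0]))

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 500)
        a = summarize_distributions(x)
        b = summarize_distributions(rng.permutation(x))
        assert (a.mean, a.sd, a.cv) == (b.mean, b.sd, b.cv)


class TestBinnedMeans:
    def test_identity_line(self):
        x = np.linspace(0, 10, 400)
        bc = binned_means(x, x, n_bins=5)
        assert np.allclose(bc.means, bc.centers)

    def test_linear_slope_recovered(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 4000)
        y = 2 * x + rng.normal(0, 1.0, x.size)
        slope, se = binned_slope(binned_means(x, y, n_bins=8))
        assert abs(slope - 2.0) < 3 * se

    def test_adder_correlations_on_simulated_truth(self):
        """Added length is uncorrelated with birth length (slope ~0) while
        division length regresses on birth length with slope ~1 — the adder's
        passive size convergence."""
        gt = simulate_lineages(SimParams(seed=37), 16, 600,
                               geometry=FovGeometry(n_channels=16, drift_max_px=0))
        cc = gt.complete_cycles()
        assert len(cc) >= 1000
        s0, e0 = binned_slope(binned_means(cc.sb_um, cc.delta_um, n_bins=8))
        assert abs(s0) < 3 * e0
        s1, e1 = binned_slope(binned_means(cc.sb_um, cc.sd_um, n_bins=8))
        assert abs(s1 - 1.0) < 3 * e1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            binned_means(np.ones(50), np.ones(50))
        with pytest.raises(ValueError):
            binned_means(np.arange(10.0), np.arange(9.0))

    def test_thin_bins_dropped(self):
        x = np.concatenate([np.zeros(30) + np.arange(30) * 1e-3, [5.0] * 3])
        y = x.copy()
        bc = binned_means(x, y, n_bins=3, min_per_bin=5)
        assert (bc.counts >= 5).all()


class TestFluorescence:
    def make_cell(self, label, y0, y1, x0, x1, frame=0):
        cell = CellRecord(id=f"c{label}", fov=0, channel=0, birth_frame=frame, rank=0)
        length, width = float(y1 - y0), float(x1 - x0)
        cell.features.append(RegionFeature(
            frame=frame, label=label, centroid_y=(y0 + y1) / 2,
            centroid_x=(x0 + x1) / 2, length=length, width=width,
            area=length * width,
            volume=RegionFeature.capsule_volume(length, width)))
        return cell

    def test_uniform_field_integrates_to_value_times_area(self):
        mask = np.zeros((1, 40, 20), dtype=np.int32)
        mask[0, 5:25, 4:14] = 1
        fluor = np.full((1, 40, 20), 7.0)
        cell = self.make_cell(1, 5, 25, 4, 14)
        df = measure_fluorescence([cell], mask, fluor)
        row = df.iloc[0]
        assert row.integrated == pytest.approx(7.0 * 200)
        assert row.per_area == pytest.approx(7.0)
        assert row.per_volume == pytest.approx(7.0 * 200 / cell.features[0].volume)

    def test_zero_plane_measures_zero(self):
        mask = np.zeros((1, 40, 20), dtype=np.int32)
        mask[0, 5:25, 4:14] = 1
        df = measure_fluorescence([self.make_cell(1, 5, 25, 4, 14)], mask,
                                  np.zeros((1, 40, 20)))
        assert (df[["integrated", "per_area", "per_volume"]] == 0).all().all()

    def test_additive_under_mask_partition(self):
        """Splitting a cell's mask in two and summing equals the whole."""
        rng = np.random.default_rng(5)
        fluor = rng.uniform(0, 100, size=(1, 40, 20))
        whole = np.zeros((1, 40, 20), dtype=np.int32)
        whole[0, 5:25, 4:14] = 1
        split = whole.copy()
        split[0, 15:25, 4:14] = 2
        a = measure_fluorescence([self.make_cell(1, 5, 25, 4, 14)], whole, fluor)
        top = self.make_cell(1, 5, 15, 4, 14)
        bot = self.make_cell(2, 15, 25, 4, 14)
        b = measure_fluorescence([top, bot], split, fluor)
        assert b.integrated.sum() == pytest.approx(a.integrated.iloc[0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            measure_fluorescence([], np.zeros((1, 4, 4)), np.zeros((1, 5, 4)))

    def test_fixture_photometry_within_blur_tolerance(self):
        """Painted per-cell fluorescence is recovered by mask integration to
        within the tolerance set by edge blur (flux leaks across the one-pixel
        blurred boundary)."""
        from trenchline.simulate import render_fov

        geom = FovGeometry(n_channels=1, drift_max_px=0, with_fluorescence=True,
                           fluor_noise_sd=0.0)
        gt = simulate_lineages(SimParams(seed=41), 1, 40, geometry=geom)
        t = 35
        fluor = render_fov(gt, t, "fluor", noise=False).astype(float)
        mask = gt.fov_mask(t)
        for label in np.unique(mask[mask > 0]):
            sel = mask == label
            measured = (fluor[sel] - geom.fluor_background).sum()
            expected = (geom.fluor_cell_intensity - geom.fluor_background) * sel.sum()
            assert abs(measured - expected) / expected < 0.15


class TestFoci:
    def spot_frame(self, positions, amplitude=60.0, sigma=1.5, shape=(60, 30)):
        img = np.zeros(shape)
        for y, x in positions:
            img[y, x] = 1.0
        img = gaussian_filter(img, sigma) * amplitude * 2 * math.pi * sigma**2
        rng = np.random.default_rng(9)
        return img + rng.normal(0, 1.0, shape)

    def test_painted_spots_found_within_one_pixel(self):
        positions = [(10, 10), (30, 15), (50, 20)]
        img = self.spot_frame(positions)
        mask = np.zeros((60, 30), dtype=np.int32)
        mask[5:15, 5:15] = 1
        mask[25:35, 10:20] = 2
        mask[45:55, 15:25] = 3
        foci = detect_foci(img, mask, spot_sigma=1.5, threshold_sd=5.0)
        assert len(foci) == 3
        for (y, x), owner in zip(positions, (1, 2, 3)):
            match = min(foci, key=lambda f: (f.y - y) ** 2 + (f.x - x) ** 2)
            assert abs(match.y - y) <= 1 and abs(match.x - x) <= 1
            assert match.cell_label == owner

    def test_no_spots_yields_empty_list(self):
        rng = np.random.default_rng(11)
        img = rng.normal(0, 1.0, (60, 30))
        assert detect_foci(img, spot_sigma=1.5, threshold_sd=6.0) == []

    def test_dim_spot_below_threshold_not_detected(self):
        bright = self.spot_frame([(30, 15)], amplitude=60.0)
        dim = self.spot_frame([(30, 15)], amplitude=2.0)
        assert len(detect_foci(bright, spot_sigma=1.5, threshold_sd=5.0)) == 1
        assert detect_foci(dim, spot_sigma=1.5, threshold_sd=5.0) == []

    def test_tracks_link_nearest_neighbor_within_cells(self):
        from trenchline.stats import Focus, link_foci

        per_frame = [
            [Focus(0, 10, 10, 5.0, 1), Focus(0, 30, 15, 4.0, 2)],
            [Focus(1, 11, 10, 5.1, 1), Focus(1, 31, 16, 4.1, 2)],
            [Focus(2, 12, 11, 5.2, 1)],
        ]
        tracks = link_foci(per_frame, max_radius=4.0)
        assert sorted(len(t) for t in tracks) == [2, 3]
        long = max(tracks, key=len)
        assert [f.frame for f in long] == [0, 1, 2]
        assert all(f.cell_label == 1 for f in long)

    def test_distant_or_foreign_foci_start_new_tracks(self):
        from trenchline.stats import Focus, link_foci

        per_frame = [
            [Focus(0, 10, 10, 5.0, 1)],
            [Focus(1, 40, 10, 5.0, 1)],   # too far: new track
            [Focus(2, 41, 10, 5.0, 2)],   # different cell: new track
        ]
        tracks = link_foci(per_frame, max_radius=5.0)
        assert sorted(len(t) for t in tracks) == [1, 1, 1]

    def test_count_monotone_in_threshold(self):
        img = self.spot_frame([(10, 10), (30, 15), (50, 20)], amplitude=30.0)
        counts = [len(detect_foci(img, spot_sigma=1.5, threshold_sd=s))
                  for s in (2.0, 4.0, 6.0, 10.0, 20.0)]
        assert counts == sorted(counts, reverse=True)
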