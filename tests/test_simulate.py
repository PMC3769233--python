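"""Ground-truth simulator: geometry, placement, rendering, determinism."""

import numpy as np
import pytest
from scipy import stats

from spinequant import SimulationConfig, SpineGeometry, make_spine_mask
from spinequant.psf import psf_profile
from spinequant.simulate import (lognormal_brightness, place_cluster_pair,
                                 place_clusters, point_in_spine, render_image,
                                 simulate_dual_color, simulate_glass_spots,
                                 spine_origin, truncated_normal)


class TestSpineMask:
    def test_mask_area_matches_closed_form(self, geometry):
        # pi*150^2 + 300*100 = 100,686 nm^2
        truth_nm2 = np.pi * 150.0**2 + 300.0 * 100.0
        mask = make_spine_mask(geometry, 20.0, 64)
        assert mask.sum() * 20.0**2 == pytest.approx(truth_nm2, rel=0.05)

    def test_mask_area_converges_with_finer_pixels(self, geometry):
        truth_nm2 = np.pi * 150.0**2 + 300.0 * 100.0
        mask = make_spine_mask(geometry, 1.0, 700)
        assert mask.sum() * 1.0 == pytest.approx(truth_nm2, rel=0.005)

    def test_degenerate_geometry_neck_as_wide_as_head(self):
        g = SpineGeometry(head_diameter_nm=100, neck_length_nm=200,
                          neck_width_nm=100)
        mask = make_spine_mask(g, 5.0, 80)
        assert mask.sum() * 25.0 == pytest.approx(
            np.pi * 50.0**2 + 200.0 * 100.0, rel=0.05)
        # single connected region
        from scipy import ndimage
        _, n_regions = ndimage.label(mask)
        assert n_regions == 1

    def test_spine_larger_than_field_rejected(self, geometry):
        with pytest.raises(ValueError, match="fit"):
            make_spine_mask(geometry, 20.0, 16)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SpineGeometry(head_diameter_nm=50, neck_width_nm=100)
        with pytest.raises(ValueError):
            SpineGeometry(head_diameter_nm=-1)


class TestPlaceClusters:
    def test_zero_clusters_gives_empty_truth(self, geometry, rng):
        truth = place_clusters(geometry, 0, 52.0, 4, rng)
        assert truth.clusters == [] and truth.emitters == []

    def test_minimum_pairwise_separation_respected(self, geometry, rng):
        truth = place_clusters(geometry, 3, 52.0, 4, rng,
                               min_separation_nm=100.0)
        c = truth.cluster_centers("A")
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.hypot(*(c[i] - c[j])) >= 100.0

    def test_infeasible_separation_raises(self, geometry, rng):
        with pytest.raises(RuntimeError, match="min_separation"):
            place_clusters(geometry, 10, 52.0, 2, rng,
                           min_separation_nm=400.0)

    def test_emitter_disc_radius_and_mean_distance(self, geometry, rng):
        # uniform disc of diameter 52: max radius 26, mean radius (2/3)*26
        dists = []
        for _ in range(300):
            truth = place_clusters(geometry, 2, 52.0, 20, rng,
                                   linkage_offset_nm=(0.0, 0.0))
            for e in truth.emitters:
                c = truth.clusters[e.cluster_id]
                dists.append(np.hypot(e.x_nm - c.x_nm, e.y_nm - c.y_nm))
        dists = np.array(dists)
        assert dists.max() <= 26.0 + 1e-9
        assert dists.mean() == pytest.approx(2.0 / 3.0 * 26.0, abs=0.3)

    def test_all_emitters_inside_spine_with_linkage(self, geometry, rng):
        for _ in range(50):
            truth = place_clusters(geometry, 4, 52.0, 5, rng)
            xs = np.array([e.x_nm for e in truth.emitters])
            ys = np.array([e.y_nm for e in truth.emitters])
            assert point_in_spine(geometry, truth.origin_xy_nm, xs, ys).all()

    def test_pair_placement_realises_drawn_separation(self, geometry, rng):
        truth = place_cluster_pair(geometry, 110.0, 52.0, 4, rng)
        c = truth.cluster_centers("A")
        assert np.hypot(*(c[0] - c[1])) == pytest.approx(110.0, abs=1e-9)


class TestRenderImage:
    def test_single_emitter_peak_and_width(self, geometry):
        from spinequant.simulate import Emitter, GroundTruthSpine
        sim = SimulationConfig(noise="none", background=0.0)
        truth = GroundTruthSpine(geometry, (640.0, 640.0))
        x = y = (32 + 0.5) * 20.0  # a pixel centre
        truth.emitters.append(Emitter("A", 0, x, y, 32.0))
        img = render_image(truth, sim, "A")
        assert img.pixels.max() == pytest.approx(32.0, rel=0.10)
        from spinequant.detect import measure_fwhm
        fwhm, _ = measure_fwhm(img, (x, y), background=0.0)
        assert fwhm == pytest.approx(sim.psf.fwhm_nm, abs=2.0)

    def test_rendering_is_linear_in_emitters(self, geometry):
        sim = SimulationConfig(noise="none", background=0.0)
        rng = np.random.default_rng(1)
        t1 = place_clusters(geometry, 1, 0.1, 1, rng,
                            linkage_offset_nm=(0.0, 0.0))
        t2 = place_clusters(geometry, 1, 0.1, 1, rng,
                            linkage_offset_nm=(0.0, 0.0))
        both = place_clusters(geometry, 0, 52.0, 1, rng)
        both.emitters = t1.emitters + t2.emitters
        a = render_image(t1, sim, "A").pixels
        b = render_image(t2, sim, "A").pixels
        ab = render_image(both, sim, "A").pixels
        assert np.allclose(ab, a + b, rtol=1e-12)

    def test_noiseless_total_counts_match_forward_model(self, geometry):
        sim = SimulationConfig(noise="none", background=2.0)
        rng = np.random.default_rng(2)
        truth = place_clusters(geometry, 3, 52.0, 4, rng)
        img = render_image(truth, sim, "A")
        # independent evaluation of the expected-counts identity
        n = sim.field_size_px
        xc = (np.arange(n) + 0.5) * sim.pixel_size_nm
        xx, yy = np.meshgrid(xc, xc)
        expected = sim.background * n * n
        for e in truth.emitters:
            r = np.hypot(xx - e.x_nm, yy - e.y_nm)
            expected += e.brightness * psf_profile("lorentzian", 40.0, r).sum()
        assert img.pixels.sum() == pytest.approx(expected, rel=0.01)

    def test_fixed_seed_reproduces_identical_rasters(self, geometry):
        def run():
            sim = SimulationConfig(seed=11)
            rng = np.random.default_rng(11)
            truth = place_clusters(geometry, 3, 52.0, 4, rng)
            return render_image(truth, sim, "A", rng=rng).pixels
        assert np.array_equal(run(), run())

    def test_unknown_channel_rejected(self, geometry, rng):
        sim = SimulationConfig()
        truth = place_clusters(geometry, 2, 52.0, 3, rng)
        with pytest.raises(ValueError, match="channel"):
            render_image(truth, sim, "Z")


class TestDualColor:
    def test_point_mass_zero_gives_zero_cross_distances(self, geometry):
        sim = SimulationConfig(noise="none")
        rng = np.random.default_rng(3)
        _, _, truth = simulate_dual_color(
            geometry, n_a=2, n_b=1, cross_nn_dist=0.0, extent_dist=52.0,
            complexes_dist=3, config=sim, rng=rng, min_separation_a_nm=0.0,
            render=False)
        d = [c.realized_cross_nn_nm for c in truth.clusters if c.channel == "A"]
        assert d == pytest.approx([0.0, 0.0], abs=1e-9)

    def test_single_pair_records_exact_distance(self, geometry):
        sim = SimulationConfig(noise="none")
        rng = np.random.default_rng(4)
        _, _, truth = simulate_dual_color(
            geometry, n_a=1, n_b=1, cross_nn_dist=70.0, extent_dist=52.0,
            complexes_dist=3, config=sim, rng=rng, render=False)
        table = truth.truth_table()
        d = table.loc[table.channel == "A", "realized_cross_nn_nm"].iloc[0]
        assert d == pytest.approx(70.0, abs=1e-9)

    def test_truncated_normal_cross_distances_match_analytic_mean(self, geometry):
        sim = SimulationConfig(noise="none")
        realized = []
        for i in range(500):
            rng = np.random.default_rng([5, i])
            _, _, truth = simulate_dual_color(
                geometry, n_a=1, n_b=1,
                cross_nn_dist=truncated_normal(70.0, 40.0), extent_dist=52.0,
                complexes_dist=3, config=sim, rng=rng, render=False)
            realized += [c.realized_cross_nn_nm for c in truth.clusters
                         if c.channel == "A"]
        realized = np.array(realized)
        analytic = stats.truncnorm.mean(-70.0 / 40.0, np.inf, loc=70.0, scale=40.0)
        sem = realized.std(ddof=1) / np.sqrt(realized.size)
        assert abs(realized.mean() - analytic) <= 3 * sem


class TestGlassSpots:
    def test_zero_spots_gives_background_only(self):
        sim = SimulationConfig(noise="none", background=1.5)
        img, table = simulate_glass_spots(0, sim)
        assert len(table) == 0
        assert np.allclose(img.pixels, 1.5)

    def test_zero_variance_spots_peak_at_calibration_value(self):
        sim = SimulationConfig(noise="none", background=0.0,
                               single_complex_sd=0.0, field_size_px=128)
        img, table = simulate_glass_spots(13, sim)
        from spinequant.detect import measure_fwhm
        for _, row in table.iterrows():
            # cubic-interpolated peak at the true position
            _, _ = row["x_nm"], row["y_nm"]
        assert np.all(np.abs(table["brightness"] - 32.0) < 1e-9)
        assert img.pixels.max() == pytest.approx(32.0, rel=0.10)

    def test_brightness_calibration_mean_32(self):
        # lognormal brightness model hits the printed 32-count calibration
        rng = np.random.default_rng(6)
        draw = lognormal_brightness(32.0, 12.0)
        peaks = np.array([draw(rng) for _ in range(1000)])
        sem = peaks.std(ddof=1) / np.sqrt(peaks.size)
        assert abs(peaks.mean() - 32.0) <= 3 * sem

    def test_overcrowded_field_raises(self):
        sim = SimulationConfig(field_size_px=32)
        with pytest.raises(RuntimeError, match="glass-spot"):
            simulate_glass_spots(50, sim, min_separation_nm=300.0)


def test_spine_origin_centres_bounding_box(geometry):
    x0, y0 = spine_origin(geometry, 20.0, 64)
    # bounding box 600x300 nm in a 1280x1280 field
    assert x0 == pytest.approx((1280 - 600) / 2 + 150)
    assert y0 == pytest.approx(640)
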