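"""Stoichiometry and copy-number arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinequant import (AVOGADRO, SpineGeometry, brightness_ratio,
                        copies_from_concentration,
                        copies_per_spine_from_imaging, spine_volume)


class TestBrightnessRatio:
    def test_published_calibration_rounds_to_four(self):
        ratio, means, sds, ns = brightness_ratio([121.0], [32.0])
        assert ratio == pytest.approx(121.0 / 32.0)
        assert round(ratio) == 4

    def test_identical_lists_give_unity(self):
        assert brightness_ratio([5.0, 7.0], [5.0, 7.0])[0] == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        assert brightness_ratio([10.0, 20.0, 30.0], [10.0])[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("clusters,ref", [([], [32.0]), ([121.0], []),
                                              ([-1.0], [32.0])])
    def test_bad_inputs_rejected(self, clusters, ref):
        with pytest.raises(ValueError):
            brightness_ratio(clusters, ref)

    @given(st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_under_common_rescaling(self, scale):
        a, b = np.array([50.0, 100.0, 150.0]), np.array([20.0, 40.0])
        r1 = brightness_ratio(a, b)[0]
        r2 = brightness_ratio(a * scale, b * scale)[0]
        assert r2 == pytest.approx(r1, rel=1e-12)


class TestSpineVolume:
    def test_default_geometry_closed_form(self):
        # (pi/6)*300^3 + pi*50^2*300 nm^3 = 1.649e-17 L
        v = spine_volume(SpineGeometry())
        expected = (np.pi / 6 * 300**3 + np.pi * 50**2 * 300) * 1e-24
        assert v == pytest.approx(expected, rel=1e-12)
        assert v == pytest.approx(1.649e-17, rel=1e-3)

    def test_degenerate_head_is_bare_cylinder(self):
        assert spine_volume((0.0, 300.0, 100.0)) == pytest.approx(2.36e-18,
                                                                  rel=1e-2)

    def test_cubic_scaling_law(self):
        v1 = spine_volume(SpineGeometry(300, 300, 100))
        v2 = spine_volume(SpineGeometry(600, 600, 200))
        assert v2 == pytest.approx(8 * v1, rel=1e-12)

    def test_matches_monte_carlo_integration(self):
        # independent 3-D rejection-sampling oracle, 1e6 points
        rng = np.random.default_rng(17)
        D, L, w = 300.0, 300.0, 100.0
        # bounding box: head sphere [-150,150]^3, neck cylinder along x
        lo = np.array([-D / 2, -D / 2, -D / 2])
        hi = np.array([D / 2 + L, D / 2, D / 2])
        pts = rng.uniform(lo, hi, size=(1_000_000, 3))
        in_head = (pts**2).sum(axis=1) <= (D / 2) ** 2
        in_neck = ((pts[:, 0] >= D / 2) & (pts[:, 0] <= D / 2 + L)
                   & (pts[:, 1] ** 2 + pts[:, 2] ** 2 <= (w / 2) ** 2))
        box_vol = np.prod(hi - lo)
        mc = box_vol * np.mean(in_head | in_neck) * 1e-24
        assert spine_volume(SpineGeometry(D, L, w)) == pytest.approx(mc,
                                                                     rel=0.005)

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            spine_volume((-1.0, 300.0, 100.0))


class TestCopiesFromConcentration:
    def test_published_worked_example(self):
        # V ~ 2e-17 L at 50 uM -> 602 copies, "approximately 600"
        assert copies_from_concentration(2e-17, 50e-6) == 602

    def test_zero_concentration(self):
        assert copies_from_concentration(1e-17, 0.0) == 0

    def test_single_molecule_unit_case(self):
        assert copies_from_concentration(1.0 / AVOGADRO, 1.0) == 1

    @given(st.floats(1e-19, 1e-15), st.floats(1e-7, 1e-3))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_linear_in_both_arguments(self, v, c):
        base = v * c * AVOGADRO
        assert copies_from_concentration(2 * v, c) == round(2 * base)
        assert copies_from_concentration(v, 3 * c) == round(3 * base)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            copies_from_concentration(0.0, 1e-6)
        with pytest.raises(ValueError):
            copies_from_concentration(1e-17, -1.0)


class TestCopiesPerSpine:
    def _cluster(self, peak):
        from spinequant.detect import Cluster
        return Cluster(x_nm=0, y_nm=0, peak_counts=peak)

    def test_three_clusters_at_four_fold_reference(self):
        clusters = [self._cluster(128.0)] * 3
        out = copies_per_spine_from_imaging(clusters, [32.0])
        assert out["per_cluster_counts"] == [4, 4, 4]
        assert out["spine_total"] == 12
        assert "unlabeled_fraction_unknown" in out["flags"]

    def test_dim_cluster_clamps_to_one_with_flag(self):
        out = copies_per_spine_from_imaging([self._cluster(10.0)], [32.0])
        assert out["per_cluster_counts"] == [1]
        assert "clamped_to_one" in out["flags"]

    def test_no_clusters_rejected(self):
        with pytest.raises(ValueError):
            copies_per_spine_from_imaging([], [32.0])

    def test_recovers_simulated_complex_total_for_compact_clusters(self):
        # compact (10 nm) clusters of fixed-brightness complexes, no noise:
        # peak-ratio counting recovers the true total within 20%
        from spinequant import AnalysisConfig, SimulationConfig, SpineGeometry
        from spinequant.pipeline import analyze_image
        from spinequant.simulate import place_clusters, render_image
        rng = np.random.default_rng(23)
        sim = SimulationConfig(noise="none", single_complex_sd=0.0)
        truth = place_clusters(SpineGeometry(), 3, 10.0, 4, rng,
                               min_separation_nm=150.0,
                               linkage_offset_nm=(0.0, 0.0),
                               brightness=lambda r: 32.0)
        img = render_image(truth, sim, "A")
        clusters, _ = analyze_image(img, AnalysisConfig())
        out = copies_per_spine_from_imaging(clusters, [32.0])
        true_total = sum(c.n_complexes for c in truth.clusters)
        assert abs(out["spine_total"] - true_total) / true_total <= 0.20
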