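"""Morphometric formulas: shape indices, ratios, thresholds, duct filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumenmorph import morphometrics as mm
from lumenmorph.fixtures import (ellipsoid_spec, gen_duct_filter_scenario,
                                 gen_intensity_samples, sphere_spec)


def sphere_measure(r):
    return mm.SurfaceMeasure(volume=4 / 3 * np.pi * r**3,
                             surface_area=4 * np.pi * r**2)


class TestSphericity:
    @pytest.mark.parametrize("r", [0.5, 1.0, 7.3, 120.0])
    def test_any_sphere_is_exactly_one(self, r):
        assert mm.sphericity(sphere_measure(r)) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_cube_value_closed_form(self):
        a = 3.7
        m = mm.SurfaceMeasure(volume=a**3, surface_area=6 * a**2)
        assert mm.sphericity(m) == pytest.approx((np.pi / 6) ** (1 / 3),
                                                 rel=1e-9)   # ≈ 0.806

    def test_elongating_ellipsoids_strictly_decrease(self):
        values = []
        for stretch in (1.0, 1.5, 2.5, 4.0):
            # constant volume: a = stretch, b = c = 1/sqrt(stretch)
            spec = ellipsoid_spec((0, 0, 0),
                                  (stretch, stretch**-0.5, stretch**-0.5))
            values.append(mm.sphericity(
                mm.SurfaceMeasure(spec["volume"], spec["surface_area"])))
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[0] == pytest.approx(1.0, abs=2e-2)  # SA approximation

    @given(r=st.floats(0.1, 50), s=st.floats(0.1, 10))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, r, s):
        m = sphere_measure(r)
        scaled = mm.SurfaceMeasure(m.volume * s**3, m.surface_area * s**2)
        assert mm.sphericity(scaled) == pytest.approx(mm.sphericity(m),
                                                      rel=1e-9)

    def test_isoperimetric_violation_rejected(self):
        with pytest.raises(ValueError):
            mm.SurfaceMeasure(volume=100.0, surface_area=1.0)


class TestOccupancy:
    @pytest.mark.parametrize("lumen, organoid, expected", [
        (30.0, 120.0, 25.0),
        (0.0, 120.0, 0.0),
        (120.0, 120.0, 100.0),
    ])
    def test_percentage(self, lumen, organoid, expected):
        assert mm.occupancy(lumen, organoid) == pytest.approx(expected)

    def test_lumen_exceeding_organoid_rejected(self):
        with pytest.raises(ValueError):
            mm.occupancy(130.0, 120.0)


class TestSurfaceToVolume:
    def test_spheres_share_the_scale_free_constant(self):
        vals = [mm.surface_to_volume_scalefree(sphere_measure(r))
                for r in (1.0, 5.0, 50.0)]
        expected = 2 * np.sqrt(np.pi) / (4 * np.pi / 3) ** (1 / 3)
        for v in vals:
            assert v == pytest.approx(expected, rel=1e-12)   # ≈ 2.199
        assert expected == pytest.approx(2.199, abs=1e-3)

    def test_splitting_a_sphere_raises_the_ratio(self):
        one = mm.surface_to_volume_scalefree(sphere_measure(1.0))
        # two spheres of half the volume each: SA scales by 2^(1/3)
        r_half = (0.5) ** (1 / 3)
        half = sphere_measure(r_half)
        split = mm.SurfaceMeasure(volume=2 * half.volume,
                                  surface_area=2 * half.surface_area)
        assert mm.surface_to_volume_scalefree(split) == pytest.approx(
            one * 2 ** (1 / 6), rel=1e-9)
        assert mm.surface_to_volume_scalefree(split) > one

    def test_degenerate_volume_rejected(self):
        with pytest.raises(ValueError):
            mm.SurfaceMeasure(volume=0.0, surface_area=1.0)


class TestCountRatios:
    def test_marker_ratio_examples(self):
        assert mm.marker_ratio(mm.CountPair(12, 48)) == 0.25
        assert mm.marker_ratio(mm.CountPair(0, 7)) == 0.0
        assert mm.marker_ratio(mm.CountPair(7, 7)) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            mm.marker_ratio(mm.CountPair(0, 0))

    def test_numerator_cannot_exceed_denominator(self):
        with pytest.raises(ValueError):
            mm.CountPair(5, 4)

    @pytest.mark.parametrize("n48, n96, expected", [
        (100.0, 200.0, 48.0),
        (100.0, 400.0, 24.0),
    ])
    def test_doubling_time(self, n48, n96, expected):
        assert mm.doubling_time(n48, n96, 48.0) == pytest.approx(expected)

    def test_no_growth_is_undefined(self):
        with pytest.raises(ValueError):
            mm.doubling_time(100.0, 100.0)


class TestKdeThreshold:
    def test_threshold_lies_between_separated_means(self):
        a, b, _ = gen_intensity_samples(0.2, 0.05, 200, 0.8, 0.05, 200,
                                        seed=0)
        thr = mm.kde_intersection_threshold(a, b)
        assert 0.4 < thr < 0.6

    def test_identical_samples_have_no_threshold(self):
        a, _, _ = gen_intensity_samples(0.5, 0.1, 100, 0.5, 0.1, 100, seed=1)
        with pytest.raises(mm.NoThresholdError):
            mm.kde_intersection_threshold(a, a)

    def test_symmetric_in_sample_order(self):
        a, b, _ = gen_intensity_samples(0.3, 0.07, 150, 0.7, 0.07, 150,
                                        seed=2)
        t1 = mm.kde_intersection_threshold(a, b)
        t2 = mm.kde_intersection_threshold(b, a)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            mm.kde_intersection_threshold([1.0, 1.0], [0.2, 0.4])


class TestDuctFilter:
    def test_printed_threshold_matches_sphere_radius(self):
        # the exact sphere-equivalent radius of 337 µm³ is 4.317 µm; the
        # published rounding is 4.31, so agreement is at printed precision
        r = (3 * mm.DUCT_MIN_VOLUME_UM3 / (4 * np.pi)) ** (1 / 3)
        assert r == pytest.approx(4.31, abs=0.01)

    def test_worked_example_volumes(self):
        """Label volumes {100, 300, 400, 500, 600} µm³: threshold keeps
        {400, 500, 600}, median 500, isolated subset {400}.  Boxes give
        exact voxel volumes."""
        labels = np.zeros((32, 20, 40), dtype=int)
        for k, v in enumerate([100, 300, 400, 500, 600], start=1):
            labels[5:5 + v // 25, 5:10, 7 * k - 5:7 * k] = k   # 5x5 column
        lv = mm.LabelVolume(labels, (1.0, 1.0, 1.0))
        assert sorted(lv.label_volumes().values()) == [100, 300, 400,
                                                       500, 600]
        out = mm.filter_duct_labels(lv)
        assert sorted(out["filtered"].label_volumes().values()) \
            == [400, 500, 600]
        assert out["median_volume"] == 500.0
        assert list(out["isolated"].label_volumes().values()) == [400.0]
        assert out["audit"] == {"input": 5, "after_edge_removal": 5,
                                "after_volume_threshold": 3, "isolated": 1}

    def test_sphere_scenario_filters_consistently(self):
        lv, truths = gen_duct_filter_scenario(
            volumes_um3=(100.0, 300.0, 400.0, 500.0, 600.0))
        out = mm.filter_duct_labels(lv)
        assert out["audit"]["after_volume_threshold"] == 3
        assert out["audit"]["isolated"] == 1

    def test_edge_touching_labels_removed_first(self):
        lv, _ = gen_duct_filter_scenario(edge_touching=True)
        out = mm.filter_duct_labels(lv)
        assert out["audit"]["after_edge_removal"] \
            == out["audit"]["input"] - 1

    def test_all_edge_touching_yields_empty(self):
        labels = np.ones((8, 8, 8), dtype=int)
        lv = mm.LabelVolume(labels, (1.0, 1.0, 1.0))
        out = mm.filter_duct_labels(lv)
        assert out["audit"]["after_volume_threshold"] == 0
        assert not out["filtered"].label_volumes()

    def test_step_counts_never_increase(self):
        lv, _ = gen_duct_filter_scenario(edge_touching=True)
        a = mm.filter_duct_labels(lv)["audit"]
        assert (a["input"] >= a["after_edge_removal"]
                >= a["after_volume_threshold"] >= a["isolated"])


class TestTileDensity:
    def _single_label_volume(self):
        labels = np.zeros((30, 100, 100), dtype=int)
        labels[12:18, 40:60, 40:60] = 1
        return mm.LabelVolume(labels, (1.0, 1.0, 1.0))

    def test_single_label_in_single_tile(self):
        lv = self._single_label_volume()
        region = np.ones(lv.labels.shape, dtype=bool)
        out = mm.tile_density(lv, region, tile_um=(24.0, 88.5, 88.5),
                              overlap_min=0.5)
        # one centroid in one of the qualifying tiles
        expected_single = 1.0 / (24.0 * 88.5 * 88.5)
        assert out["mean_density"] == pytest.approx(
            expected_single / out["n_tiles"], rel=1e-9)
        assert expected_single == pytest.approx(5.32e-6, rel=0.01)

    def test_zero_isolated_labels_zero_density(self):
        lv = mm.LabelVolume(np.zeros((30, 100, 100), dtype=int),
                            (1.0, 1.0, 1.0))
        region = np.ones(lv.labels.shape, dtype=bool)
        out = mm.tile_density(lv, region)
        assert out["mean_density"] == 0.0

    def test_region_smaller_than_tile_with_full_overlap_required(self):
        lv = self._single_label_volume()
        region = np.zeros(lv.labels.shape, dtype=bool)
        region[:4, :4, :4] = True
        with pytest.raises(ValueError):
            mm.tile_density(lv, region, overlap_min=1.0)


class TestDextranRatio:
    def test_ratio_of_means(self):
        assert mm.dextran_ratio([400, 400], [400, 400]) == 1.0
        assert mm.dextran_ratio([800, 800], [400, 400]) == 2.0

    def test_single_lumen_sample_rejected(self):
        with pytest.raises(ValueError):
            mm.dextran_ratio([400], [400])

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mm.dextran_ratio([400, 500], [400])


class TestSkeletonLength:
    def test_straight_line_isotropic(self):
        voxels = [(0, 0, k) for k in range(11)]
        assert mm.skeleton_total_length(voxels, (1.0, 1.0, 1.0)) \
            == pytest.approx(10.0)

    def test_anisotropic_z_spacing(self):
        voxels = [(k, 0, 0) for k in range(11)]
        assert mm.skeleton_total_length(voxels, (2.0, 1.0, 1.0)) \
            == pytest.approx(20.0)

    def test_two_disjoint_lines_add(self):
        voxels = ([(0, 0, k) for k in range(11)]
                  + [(5, 5, k) for k in range(11)])
        assert mm.skeleton_total_length(voxels, (1.0, 1.0, 1.0)) \
            == pytest.approx(20.0)

    def test_empty_skeleton_is_zero(self):
        assert mm.skeleton_total_length([], (1.0, 1.0, 1.0)) == 0.0

    def test_diagonal_steps_use_euclidean_length(self):
        voxels = [(k, k, 0) for k in range(5)]
        assert mm.skeleton_total_length(voxels, (1.0, 1.0, 1.0)) \
            == pytest.approx(4 * np.sqrt(2))


class TestMidplaneOccupancy:
    def test_label_volumes_and_midplane_rule(self):
        organoid = np.zeros((9, 12, 12), dtype=int)
        organoid[2:7, 2:10, 2:10] = 1          # 5 slices of 64 voxels
        lumen = np.zeros((9, 12, 12), dtype=int)
        lumen[3:6, 4:8, 4:8] = 1               # 3 slices of 16 voxels
        vs = (2.0, 1.0, 1.0)
        lv_o = mm.LabelVolume(organoid, vs)
        lv_l = mm.LabelVolume(lumen, vs)
        assert mm.occupancy(lv_l, lv_o) == pytest.approx(
            100.0 * (3 * 16) / (5 * 64))
        mid_o = mm.midplane_slice(lv_o)
        mid_l = mm.midplane_slice(lv_l)
        assert mid_o.labels.ndim == 2
        assert mm.occupancy(mid_l, mid_o) == pytest.approx(
            100.0 * 16 / 64)
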