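"""Septum morphometry: segmentation, profiles, moments of area, AUC tests."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage.measure import regionprops

from coralskel.morphometry import (
    LabelVolume,
    auc,
    compare_auc,
    inertia_profile,
    max_moment_of_inertia,
    phase_volume,
    principal_moments_of_area,
    rad_onset_height,
    segment_phases,
    septum_profile,
    slice_metrics,
)
from coralskel.phantom import generate_polyp_phantom


def _density_volume(phantom):
    spec = phantom.truth["spec"]
    scale = (spec.gray_enamel - spec.gray_background) / 2.8
    return (phantom.gray - spec.gray_background) / scale


class TestSegmentation:
    def test_noise_free_phantom_segments_exactly(self, small_phantom):
        rho = _density_volume(small_phantom)
        lv = segment_phases(rho, (1.0, 2.14), small_phantom.voxel_size)
        assert np.array_equal(lv.labels, small_phantom.labels)

    def test_all_background_volume(self):
        lv = segment_phases(np.zeros((8, 8, 8)), (1.0, 2.14), 1.0)
        assert np.count_nonzero(lv.labels) == 0

    def test_noisy_phantom_disagreement_below_one_percent(self, noisy_phantom):
        rho = _density_volume(noisy_phantom)
        lv = segment_phases(rho, (1.0, 2.14), noisy_phantom.voxel_size)
        disagree = np.mean(lv.labels != noisy_phantom.labels)
        assert disagree < 0.01

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            segment_phases(np.zeros((4, 4, 4)), (2.0, 1.0), 1.0)


class TestSliceMetrics:
    def test_disc_axes_recovered(self):
        yy, xx = np.mgrid[-32:33, -32:33]
        disc = (xx**2 + yy**2 <= 20**2).astype(np.uint8)
        vol = LabelVolume(disc[:, :, None], 1.0)
        m = slice_metrics(vol, 1, 0)
        assert m.width == pytest.approx(40.0, abs=1.0)
        assert m.length == pytest.approx(40.0, abs=1.0)

    def test_ellipse_axes_recovered_within_one_pixel(self):
        yy, xx = np.mgrid[-48:49, -48:49]
        ell = ((xx / 40.0) ** 2 + (yy / 10.0) ** 2 <= 1.0).astype(np.uint8)
        vol = LabelVolume(ell[:, :, None], 1.0)
        m = slice_metrics(vol, 1, 0)
        assert m.length == pytest.approx(80.0, abs=1.0)
        assert m.width == pytest.approx(20.0, abs=1.0)

    def test_axes_match_skimage_regionprops(self):
        yy, xx = np.mgrid[-48:49, -48:49]
        ell = ((xx / 33.0) ** 2 + (yy / 12.0) ** 2 <= 1.0).astype(np.uint8)
        props = regionprops(ell)[0]
        vol = LabelVolume(ell[:, :, None], 1.0)
        m = slice_metrics(vol, 1, 0)
        assert m.length == pytest.approx(props.axis_major_length, rel=0.02)
        assert m.width == pytest.approx(props.axis_minor_length, rel=0.02)

    def test_single_voxel_area(self):
        arr = np.zeros((5, 5, 1), dtype=np.uint8)
        arr[2, 2, 0] = 1
        m = slice_metrics(LabelVolume(arr, 2.2), 1, 0)
        assert m.area == pytest.approx(2.2**2)

    def test_empty_slice_gives_zeros(self):
        arr = np.zeros((5, 5, 2), dtype=np.uint8)
        arr[2, 2, 0] = 1
        m = slice_metrics(LabelVolume(arr, 1.0), 1, 1)
        assert m.area == 0.0 and m.width == 0.0 and m.length == 0.0


class TestSeptumProfiles:
    def test_constant_cross_section_gives_flat_profile(self, small_spec):
        # no RAD carve-out, so the TD cross-section is constant with height
        spec = dataclasses.replace(small_spec, rad_radius=0.0)
        vol = generate_polyp_phantom(spec)
        lv = LabelVolume(vol.labels, vol.voxel_size)
        prof = septum_profile(lv, 1, vol.septum_labels, n_bins=20)
        assert np.nanmax(prof.mean) - np.nanmin(prof.mean) < 0.05 * np.nanmean(
            prof.mean
        )

    def test_linear_taper_gives_linear_profile(self, small_spec):
        spec = dataclasses.replace(
            small_spec,
            septum_width_profile=lambda h: 14.0 - 6.0 * h,
            rad_radius=0.0,
        )
        vol = generate_polyp_phantom(spec)
        lv = LabelVolume(vol.labels, vol.voxel_size)
        prof = septum_profile(lv, 1, vol.septum_labels, n_bins=20)
        h = prof.height_pct / 100.0
        fit = np.polyfit(h, prof.mean, 1)
        resid = prof.mean - np.polyval(fit, h)
        # voxelization leaves small steps; the linear trend dominates
        assert fit[0] < 0
        assert np.abs(resid).max() < 0.05 * prof.mean.mean()

    def test_rad_profile_zero_below_onset(self, small_phantom):
        lv = LabelVolume(small_phantom.labels, small_phantom.voxel_size)
        prof = septum_profile(lv, 2, small_phantom.septum_labels, n_bins=100)
        onset = small_phantom.truth["spec"].rad_onset_fraction
        below = prof.height_pct < onset * 100.0 - 1.0
        assert np.all(np.nan_to_num(prof.mean[below]) == 0.0)

    @pytest.mark.parametrize("onset", [0.05, 0.10])
    def test_rad_onset_recovered_within_one_bin(self, small_spec, onset):
        spec = dataclasses.replace(small_spec, rad_onset_fraction=onset)
        vol = generate_polyp_phantom(spec)
        lv = LabelVolume(vol.labels, vol.voxel_size)
        prof = septum_profile(lv, 2, vol.septum_labels, n_bins=100)
        got = rad_onset_height(prof)
        assert got is not None
        assert abs(got - onset * 100.0) <= 1.0 + 0.5  # one 1%-bin plus centre offset

    def test_rad_onset_absent_for_zero_rad(self, small_spec):
        spec = dataclasses.replace(small_spec, rad_radius=0.0)
        vol = generate_polyp_phantom(spec)
        lv = LabelVolume(vol.labels, vol.voxel_size)
        prof = septum_profile(lv, 2, vol.septum_labels, n_bins=50)
        assert rad_onset_height(prof) is None


class TestPhaseVolume:
    def test_empty_phase(self):
        lv = LabelVolume(np.zeros((4, 4, 4), dtype=np.uint8), 1.0)
        assert phase_volume(lv, 2) == 0.0

    def test_counting_rod(self):
        arr = np.zeros((10, 10, 10), dtype=np.uint8)
        arr[4, 4, :] = 2
        lv = LabelVolume(arr, 2.2)
        assert phase_volume(lv, 2) == pytest.approx(10 * 2.2**3)

    def test_phase_volumes_partition_mineral_volume(self, small_phantom):
        lv = LabelVolume(small_phantom.labels, small_phantom.voxel_size)
        total = np.count_nonzero(small_phantom.labels) * small_phantom.voxel_size**3
        assert phase_volume(lv, 1) + phase_volume(lv, 2) == pytest.approx(total)


class TestMomentsOfArea:
    def test_disc_matches_closed_form(self):
        r = 25
        yy, xx = np.mgrid[-40:41, -40:41]
        disc = xx**2 + yy**2 <= r**2
        assert max_moment_of_inertia(disc, 1.0) == pytest.approx(
            np.pi * r**4 / 4.0, rel=0.02
        )

    def test_square_matches_closed_form(self):
        a = 31
        sq = np.ones((a, a), dtype=bool)
        assert max_moment_of_inertia(sq, 1.0) == pytest.approx(a**4 / 12.0, rel=0.02)

    def test_voxel_size_scaling(self):
        sq = np.ones((15, 15), dtype=bool)
        assert max_moment_of_inertia(sq, 2.0) == pytest.approx(
            16.0 * max_moment_of_inertia(sq, 1.0)
        )

    def test_separating_bars_increases_imax(self):
        def bars(gap):
            # short bars: the separation axis carries the largest moment
            m = np.zeros((61, 61), dtype=bool)
            m[30 - gap - 3 : 30 - gap, 28:33] = True
            m[30 + gap : 30 + gap + 3, 28:33] = True
            return m

        vals = [max_moment_of_inertia(bars(g), 1.0) for g in (2, 6, 12, 20)]
        assert np.all(np.diff(vals) > 0)

    def test_imax_geq_imin_geq_zero_and_rotation_invariance(self, rng):
        mask = rng.random((25, 25)) > 0.6
        imax, imin = principal_moments_of_area(mask, 1.0)
        assert imax >= imin >= 0.0
        imax90, _ = principal_moments_of_area(np.rot90(mask), 1.0)
        assert imax90 == pytest.approx(imax, rel=1e-9)

    def test_empty_mask(self):
        assert max_moment_of_inertia(np.zeros((5, 5), bool), 1.0) == 0.0

    def test_inertia_profile_positive_over_height(self, small_phantom):
        lv = LabelVolume(small_phantom.labels, small_phantom.voxel_size)
        prof = inertia_profile(lv, 1, n_bins=20)
        assert np.all(prof.i_max > 0.0)


class TestAUC:
    def test_constant_profile(self):
        h = np.linspace(0, 1, 11)
        assert auc(np.full(11, 3.0), h) == pytest.approx(3.0)

    def test_linear_ramp(self):
        h = np.linspace(0, 1, 101)
        assert auc(h, h) == pytest.approx(0.5)

    def test_matches_refined_grid_oracle(self, rng):
        h = np.linspace(0, 1, 51)
        v = rng.random(51)
        # piecewise-linear refined-grid integration oracle
        hf = np.linspace(0, 1, 50 * 64 + 1)
        vf = np.interp(hf, h, v)
        oracle = np.trapezoid(vf, hf)
        assert abs(auc(v, h) - oracle) < 1e-10 * max(abs(oracle), 1.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            auc([1.0], [0.0])

    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
    )
    def test_linearity(self, a, b):
        h = np.linspace(0, 1, 21)
        f = np.sin(3 * h)
        g = np.cos(2 * h)
        lhs = auc(a * f + b * g, h)
        rhs = a * auc(f, h) + b * auc(g, h)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestCompareAUC:
    def test_identical_groups_not_significant(self):
        g = [1.0, 1.0, 1.0, 1.0]
        res = compare_auc(g, g)
        assert res.p_value >= 0.05

    def test_large_separation_detected(self, rng):
        a = rng.normal(0.0, 1.0, 18)
        b = rng.normal(5.0, 1.0, 18)
        res = compare_auc(a, b)
        assert res.p_value < 0.05

    def test_heavy_tails_route_to_mann_whitney(self, rng):
        a = rng.standard_cauchy(18) * 3.0
        b = rng.standard_cauchy(18) * 3.0 + 1.0
        res = compare_auc(a, b)
        assert res.test_name == "Mann-Whitney"
        assert not res.normality_pass

    def test_normal_groups_route_to_t_test(self, rng):
        a = rng.normal(0.0, 1.0, 18)
        b = rng.normal(0.3, 1.0, 18)
        res = compare_auc(a, b)
        assert res.test_name == "t-test"
        assert res.normality_pass and res.variance_pass

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1.0, 2.0], [1.0, 2.0, 3.0])
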