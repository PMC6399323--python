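"""Scar image analysis: wall thickness, subtraction, orientation, circular stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccinfarct import scarfiber, simulate
from ccinfarct.scarfiber import (
    CircularSummary,
    FiberField,
    SectionStack,
    alignment_significance,
    circular_summary,
    collagen_area_fraction,
    estimate_fiber_orientations,
    select_midwall,
    subtract_images,
    wall_thickness,
)


def _field(angles, weights=None):
    angles = np.asarray(angles, dtype=float)
    w = np.ones_like(angles) if weights is None else np.asarray(weights, float)
    return FiberField(
        centers=np.zeros((angles.size, 2)), theta=angles, weight=w,
        valid=np.ones(angles.size, dtype=bool),
    )


class TestWallThickness:
    def test_span_times_thickness(self):
        has = np.zeros(40, dtype=bool)
        has[3:34] = True
        assert wall_thickness(SectionStack(has)) == 210.0

    def test_first_zero_last_fifteen(self):
        has = np.zeros(20, dtype=bool)
        has[0:16] = True
        assert wall_thickness(SectionStack(has)) == 105.0

    def test_single_section_warns_zero(self):
        has = np.zeros(5, dtype=bool)
        has[2] = True
        with pytest.warns(UserWarning):
            assert wall_thickness(SectionStack(has)) == 0.0

    def test_no_tissue_errors(self):
        with pytest.raises(ValueError):
            wall_thickness(SectionStack(np.zeros(5, dtype=bool)))


class TestMidwall:
    def test_ten_sections_keep_depths_4_and_5_ninths(self):
        stack = SectionStack(np.ones(10, dtype=bool))
        np.testing.assert_array_equal(select_midwall(stack), [4, 5])

    def test_five_sections_keep_middle(self):
        stack = SectionStack(np.ones(5, dtype=bool))
        np.testing.assert_array_equal(select_midwall(stack), [2])

    def test_too_few_sections_error(self):
        with pytest.raises(ValueError):
            select_midwall(SectionStack(np.array([True, True, False])))


class TestSubtraction:
    def test_fiber_and_background_pixels(self):
        pol = np.array([[1.0, 0.05], [0.5, 0.0]])
        bf = np.array([[0.0, 0.95], [0.5, 1.0]])
        out = subtract_images(pol, bf)
        assert out[0, 0] == pytest.approx(1.0)
        assert out[0, 1] == 0.0  # clamped
        assert np.all(out >= 0)

    def test_identical_images_zero(self):
        img = np.random.default_rng(0).random((16, 16))
        assert subtract_images(img, img).max() == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            subtract_images(np.zeros((4, 4)), np.zeros((5, 4)))


class TestAreaFraction:
    def test_constant_zero_image(self):
        with pytest.warns(UserWarning):
            assert collagen_area_fraction(np.zeros((32, 32))) == 0.0

    def test_bright_image_absolute_threshold(self):
        assert collagen_area_fraction(
            np.ones((16, 16)), "absolute", absolute_threshold=0.5
        ) == 1.0

    def test_painted_mask_fraction_recovered(self):
        # mask covering 37% of pixels: fibers bright in pol, dark in bf
        h = w = 100
        mask = np.zeros((h, w))
        mask[:37, :] = 1.0
        pol, bf = mask, 1.0 - mask
        af = collagen_area_fraction(subtract_images(pol, bf))
        assert af == pytest.approx(0.37, abs=0.02)


class TestOrientationEstimator:
    @pytest.mark.parametrize("theta", [0.0, 30.0, 90.0, 150.0])
    def test_stripes_recovered(self, theta):
        r, c = np.mgrid[0:128, 0:128].astype(float)
        th = np.radians(theta)
        img = 0.5 + 0.5 * np.cos(
            2 * np.pi / 10.0 * (-np.sin(th) * c + np.cos(th) * r)
        )
        field = estimate_fiber_orientations(img, 16)
        cs = circular_summary(field)
        diff = abs((cs.theta_m - theta + 90) % 180 - 90)
        assert diff < 3.0

    def test_axial_wrap_zero_vs_ninety(self):
        r, c = np.mgrid[0:64, 0:64].astype(float)
        horiz = 0.5 + 0.5 * np.cos(2 * np.pi / 8 * r)  # fibers along x (0 deg)
        vert = 0.5 + 0.5 * np.cos(2 * np.pi / 8 * c)   # fibers along y (90 deg)
        t0 = circular_summary(estimate_fiber_orientations(horiz, 16)).theta_m
        t90 = circular_summary(estimate_fiber_orientations(vert, 16)).theta_m
        diff = abs((t90 - t0 + 90) % 180 - 90)
        assert diff == pytest.approx(90.0, abs=3.0)

    def test_blank_image_no_valid_subwindows(self):
        field = estimate_fiber_orientations(np.zeros((64, 64)), 16)
        assert field.valid.sum() == 0

    def test_image_smaller_than_subwindow(self):
        with pytest.raises(ValueError):
            estimate_fiber_orientations(np.zeros((8, 8)), 16)


class TestCircularSummary:
    def test_all_equal_angles_mvl_one(self):
        cs = circular_summary(_field([25.0] * 10))
        assert cs.mvl == pytest.approx(1.0)
        assert cs.theta_m == pytest.approx(25.0)

    def test_symmetric_four_angles_cancel(self):
        cs = circular_summary(_field([0.0, 45.0, 90.0, 135.0]))
        assert cs.mvl == pytest.approx(0.0, abs=1e-12)

    def test_two_angle_example(self):
        cs = circular_summary(_field([0.0, 30.0]))
        assert cs.mvl == pytest.approx(np.sqrt(3) / 2, abs=1e-12)
        assert cs.theta_m == pytest.approx(15.0, abs=1e-9)

    def test_matches_brute_force_complex_sum(self, rng):
        for _ in range(20):
            n = rng.integers(2, 50)
            ang = rng.uniform(0, 180, n)
            w = rng.uniform(0.1, 5, n)
            cs = circular_summary(_field(ang, w))
            # independent oracle: direct complex-exponential sum
            vec = sum(
                wi * complex(np.cos(2 * np.radians(a)), np.sin(2 * np.radians(a)))
                for a, wi in zip(ang, w)
            ) / w.sum()
            assert cs.mvl == pytest.approx(abs(vec), abs=1e-10)
            expected = (np.degrees(np.angle(vec)) / 2) % 180
            assert abs((cs.theta_m - expected + 90) % 180 - 90) < 1e-10

    @given(shift=st.floats(0, 180))
    @settings(max_examples=50, deadline=None)
    def test_rotation_invariance_of_mvl(self, shift):
        ang = np.array([10.0, 40.0, 75.0, 130.0])
        base = circular_summary(_field(ang))
        rot = circular_summary(_field((ang + shift) % 180))
        assert rot.mvl == pytest.approx(base.mvl, abs=1e-9)
        diff = abs((rot.theta_m - base.theta_m - shift + 90) % 180 - 90)
        assert diff < 1e-6

    def test_no_valid_elements_error(self):
        f = _field([10.0])
        f.valid[:] = False
        with pytest.raises(ValueError):
            circular_summary(f)


class TestAlignmentTest:
    def test_aligned_samples_project_to_mvl(self):
        samples = [CircularSummary(40.0, m, 10) for m in (0.5, 0.6, 0.7)]
        res = alignment_significance(samples)
        np.testing.assert_allclose(res.v, [0.5, 0.6, 0.7], atol=1e-12)
        assert res.t == pytest.approx(10.392, abs=1e-3)
        assert res.df == 2

    def test_orthogonal_pair_cancels(self):
        samples = [CircularSummary(20.0, 0.6, 5), CircularSummary(110.0, 0.6, 5)]
        res = alignment_significance(samples)
        assert abs(res.v.sum()) < 1e-9

    def test_degenerate_zero_variance(self):
        samples = [CircularSummary(30.0, 0.5, 5), CircularSummary(30.0, 0.5, 5)]
        with pytest.warns(UserWarning):
            res = alignment_significance(samples)
        assert res.degenerate and np.isnan(res.p)


class TestRecoveryFromImages:
    def test_concentrated_fibers_recovered(self):
        truth = simulate.FiberTruth(mu=30.0, kappa=1e6)
        pol, bf, _ = simulate.simulate_scar_image_pair(truth, (256, 256), seed=21)
        cs = circular_summary(
            estimate_fiber_orientations(subtract_images(pol, bf), 16)
        )
        assert abs((cs.theta_m - 30 + 90) % 180 - 90) < 2.0
        assert cs.mvl > 0.95

    def test_planted_mu_recovery_from_angles(self, rng):
        for kappa in (4.0, 8.0):
            truth = simulate.FiberTruth(mu=110.0, kappa=kappa)
            ang = simulate.sample_axial_angles(truth, 300, rng)
            cs = circular_summary(_field(ang))
            assert abs((cs.theta_m - 110 + 90) % 180 - 90) < 3.0

    def test_mvl_increases_with_kappa(self, rng):
        kappas = [0.0, 1.0, 2.0, 4.0, 8.0]
        means = []
        for kappa in kappas:
            truth = simulate.FiberTruth(mu=45.0, kappa=kappa)
            vals = [
                circular_summary(_field(simulate.sample_axial_angles(truth, 200, rng))).mvl
                for _ in range(20)
            ]
            means.append(np.mean(vals))
        assert all(a < b for a, b in zip(means, means[1:]))
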