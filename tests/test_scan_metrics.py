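"""Curve metrics: smoothing, normalization, d_max, PDD, FWHM, penumbra."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erf

import sfdose as sf
from sfdose.errors import (
    DegenerateInputError,
    RangeError,
    ShapeError,
    ValidationError,
)
from sfdose.synthetic_data import _convolve_with_aperture


def depth_curve(positions, values, **kwargs):
    defaults = dict(detector_id="X", field_x_cm=10.0, field_y_cm=10.0)
    defaults.update(kwargs)
    return sf.ScanCurve(axis="depth", positions=positions, values=values, **defaults)


def lateral_curve(positions, values, **kwargs):
    defaults = dict(
        detector_id="X", field_x_cm=2.0, field_y_cm=2.0, scan_depth_mm=100.0
    )
    defaults.update(kwargs)
    return sf.ScanCurve(axis="crossline", positions=positions, values=values, **defaults)


# ---------------------------------------------------------------------------
# smoothing


class TestSmooth:
    @given(
        coeffs=st.lists(
            st.floats(min_value=-5, max_value=5), min_size=1, max_size=3
        )
    )
    def test_preserves_polynomials_up_to_polyorder(self, coeffs):
        x = np.linspace(0, 50, 41)
        # offset keeps the curve positive for any coefficients in range
        y = np.polynomial.polynomial.polyval(x / 50.0, coeffs) + 20.0
        curve = depth_curve(x, y)
        out = sf.smooth(curve, window=7, polyorder=2)
        np.testing.assert_allclose(out.values, curve.values, rtol=1e-9, atol=1e-9)

    def test_quadratic_reproduced_exactly(self):
        x = np.arange(0, 30.0)
        y = 100.0 - 0.1 * (x - 14.0) ** 2
        out = sf.smooth(depth_curve(x, y), window=5, polyorder=2)
        np.testing.assert_allclose(out.values, y, rtol=1e-9)

    def test_reduces_noise_variance_in_every_seeded_trial(self):
        x = np.arange(0, 100.0)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = np.abs(50.0 + rng.normal(0, 0.5, size=x.size))
            out = sf.smooth(depth_curve(x, noisy), window=9, polyorder=2)
            assert out.values.std() < noisy.std()

    def test_nonuniform_grid_still_preserves_quadratics(self):
        x = np.sort(np.concatenate([np.arange(0, 20.0), [0.3, 5.7, 13.2]]))
        y = 50.0 + 2.0 * x - 0.05 * x**2
        out = sf.smooth(depth_curve(x, y), window=5, polyorder=2)
        np.testing.assert_allclose(out.values, y, rtol=1e-8)

    @pytest.mark.parametrize("window, polyorder", [(4, 2), (7, 7), (99, 2)])
    def test_invalid_arguments_rejected(self, window, polyorder):
        x = np.arange(0, 20.0)
        with pytest.raises(ValidationError):
            sf.smooth(depth_curve(x, x + 1.0), window=window, polyorder=polyorder)


# ---------------------------------------------------------------------------
# normalization and PDD


class TestDepthMetrics:
    def test_normalize_to_max_scales_peak_to_100(self):
        curve = depth_curve([0, 1, 2, 3, 4], [1, 2, 4, 2, 1])
        out = sf.normalize_to_max(curve)
        np.testing.assert_allclose(out.values, [25, 50, 100, 50, 25])
        assert out.normalized == "max100"

    def test_normalize_to_max_idempotent(self):
        curve = depth_curve([0, 1, 2, 3, 4], [1, 2, 4, 2, 1])
        once = sf.normalize_to_max(curve)
        twice = sf.normalize_to_max(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_all_zero_curve_rejected(self):
        curve = depth_curve([0, 1, 2, 3, 4], [0, 0, 0, 0, 0])
        with pytest.raises(DegenerateInputError):
            sf.normalize_to_max(curve)

    def test_pdd_on_grid_lookup(self):
        curve = depth_curve([0, 15, 50, 100, 200], [50, 100, 90, 66.5, 40])
        curve = sf.normalize_to_max(curve)
        assert sf.pdd_at_depth(curve, 100.0) == pytest.approx(66.5)

    def test_pdd_midpoint_interpolation(self):
        curve = depth_curve([0, 15, 95, 105, 200], [50, 100, 68, 66, 40])
        curve = sf.normalize_to_max(curve)
        assert sf.pdd_at_depth(curve, 100.0) == pytest.approx(67.0)

    def test_pdd_outside_range_raises(self):
        curve = sf.normalize_to_max(depth_curve([0, 15, 50, 100, 200], [50, 100, 90, 66, 40]))
        with pytest.raises(RangeError):
            sf.pdd_at_depth(curve, 250.0)

    def test_pdd_matches_biexponential_closed_form(self, beam):
        """PDD(100 mm) of the synthetic curve equals its analytic value."""
        curve = sf.true_pdd(beam, 10.0)
        a, mu = beam.buildup_per_mm, beam.mu_per_mm

        def analytic(d):
            return -np.expm1(-a * d) * np.exp(-mu * d)

        expected = 100.0 * analytic(100.0) / analytic(beam.dmax_mm)
        assert sf.pdd_at_depth(curve, 100.0) == pytest.approx(expected, abs=0.05)

    def test_pdd_at_dmax_is_100_after_normalization(self, beam):
        curve = sf.normalize_to_max(sf.true_pdd(beam, 10.0))
        dmax = sf.find_dmax(curve)
        assert sf.pdd_at_depth(curve, dmax) == pytest.approx(100.0, abs=1e-3)


class TestFindDmax:
    def test_exact_sample_peak(self):
        curve = depth_curve([0, 5, 15, 25, 35], [40, 80, 100, 80, 60])
        assert sf.find_dmax(curve) == pytest.approx(15.0, abs=1e-9)

    def test_parabola_peak_recovered_off_grid(self):
        x = np.arange(0, 30.0)
        y = 100.0 - 0.2 * (x - 14.3) ** 2
        assert sf.find_dmax(depth_curve(x, y)) == pytest.approx(14.3, abs=0.01)

    def test_synthetic_pdd_recovers_generator_dmax(self, beam):
        curve = sf.true_pdd(beam, 10.0)
        assert sf.find_dmax(curve) == pytest.approx(beam.dmax_mm, abs=0.25)

    def test_plateau_returns_midpoint(self):
        curve = depth_curve([0, 10, 20, 30, 40], [50, 100, 100, 100, 60])
        assert sf.find_dmax(curve) == pytest.approx(20.0)

    def test_boundary_maximum_warns_and_returns_boundary(self):
        curve = depth_curve([0, 10, 20, 30, 40], [100, 90, 80, 70, 60])
        with pytest.warns(UserWarning, match="boundary"):
            assert sf.find_dmax(curve) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# lateral metrics


def brute_force_crossing(beam, field_cm, depth_mm, level_fraction, side=+1):
    """Independent oracle: 0.001 mm grid search on the analytic profile."""
    from sfdose.synthetic_data import _profile_values

    w = beam.projected_width_mm(field_cm, depth_mm, "crossline")
    x = np.arange(0.0, 1.5 * w, 0.001) * side
    x = np.sort(x)
    values = _profile_values(beam, field_cm, depth_mm, x)
    central = _profile_values(beam, field_cm, depth_mm, np.array([0.0]))[0]
    target = level_fraction * central
    idx = np.nonzero(np.diff(np.sign(values - target)))[0]
    assert len(idx) == 1
    return 0.5 * (x[idx[0]] + x[idx[0] + 1])


class TestLateralMetrics:
    def test_trapezoid_symmetric_50_crossings(self):
        x = np.array([-15, -10.0, -5, 0, 5, 10.0, 15])
        y = np.array([0, 50.0, 100, 100, 100, 50.0, 0])
        profile = lateral_curve(x, y, normalized="cax100")
        left, right = sf.level_crossings(profile, 50.0)
        assert (left, right) == pytest.approx((-10.0, 10.0))
        assert sf.fwhm(profile) == pytest.approx(20.0)

    def test_linear_interpolation_between_samples(self):
        x = np.array([-6, -5, -4, 0, 4.0, 5.0, 6])
        y = np.array([10, 40, 60, 100, 60.0, 40.0, 10])
        profile = lateral_curve(x, y, normalized="cax100")
        _, right = sf.level_crossings(profile, 50.0)
        assert right == pytest.approx(4.5)

    def test_erf_crossing_matches_dense_grid_oracle(self, symmetric_beam, erf_profile):
        for level in (20.0, 50.0, 80.0):
            left, right = sf.level_crossings(erf_profile, level)
            oracle = brute_force_crossing(symmetric_beam, 3.0, 100.0, level / 100.0)
            assert right == pytest.approx(oracle, abs=0.01)
            assert left == pytest.approx(-oracle, abs=0.01)

    def test_fwhm_of_2cm_field_equals_nominal_width(self, symmetric_beam):
        profile = sf.normalize_to_cax(sf.true_profile(symmetric_beam, 2.0, 0.0))
        assert sf.fwhm(profile) == pytest.approx(20.0, abs=0.05)

    def test_penumbra_matches_erf_closed_form(self, erf_profile, symmetric_beam):
        """An isolated erf edge falls 80->20 over sigma*(z80-z20) = 1.683 sigma."""
        z_span = 1.6832424  # z(0.8) - z(0.2) of the standard normal
        expected = symmetric_beam.sigma_mm * z_span
        left, right = sf.penumbra_widths(erf_profile)
        assert left == pytest.approx(expected, rel=0.01)
        assert right == pytest.approx(expected, rel=0.01)

    def test_piecewise_linear_edge_penumbra(self):
        x = np.array([-8, -6.5, -3.5, 0, 3.5, 6.5, 8.0])
        y = np.array([0, 20.0, 80.0, 100, 80.0, 20.0, 0])
        profile = lateral_curve(x, y, normalized="cax100")
        left, right = sf.penumbra_widths(profile)
        assert left == pytest.approx(3.0)
        assert right == pytest.approx(3.0)

    def test_volume_averaging_broadens_penumbra(self, symmetric_beam):
        profile = sf.true_profile(symmetric_beam, 2.0, 100.0)
        sharp = sf.normalize_to_cax(profile)
        blurred = sf.normalize_to_cax(_convolve_with_aperture(profile, 3.6))
        assert np.mean(sf.penumbra_widths(blurred)) > np.mean(sf.penumbra_widths(sharp))

    def test_broadening_monotone_in_aperture_width(self, symmetric_beam):
        profile = sf.true_profile(symmetric_beam, 3.0, 100.0)
        widths = []
        for aperture in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0):
            blurred = sf.normalize_to_cax(_convolve_with_aperture(profile, aperture))
            widths.append(np.mean(sf.penumbra_widths(blurred)))
        assert np.all(np.diff(widths) >= 0)

    def test_monotone_profile_rejected_with_side(self):
        x = np.linspace(-10, 10, 11)
        y = np.linspace(0, 100, 11)
        profile = lateral_curve(x, y, normalized="cax100")
        with pytest.raises(ShapeError, match="side"):
            sf.level_crossings(profile, 50.0)

    @given(
        scale=st.floats(min_value=0.1, max_value=10.0),
        shift=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_widths_invariant_under_rescaling_and_translation(self, scale, shift):
        """FWHM/penumbra depend only on shape, not units or alignment."""
        beam = sf.BeamModel(width_bias_cross_mm=0.0, width_bias_in_mm=0.0)
        base = sf.true_profile(beam, 3.0, 100.0)
        moved = sf.ScanCurve(
            axis=base.axis,
            positions=base.positions + shift,
            values=base.values * scale,
            detector_id=base.detector_id,
            field_x_cm=base.field_x_cm,
            field_y_cm=base.field_y_cm,
            ssd_cm=base.ssd_cm,
            scan_depth_mm=base.scan_depth_mm,
        )
        reference = sf.normalize_to_cax(base)
        transformed = sf.normalize_to_cax(sf.recenter(moved))
        assert sf.fwhm(transformed) == pytest.approx(sf.fwhm(reference), abs=1e-6)
        np.testing.assert_allclose(
            sf.penumbra_widths(transformed), sf.penumbra_widths(reference), atol=1e-6
        )


class TestRecenter:
    def test_symmetric_profile_unchanged(self, erf_profile):
        out = sf.recenter(erf_profile)
        np.testing.assert_allclose(out.positions, erf_profile.positions, atol=1e-9)

    def test_shifted_profile_restored(self, symmetric_beam):
        base = sf.true_profile(symmetric_beam, 3.0, 100.0)
        shifted = sf.ScanCurve(
            axis=base.axis,
            positions=base.positions + 2.0,
            values=base.values,
            detector_id=base.detector_id,
            field_x_cm=base.field_x_cm,
            field_y_cm=base.field_y_cm,
            scan_depth_mm=base.scan_depth_mm,
        )
        restored = sf.recenter(shifted)
        np.testing.assert_allclose(restored.positions, base.positions, atol=1e-9)

    def test_idempotent(self, erf_profile):
        once = sf.recenter(erf_profile)
        twice = sf.recenter(once)
        np.testing.assert_allclose(twice.positions, once.positions, atol=1e-12)
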