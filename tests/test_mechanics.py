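"""Kinematics, stress computation, fitting and the in-vivo stretch criterion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acamech import (
    MMHG_TO_KPA,
    ExponentialFit,
    MyographRecording,
    ReferenceGeometry,
    axial_stretch,
    circumferential_stretch,
    deformed_inner_radius,
    estimate_in_vivo_stretch,
    fit_exponential,
    process_recording,
    radii_from_perimeters,
    stiffness_at_pressure,
    tangent_stiffness,
    wall_stresses,
)
from acamech.errors import (
    DegenerateWallError,
    ExtrapolationError,
    FitError,
    InfeasibleGeometryError,
    InvalidGeometryError,
    NormalizationAnchorError,
)
from acamech.mechanics import StressStretchCurve


class TestReferenceGeometry:
    def test_radii_from_perimeters(self):
        g = radii_from_perimeters(2 * math.pi, math.pi, 10.0)
        assert g.Ro == pytest.approx(1.0, abs=1e-12)
        assert g.Ri == pytest.approx(0.5, abs=1e-12)
        assert g.L == 10.0

    def test_radii_high_precision(self):
        g = radii_from_perimeters(8.1681, 6.2832, 12.0)
        assert g.Ro == pytest.approx(8.1681 / (2 * math.pi), rel=1e-14)
        assert g.Ri == pytest.approx(6.2832 / (2 * math.pi), rel=1e-14)
        assert round(g.Ro, 4) == 1.3000
        assert round(g.Ri, 4) == 1.0000

    @pytest.mark.parametrize(
        "outer,inner,L",
        [(5.0, 6.0, 10.0), (-1.0, 0.5, 10.0), (6.0, 0.0, 10.0), (6.0, 5.0, 0.0)],
    )
    def test_invalid_geometry_rejected(self, outer, inner, L):
        with pytest.raises(InvalidGeometryError):
            radii_from_perimeters(outer, inner, L)


class TestKinematics:
    def test_axial_stretch(self):
        assert axial_stretch(10.0, 10.0) == 1.0
        assert axial_stretch(13.2, 12.0) == pytest.approx(1.10)
        with pytest.raises(ValueError):
            axial_stretch(0.0, 10.0)

    def test_identity_deformation(self, geom):
        ri = deformed_inner_radius(geom.Ro, geom, 1.0)
        assert ri == pytest.approx(geom.Ri, rel=1e-12)
        assert circumferential_stretch(geom.Ro, ri, geom) == pytest.approx(1.0)

    def test_inner_radius_conserves_wall_volume(self, geom):
        ri = deformed_inner_radius(1.25, geom, 1.10)
        assert ri == pytest.approx(0.9671, abs=5e-5)
        deformed = math.pi * (1.25**2 - ri**2) * 1.10
        assert deformed == pytest.approx(geom.wall_area, rel=1e-12)

    def test_infeasible_radius_raises(self, geom):
        with pytest.raises(InfeasibleGeometryError):
            deformed_inner_radius(0.5, geom, 1.0)

    def test_circumferential_stretch_value(self, geom):
        ri = deformed_inner_radius(1.25, geom, 1.10)
        lam = circumferential_stretch(1.25, ri, geom)
        assert lam == pytest.approx((1.25 + ri) / 2.30, rel=1e-14)
        assert lam == pytest.approx(0.9640, abs=1e-4)
        with pytest.raises(ValueError):
            circumferential_stretch(1.0, 1.0, geom)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        Ro=st.floats(0.5, 3.0),
        thickness=st.floats(0.05, 0.4),
        lam_z=st.floats(0.8, 1.5),
        bulge=st.floats(1.0, 1.6),
    )
    def test_volume_conservation_property(self, Ro, thickness, lam_z, bulge):
        """Incompressibility holds for any feasible deformed outer radius."""
        geom = ReferenceGeometry(Ro=Ro, Ri=Ro - thickness, L=10.0)
        ro = bulge * math.sqrt((Ro**2 - geom.Ri**2) / lam_z) + 1e-6
        ri = deformed_inner_radius(ro, geom, lam_z)
        rel = abs(math.pi * (ro**2 - ri**2) * lam_z - geom.wall_area) / geom.wall_area
        assert rel < 1e-9


class TestWallStresses:
    def test_zero_load_zero_stress(self):
        assert wall_stresses(0.0, 1.25, 0.97, 0.0) == (0.0, 0.0)

    def test_against_independent_recomputation(self):
        P, ri, ro, fT = 80.0, 0.9671, 1.25, 20.0
        s_t, s_z = wall_stresses(P, ro, ri, fT)
        p_kpa = P * MMHG_TO_KPA
        assert s_t == pytest.approx(p_kpa * ri / (ro - ri), rel=1e-14)
        assert s_z == pytest.approx(
            (fT + p_kpa * math.pi * ri**2) / (math.pi * (ro - ri) * (ri + ro)),
            rel=1e-14,
        )
        # magnitudes in the physiological range
        assert s_t == pytest.approx(36.4, abs=0.1)
        assert s_z == pytest.approx(26.0, abs=0.1)

    def test_degenerate_wall(self):
        with pytest.raises(DegenerateWallError):
            wall_stresses(80.0, 1.0, 1.0, 0.0)

    def test_monotonicity_in_loads(self):
        s_t = [wall_stresses(P, 1.25, 0.97, 10.0)[0] for P in (20, 40, 60, 80)]
        assert np.all(np.diff(s_t) > 0)
        s_z = [wall_stresses(40.0, 1.25, 0.97, fT)[1] for fT in (0, 10, 20)]
        assert np.all(np.diff(s_z) > 0)

    def test_unit_conversion_guard(self):
        """Feeding pressure already in kPa (skipping the conversion) must not
        reproduce the mmHg-based stress: guards against unit mix-ups."""
        s_mmhg, _ = wall_stresses(80.0, 1.25, 0.9671, 0.0)
        s_wrong, _ = wall_stresses(80.0 * MMHG_TO_KPA, 1.25, 0.9671, 0.0)
        assert not math.isclose(s_mmhg, s_wrong, rel_tol=0.5)


class TestProcessRecording:
    def test_single_zero_pressure_point(self, geom):
        rec = MyographRecording([0.0], [2.5], [5.0], stretched_length=13.2)
        curve = process_recording(rec, geom)
        assert curve.normalized_lambda_theta[0] == 1.0

    def test_missing_anchor_raises(self, geom):
        rec = MyographRecording(
            [10.0, 20.0], [2.5, 2.6], [5.0, 5.0], stretched_length=13.2
        )
        with pytest.raises(NormalizationAnchorError):
            process_recording(rec, geom)

    def test_anchor_tolerance_configurable(self, geom):
        rec = MyographRecording(
            [0.3, 20.0], [2.5, 2.6], [5.0, 5.0], stretched_length=13.2
        )
        curve = process_recording(rec, geom)  # 0.3 within default +/-0.5
        assert curve.normalized_lambda_theta[0] == 1.0
        with pytest.raises(NormalizationAnchorError):
            process_recording(rec, geom, zero_pressure_tol=0.1)


class TestExponentialFit:
    @staticmethod
    def _curve_from_law(a, b, lam):
        lam = np.asarray(lam)
        sigma = a * (np.exp(b * (lam - 1.0)) - 1.0)
        return StressStretchCurve(
            normalized_lambda_theta=lam,
            sigma_theta=sigma,
            sigma_z=np.zeros_like(lam),
            pressure=np.linspace(0, 80, lam.size),
        )

    def test_exact_recovery(self):
        lam = np.arange(1.00, 1.101, 0.01)
        fit = fit_exponential(self._curve_from_law(5.0, 12.0, lam))
        assert fit.a == pytest.approx(5.0, rel=1e-6)
        assert fit.b == pytest.approx(12.0, rel=1e-6)
        assert fit.rmse < 1e-8

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(FitError):
            fit_exponential(self._curve_from_law(5.0, 12.0, [1.0, 1.05]))
        with pytest.raises(FitError):
            fit_exponential(self._curve_from_law(5.0, 12.0, [1.02, 1.02, 1.02]))

    def test_near_linear_data_gives_small_b_not_error(self):
        lam = np.arange(1.00, 1.101, 0.01)
        curve = self._curve_from_law(5.0, 12.0, lam)
        curve.sigma_theta = 10.0 * (lam - 1.0)  # linear response
        fit = fit_exponential(curve)
        assert fit.b < 1.0
        assert fit.rmse < 0.05

    def test_noisy_recovery_median_within_15pct(self):
        lam = np.arange(1.00, 1.101, 0.01)
        errs = []
        rng = np.random.default_rng(2024)
        for _ in range(100):
            curve = self._curve_from_law(5.0, 12.0, lam)
            curve.sigma_theta = curve.sigma_theta + rng.normal(0, 0.5, lam.size)
            fit = fit_exponential(curve)
            errs.append(abs(fit.b - 12.0) / 12.0)
        assert np.median(errs) < 0.15


class TestTangentStiffness:
    def test_analytic_values(self):
        fit = ExponentialFit(a=5.0, b=12.0, rmse=0.0)
        assert tangent_stiffness(fit, 1.0) == pytest.approx(60.0)
        assert tangent_stiffness(fit, 1.05) == pytest.approx(
            5 * 12 * math.exp(0.6), rel=1e-12
        )

    def test_matches_finite_difference_of_fitted_form(self):
        fit = ExponentialFit(a=5.0, b=12.0, rmse=0.0)
        h = 1e-7
        for lam in (1.0, 1.03, 1.08):
            sigma = lambda x: fit.a * (math.exp(fit.b * (x - 1.0)) - 1.0)
            fd = (sigma(lam + h) - sigma(lam - h)) / (2 * h)
            assert tangent_stiffness(fit, lam) == pytest.approx(fd, rel=1e-6)

    def test_strictly_increasing_for_positive_b(self):
        fit = ExponentialFit(a=3.0, b=8.0, rmse=0.0)
        lams = np.linspace(0.95, 1.15, 50)
        stiff = [tangent_stiffness(fit, x) for x in lams]
        assert np.all(np.diff(stiff) > 0)


class TestStiffnessAtPressure:
    def _curve(self):
        lam = np.array([1.0, 1.02, 1.05, 1.08])
        return StressStretchCurve(
            normalized_lambda_theta=lam,
            sigma_theta=5 * (np.exp(12 * (lam - 1)) - 1),
            sigma_z=np.zeros(4),
            pressure=np.array([0.0, 20.0, 50.0, 80.0]),
        )

    def test_grid_point_exact(self):
        fit = ExponentialFit(a=5.0, b=12.0, rmse=0.0)
        assert stiffness_at_pressure(self._curve(), fit, 50.0) == pytest.approx(
            tangent_stiffness(fit, 1.05), rel=1e-12
        )

    def test_interpolated_point(self):
        fit = ExponentialFit(a=5.0, b=12.0, rmse=0.0)
        lam_35 = 1.02 + (1.05 - 1.02) * 0.5
        assert stiffness_at_pressure(self._curve(), fit, 35.0) == pytest.approx(
            tangent_stiffness(fit, lam_35), rel=1e-12
        )

    def test_out_of_range(self):
        fit = ExponentialFit(a=5.0, b=12.0, rmse=0.0)
        with pytest.raises(ExtrapolationError):
            stiffness_at_pressure(self._curve(), fit, 120.0)


class TestInVivoStretch:
    @staticmethod
    def _rec(force):
        n = len(force)
        return MyographRecording(
            np.linspace(0, 80, n), np.full(n, 2.5), np.asarray(force, float), 13.2
        )

    def test_single_candidate(self):
        assert estimate_in_vivo_stretch([(1.1, self._rec([5, 6, 7]))]) == 1.1

    def test_minimal_variance_selected(self):
        recs = [
            (1.05, self._rec([5.0, 8.0, 12.0])),
            (1.12, self._rec([7.0, 7.1, 7.0])),
            (1.20, self._rec([6.0, 10.0, 15.0])),
        ]
        assert estimate_in_vivo_stretch(recs) == 1.12

    def test_tie_broken_toward_smaller_stretch(self):
        recs = [
            (1.20, self._rec([5.0, 5.0, 5.0])),
            (1.05, self._rec([9.0, 9.0, 9.0])),
        ]
        assert estimate_in_vivo_stretch(recs) == 1.05

    def test_empty_candidates(self):
        with pytest.raises(ValueError):
            estimate_in_vivo_stretch([])
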