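"""Elastic-foundation contact: equilibrium, oracle agreement, calibration."""

import numpy as np
import pytest
from scipy.integrate import quad

from hrasim.contact import (
    FoundationModel,
    calibrate_stiffness,
    closed_form_polar,
    contact_metrics,
    discretize_bearing,
    physical_foundation,
    solve_contact,
)
from hrasim.geometry import ImplantSpec, spherical_cap_area
from hrasim.kinematics import CupPose, FemoralPose
from hrasim.loads import LOAD_CASES


@pytest.fixture(scope="module")
def hemi_implant():
    return ImplantSpec(cup_coverage_arc=180.0)


@pytest.fixture(scope="module")
def foundation():
    return FoundationModel(stiffness=500.0, clearance=0.08, source="physical")


class TestDiscretization:
    def test_hemisphere_area_closed_form(self, hemi_implant):
        b = discretize_bearing(hemi_implant, CupPose(0.0, 0.0), 20_000)
        assert b.areas.sum() == pytest.approx(
            2 * np.pi * hemi_implant.cup_bearing_radius**2, rel=0.005
        )

    def test_area_converges_with_n(self, implant):
        a1 = discretize_bearing(implant, CupPose(40.0, 15.0), 20_000).areas.sum()
        a2 = discretize_bearing(implant, CupPose(40.0, 15.0), 40_000).areas.sum()
        assert abs(a1 - a2) / a1 < 0.001

    def test_partial_cap_area(self, implant):
        b = discretize_bearing(implant, CupPose(40.0, 15.0), 5_000)
        expected = spherical_cap_area(
            implant.cup_bearing_radius, implant.cup_coverage_arc / 2.0
        )
        assert b.areas.sum() == pytest.approx(expected, rel=0.005)

    def test_normals_point_inward(self, implant):
        b = discretize_bearing(implant, CupPose(40.0, 15.0), 1_000)
        assert np.allclose(np.linalg.norm(b.directions, axis=1), 1.0, atol=1e-12)
        assert np.allclose(b.normals, -b.directions)

    def test_too_few_elements_rejected(self, implant):
        with pytest.raises(ValueError):
            discretize_bearing(implant, CupPose(40.0, 15.0), 50)


class TestSolver:
    def test_zero_load(self, hemi_implant, foundation):
        b = discretize_bearing(hemi_implant, CupPose(0.0, 0.0), 2_000)
        sol = solve_contact(b, foundation, np.zeros(3))
        assert np.allclose(sol.displacement, 0.0)
        assert sol.peak_pressure == 0.0 and sol.contact_area == 0.0
        assert sol.patch_centroid_octant == "none"

    def test_polar_load_matches_closed_form(self, hemi_implant, foundation):
        b = discretize_bearing(hemi_implant, CupPose(0.0, 0.0), 20_000)
        F = 1500.0
        sol = solve_contact(b, foundation, np.array([0.0, 0.0, F]))
        peak_cf, half_cf = closed_form_polar(
            foundation, hemi_implant.cup_bearing_radius, F
        )
        assert sol.peak_pressure == pytest.approx(peak_cf, rel=0.01)
        area_cf = spherical_cap_area(hemi_implant.cup_bearing_radius, half_cf)
        assert sol.contact_area == pytest.approx(area_cf, rel=0.02)

    def test_equilibrium_residual_every_converged_solve(self, engine):
        for load in LOAD_CASES.values():
            for version in (30.0, 0.0, -30.0):
                sol = engine.solve_one_contact(version, (50.0, 15.0), load)
                assert sol.equilibrium_residual <= 1e-6 * load.magnitude

    def test_load_outside_cap_raises(self, hemi_implant, foundation):
        b = discretize_bearing(
            ImplantSpec(cup_coverage_arc=120.0), CupPose(0.0, 0.0), 2_000
        )
        with pytest.raises(RuntimeError):
            solve_contact(b, foundation, np.array([0.0, 0.0, -2000.0]))

    def test_mesh_refinement_stability(self, engine):
        """Peak pressure moves < 2% when the element count doubles."""
        cap = engine.head_cap(-30.0, 90.0)
        peaks = []
        for n in (20_000, 40_000):
            b = discretize_bearing(engine.config.implant, CupPose(50.0, 15.0), n)
            sol = solve_contact(
                b, engine.foundation, LOAD_CASES["flex90"].vector, head_cap=cap
            )
            peaks.append(sol.peak_pressure)
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 0.02

    def test_articular_cap_truncation_raises_pressure(self, engine):
        """Retroversion at the sitting load truncates the patch at the
        head-component rim: smaller area, higher peak."""
        load = LOAD_CASES["flex90"]
        neutral = engine.solve_one_contact(0.0, (50.0, 15.0), load)
        retro = engine.solve_one_contact(-30.0, (50.0, 15.0), load)
        assert retro.peak_pressure > neutral.peak_pressure
        assert retro.contact_area < neutral.contact_area


class TestClosedForm:
    def test_zero_load_limit(self, foundation):
        assert closed_form_polar(foundation, 27.08, 0.0) == (0.0, 0.0)

    def test_quadrature_cross_check(self, foundation):
        """Exact antiderivative vs adaptive numerical quadrature."""
        R, F = 27.08, 1800.0
        peak, half = closed_form_polar(foundation, R, F)
        k, c = foundation.stiffness, foundation.clearance
        u = c + peak / k

        def integrand(theta):
            over = u * np.cos(theta) - c
            return (
                k * max(over, 0.0) * np.cos(theta) * 2 * np.pi * R**2 * np.sin(theta)
            )

        F_quad, _ = quad(integrand, 0.0, np.pi / 2, epsabs=1e-12, epsrel=1e-12)
        assert abs(F_quad - F) / F < 1e-8

    def test_monotone_in_load_and_stiffness(self):
        c = 0.08
        peaks_F = [
            closed_form_polar(FoundationModel(500.0, c), 27.08, F)[0]
            for F in (200.0, 800.0, 1800.0, 3000.0)
        ]
        assert np.all(np.diff(peaks_F) > 0)
        peaks_k = [
            closed_form_polar(FoundationModel(k, c), 27.08, 1500.0)[0]
            for k in (100.0, 300.0, 900.0, 2700.0)
        ]
        assert np.all(np.diff(peaks_k) > 0)


class TestCalibration:
    def test_fixed_point(self, implant):
        """Calibrating to the model's own peak returns the same stiffness."""
        b = discretize_bearing(implant, CupPose(40.0, 15.0), 5_000)
        base = FoundationModel(420.0, implant.radial_clearance_mm)
        load = LOAD_CASES["flex0"].vector

        def ref(fm):
            return solve_contact(b, fm, load).peak_pressure

        target = ref(base)
        calibrated = calibrate_stiffness(ref, target, clearance=base.clearance)
        assert calibrated.stiffness == pytest.approx(base.stiffness, rel=1e-4)
        assert calibrated.source == "calibrated"
        assert abs(ref(calibrated) - target) / target < 1e-3

    def test_unreachable_target_rejected(self, implant):
        b = discretize_bearing(implant, CupPose(40.0, 15.0), 1_000)

        def ref(fm):
            return solve_contact(b, fm, LOAD_CASES["flex0"].vector).peak_pressure

        with pytest.raises(ValueError):
            calibrate_stiffness(ref, 1e9, clearance=implant.radial_clearance_mm)

    def test_physical_mode_stiffness(self, implant):
        fm = physical_foundation(implant, support_thickness=5.0)
        assert fm.stiffness == pytest.approx(200.0)  # 1 GPa / 5 mm
        assert fm.source == "physical"


class TestMetrics:
    def test_stance_patch_superior(self, engine):
        sol = engine.solve_one_contact(0.0, (40.0, 15.0), LOAD_CASES["flex0"])
        peak, area, octant = contact_metrics(sol)
        assert peak > 0 and area > 0
        assert "superior" in octant or octant.startswith("supero")

    def test_retroverted_sitting_patch_anterior_on_femur(self, engine):
        load = LOAD_CASES["flex90"]
        sol = engine.solve_one_contact(-30.0, (50.0, 15.0), load)
        rot = FemoralPose(-30.0, load.flexion).rotation(engine.config.anatomy)
        _, _, octant = contact_metrics(sol, depose_rotation=rot)
        assert octant == "anterior" or octant.startswith("antero")

    def test_zero_solution_labelled_none(self, hemi_implant, foundation):
        b = discretize_bearing(hemi_implant, CupPose(0.0, 0.0), 1_000)
        sol = solve_contact(b, foundation, np.zeros(3))
        assert contact_metrics(sol) == (0.0, 0.0, "none")
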