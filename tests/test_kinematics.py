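"""Sphere fitting and rigid pose operations about the center of rotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrasim.frame import cup_pole_axis, octant_label, rot_x, rot_z
from hrasim.geometry import LabeledMesh
from hrasim.kinematics import (
    CupPose,
    apply_cup_pose,
    apply_femoral_version,
    fit_sphere,
    flex,
)


def sphere_points(rng, n, center, radius, hemisphere=False):
    z = rng.uniform(0.0 if hemisphere else -1.0, 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - z**2)
    pts = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    return center + radius * pts


class TestFitSphere:
    def test_exact_recovery(self, rng):
        pts = sphere_points(rng, 500, np.zeros(3), 27.0)
        center, radius, rms = fit_sphere(pts)
        assert np.allclose(center, 0.0, atol=1e-9)
        assert radius == pytest.approx(27.0, abs=1e-9)
        assert rms < 1e-9

    def test_noisy_recovery(self, rng):
        """Monte-Carlo: 0.1 mm isotropic noise leaves sub-0.05 mm errors."""
        for _ in range(5):
            true_c = rng.uniform(-5, 5, 3)
            pts = sphere_points(rng, 2000, true_c, 27.0)
            pts = pts + rng.normal(0.0, 0.1, pts.shape)
            center, radius, _ = fit_sphere(pts)
            assert np.linalg.norm(center - true_c) < 0.05
            assert abs(radius - 27.0) < 0.05

    def test_hemisphere_coverage(self, rng):
        pts = sphere_points(rng, 2000, np.zeros(3), 27.0, hemisphere=True)
        _, radius, _ = fit_sphere(pts)
        assert radius == pytest.approx(27.0, abs=0.1)

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ValueError):
            fit_sphere(np.zeros((3, 3)))
        coplanar = np.column_stack(
            [rng.uniform(-1, 1, 50), rng.uniform(-1, 1, 50), np.zeros(50)]
        )
        with pytest.raises(ValueError):
            fit_sphere(coplanar)

    def test_rigid_transform_equivariance(self, rng):
        pts = sphere_points(rng, 300, np.array([1.0, 2.0, 3.0]), 10.0)
        R = rot_z(33.0) @ rot_x(12.0)
        t = np.array([4.0, -5.0, 6.0])
        c0, r0, _ = fit_sphere(pts)
        c1, r1, _ = fit_sphere(pts @ R.T + t)
        assert np.allclose(c1, R @ c0 + t, atol=1e-8)
        assert r1 == pytest.approx(r0, abs=1e-9)


def small_mesh(rng):
    v = rng.uniform(-10, 10, (8, 3))
    f = np.array([[0, 1, 2], [3, 4, 5], [5, 6, 7]])
    return LabeledMesh(v, f, np.array(["neck"] * 3))


class TestPoseOperations:
    def test_zero_version_identity(self, rng):
        m = small_mesh(rng)
        assert np.allclose(apply_femoral_version(m, 0.0).vertices, m.vertices)

    def test_version_roundtrip(self, rng):
        m = small_mesh(rng)
        back = apply_femoral_version(apply_femoral_version(m, 30.0), -30.0)
        assert np.allclose(back.vertices, m.vertices, atol=1e-9)

    def test_cor_invariant_under_version_and_flexion(self):
        m = LabeledMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]), np.array(["neck"]))
        for op in (lambda mm: apply_femoral_version(mm, 17.0), lambda mm: flex(mm, 45.0)):
            assert np.allclose(op(m).vertices, 0.0, atol=0.0)

    def test_flexion_composition(self, rng):
        m = small_mesh(rng)
        twice = flex(flex(m, 90.0), 90.0)
        with pytest.warns(UserWarning):
            once = flex(m, 180.0)
        assert np.allclose(twice.vertices, once.vertices, atol=1e-9)

    def test_flexion_moves_shaft_tip_anteriorly(self, femur):
        tip_idx = int(np.argmin(femur.vertices[:, 2]))  # most distal vertex
        ys = [
            flex(femur, a).vertices[tip_idx, 1] for a in (0.0, 15.0, 30.0, 60.0, 90.0)
        ]
        assert np.all(np.diff(ys) > 0)

    @settings(deadline=None, max_examples=25)
    @given(
        angle=st.floats(-180, 180, allow_nan=False),
        which=st.sampled_from(["version", "flex"]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_pose_operations_are_isometries(self, angle, which, seed):
        rng = np.random.default_rng(seed)
        m = small_mesh(rng)
        if which == "version":
            out = apply_femoral_version(m, angle)
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = flex(m, angle)
        d0 = np.linalg.norm(m.vertices[:, None] - m.vertices[None, :], axis=-1)
        d1 = np.linalg.norm(out.vertices[:, None] - out.vertices[None, :], axis=-1)
        assert np.allclose(d0, d1, rtol=1e-9, atol=1e-9)


class TestCupPose:
    def test_neutral_pose_pole_is_axial(self):
        assert np.allclose(cup_pole_axis(0.0, 0.0), [0.0, 0.0, 1.0], atol=1e-12)

    def test_pole_matches_closed_form(self):
        inc, ver = np.deg2rad(40.0), np.deg2rad(15.0)
        expected = np.array(
            [np.sin(inc) * np.cos(ver), -np.sin(ver), np.cos(inc) * np.cos(ver)]
        )
        assert np.allclose(cup_pole_axis(40.0, 15.0), expected, atol=1e-12)

    def test_pole_separation_great_circle(self):
        p1 = cup_pole_axis(40.0, 15.0)
        p2 = cup_pole_axis(50.0, 25.0)
        got = np.rad2deg(np.arccos(np.clip(p1 @ p2, -1, 1)))
        # spherical law of cosines on the (inclination, version) angles
        i1, v1, i2, v2 = map(np.deg2rad, (40.0, 15.0, 50.0, 25.0))
        cosang = np.sin(i1) * np.sin(i2) * np.cos(v1) * np.cos(v2) + np.sin(
            v1
        ) * np.sin(v2) + np.cos(i1) * np.cos(i2) * np.cos(v1) * np.cos(v2)
        assert got == pytest.approx(np.rad2deg(np.arccos(cosang)), abs=1e-9)

    def test_apply_cup_pose_carries_pole(self, cup):
        pose = CupPose(40.0, 15.0)
        posed = apply_cup_pose(cup, pose)
        # the apex vertex (originally at +Z * R) must map onto the pole axis
        apex = np.argmax(cup.vertices[:, 2])
        got = posed.vertices[apex] / np.linalg.norm(posed.vertices[apex])
        assert np.allclose(got, pose.pole, atol=1e-9)

    def test_invalid_angles_rejected(self):
        with pytest.raises(ValueError):
            CupPose(95.0, 10.0)
        with pytest.raises(ValueError):
            CupPose(40.0, -5.0)


def test_octant_labels():
    assert octant_label([0.0, 0.0, 1.0]) == "superior"
    assert octant_label([0.0, 1.0, -1.0]) == "anteroinferior"
    assert octant_label([1.0, 0.0, 1.0]) == "superomedial"
    assert octant_label([0.0, 0.0, 0.0]) == "none"
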