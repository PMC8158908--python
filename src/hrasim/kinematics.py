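"""Pose kinematics: COR sphere fit, cup pose, femoral version and flexion.

All pose operations are rigid rotations about axes through the center of
rotation (origin of the pelvic frame):

* femoral version -- rotation about the axial (Z) axis, positive =
  increasing anteversion;
* hip flexion -- rotation about the medial-lateral (X) axis, positive =
  distal shaft moves anteriorly (pure sagittal-plane flexion);
* cup pose -- rotation carrying the unposed pole (+Z) onto the radiographic
  inclination/version axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .frame import AngleConvention, cup_pole_axis, rot_axis, rot_x, rot_z
from .geometry import AnatomySpec, ImplantSpec, LabeledMesh, neck_axis_direction

__all__ = [
    "CupPose",
    "FemoralPose",
    "fit_sphere",
    "apply_femoral_version",
    "apply_cup_pose",
    "flex",
    "posed_head_cap_pole",
]


@dataclass(frozen=True)
class CupPose:
    """Acetabular component orientation (radiographic convention default)."""

    inclination: float = 40.0  # deg
    version: float = 15.0  # deg
    convention: AngleConvention = AngleConvention.RADIOGRAPHIC

    def __post_init__(self) -> None:
        if not 0 <= self.inclination < 90:
            raise ValueError("inclination must be in [0, 90)")
        if not 0 <= self.version < 90:
            raise ValueError("version must be in [0, 90)")

    @property
    def pole(self) -> np.ndarray:
        """Unit direction from COR to cup apex."""
        return cup_pole_axis(self.inclination, self.version, self.convention)


@dataclass(frozen=True)
class FemoralPose:
    """Femoral orientation state: absolute version target and flexion."""

    version: float = 20.0  # deg, anteversion positive (absolute)
    flexion: float = 0.0  # deg

    def rotation(self, anatomy: AnatomySpec) -> np.ndarray:
        """Rotation applied to the as-built femur (native version baked in)."""
        delta = self.version - anatomy.native_version
        return rot_x(self.flexion) @ rot_z(delta)


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares sphere through a point cloud.

    Linearised algebraic fit: ``|x|^2 = 2 c.x + (r^2 - |c|^2)`` solved by
    least squares, exact for noise-free spherical data.  Returns
    ``(center, radius, rms_residual)`` where the residual is the RMS of
    radial distance minus radius.

    Raises ``ValueError`` for fewer than 4 points or a degenerate
    (coplanar/collinear) configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need >= 4 three-dimensional points")
    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise ValueError("degenerate point set: sphere fit is rank-deficient")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("degenerate point set: negative squared radius")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def apply_femoral_version(mesh: LabeledMesh, delta_deg: float) -> LabeledMesh:
    """Rotate the femur about the axial axis through the COR.

    Positive ``delta_deg`` increases anteversion.  The COR (origin) is
    invariant.
    """
    return mesh.transformed(rot_z(delta_deg))


def flex(mesh: LabeledMesh, angle_deg: float) -> LabeledMesh:
    """Flex the femur about the medial-lateral axis through the COR.

    Positive angle moves the distal shaft anteriorly.  Angles outside
    [0, 90] are allowed for exploration but warned about.
    """
    if not 0 <= angle_deg <= 90:
        warnings.warn(
            f"flexion {angle_deg} deg outside the studied 0-90 deg range",
            stacklevel=2,
        )
    return mesh.transformed(rot_x(angle_deg))


def apply_cup_pose(mesh: LabeledMesh, pose: CupPose) -> LabeledMesh:
    """Orient an unposed cup (pole along +Z) to the given pose.

    The rotation is the minimal rotation carrying +Z onto the pose's pole
    axis; the cup center stays at the COR.
    """
    z = np.array([0.0, 0.0, 1.0])
    p = pose.pole
    c = float(np.clip(z @ p, -1.0, 1.0))
    if c > 1.0 - 1e-12:
        return mesh.transformed(np.eye(3))
    if c < -1.0 + 1e-12:
        return mesh.transformed(rot_axis(np.array([1.0, 0.0, 0.0]), 180.0))
    axis = np.cross(z, p)
    return mesh.transformed(rot_axis(axis, np.rad2deg(np.arccos(c))))


def posed_head_cap_pole(
    anatomy: AnatomySpec, pose: FemoralPose
) -> np.ndarray:
    """Unit direction of the femoral articular-cap pole after posing.

    The cap pole points from the COR into the cup, opposite the distal neck
    axis; version and flexion rotate it rigidly.
    """
    return pose.rotation(anatomy) @ (-neck_axis_direction(anatomy))
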