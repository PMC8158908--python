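"""Geometric impingement analysis: flexion sweep, onset angle, contact area.

The femur is flexed from 0 to 90 deg in the sagittal plane about the
medial-lateral axis through the COR; at each step the femoral neck/shaft
surface is tested for collision against the acetabular obstacle (component
rim region + peri-acetabular bone skirt).  The onset angle is the first
swept angle with contact; the impingement area is the femoral-neck surface
area penetrating the obstacle solid at a given flexion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .collision import detect_contact
from .frame import octant_label, rot_x
from .geometry import ImplantSpec, LabeledMesh
from .kinematics import CupPose

__all__ = [
    "NO_IMPINGEMENT",
    "ImpingementResult",
    "CupObstacleSolid",
    "HalfSpaceSolid",
    "onset_flexion",
    "impingement_area",
    "impingement_patch",
]

#: Sentinel onset for configurations that never collide within the sweep.
NO_IMPINGEMENT = float("inf")


@dataclass(frozen=True)
class CupObstacleSolid:
    """Point-membership model of the cup wall + bone skirt solid.

    A point penetrates the obstacle if it lies either

    * inside the cup wall: within the coverage cone of the pole and at a
      radial distance beyond the inner bearing surface, or
    * inside the bone-skirt slab: past the rim plane (deeper than the cup
      opening), within the skirt annulus, within the slab thickness.
    """

    implant: ImplantSpec
    pose: CupPose
    wall_thickness: float = 3.0  # mm, radial extent of the cup wall solid
    skirt_thickness: float = 3.0  # mm, slab depth behind the rim plane

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = self.pose.pole
        pts = np.asarray(points, dtype=float)
        r = np.linalg.norm(pts, axis=1)
        along = pts @ p
        half = np.deg2rad(self.implant.cup_coverage_arc / 2.0)
        Rb = self.implant.cup_bearing_radius
        with np.errstate(invalid="ignore", divide="ignore"):
            polar = np.arccos(np.clip(along / np.maximum(r, 1e-12), -1.0, 1.0))
        in_wall = (polar <= half) & (r > Rb) & (r <= Rb + self.wall_thickness)
        rim_t = Rb * np.cos(half)
        rim_r = Rb * np.sin(half)
        rho = np.sqrt(np.maximum(r**2 - along**2, 0.0))
        in_skirt = (
            (along >= rim_t)
            & (along <= rim_t + self.skirt_thickness)
            & (rho >= rim_r)
            & (rho <= rim_r + self.implant.skirt_width)
        )
        return in_wall | in_skirt


@dataclass(frozen=True)
class HalfSpaceSolid:
    """Half space {x : (x - origin) . normal <= 0}; analytic test oracle."""

    normal: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) @ n <= 0.0


@dataclass
class ImpingementResult:
    """Outcome of one flexion sweep for a fixed femoral version / cup pose."""

    onset_flexion: float  # deg, or NO_IMPINGEMENT
    area_by_flexion: dict[float, float] = field(default_factory=dict)
    patch_faces: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    patch_location: str = "none"

    @property
    def impinged(self) -> bool:
        return np.isfinite(self.onset_flexion)


def onset_flexion(
    femur: LabeledMesh,
    obstacle_mesh: LabeledMesh,
    *,
    step: float = 1.0,
    max_angle: float = 90.0,
    tolerance: float = 0.0,
) -> float:
    """First swept flexion angle (deg) with neck/shaft-vs-obstacle contact.

    ``femur`` must already carry its version (COR at origin); the obstacle
    mesh must already be posed.  Only ``neck``/``shaft`` faces of the femur
    are tested (the bearing surfaces articulate by design and are excluded).
    Returns ``NO_IMPINGEMENT`` if no contact occurs up to ``max_angle``.
    Contact already present at 0 deg returns 0 with a warning.
    """
    if step <= 0:
        raise ValueError("sweep step must be positive")
    if len(obstacle_mesh.faces) == 0:
        return NO_IMPINGEMENT  # nothing to collide with
    mask_f = femur.label_mask("neck", "shaft")
    angles = np.arange(0.0, max_angle + 0.5 * step, step)
    for angle in angles:
        posed = femur.transformed(rot_x(angle))
        contacting, _ = detect_contact(
            posed, obstacle_mesh, tolerance, mask_a=mask_f, find_all=False
        )
        if contacting:
            if angle == 0.0:
                warnings.warn(
                    "impingement already present at 0 deg flexion; "
                    "the reference models start impingement-free",
                    stacklevel=2,
                )
            return float(angle)
    return NO_IMPINGEMENT


def impingement_patch(
    femur: LabeledMesh,
    obstacle,
    flexion: float,
    *,
    version_rotation: np.ndarray | None = None,
    neck_axis: np.ndarray | None = None,
) -> tuple[float, np.ndarray, str]:
    """Penetrating femoral-neck area (mm^2), face indices, and octant label.

    A neck/shaft face penetrates if its centroid lies inside the obstacle
    solid (an object exposing ``contains(points)``).  The patch octant is
    labelled from the area-weighted centroid direction; if
    ``version_rotation`` (the rotation already applied to build the
    versioned femur) is given, the label is expressed in the femur-fixed
    anatomical frame by undoing the full pose.  With ``neck_axis`` (unit,
    femur frame) the label describes the circumferential position of the
    patch on the neck (its radial direction off the neck axis), the
    clinically reported quantity ("anterior neck", etc.).
    """
    posed = femur.transformed(rot_x(flexion))
    mask = posed.label_mask("neck", "shaft")
    idx = np.flatnonzero(mask)
    cents = posed.face_centroids()[idx]
    areas = posed.face_areas()[idx]
    inside = obstacle.contains(cents)
    patch_idx = idx[inside]
    area = float(areas[inside].sum())
    if area == 0.0:
        return 0.0, patch_idx, "none"
    direction = (cents[inside] * areas[inside, None]).sum(axis=0)
    if version_rotation is not None:
        total = rot_x(flexion) @ version_rotation
        direction = total.T @ direction
        if neck_axis is not None:
            a = np.asarray(neck_axis, dtype=float)
            a = a / np.linalg.norm(a)
            direction = direction - (direction @ a) * a
    return area, patch_idx, octant_label(direction)


def impingement_area(
    femur: LabeledMesh,
    obstacle,
    flexion: float,
) -> float:
    """Total femoral-neck area penetrating the obstacle at ``flexion`` deg."""
    area, _, _ = impingement_patch(femur, obstacle, flexion)
    return area


def sweep_impingement(
    femur_versioned: LabeledMesh,
    obstacle_mesh: LabeledMesh,
    obstacle_solid,
    *,
    step: float = 1.0,
    max_angle: float = 90.0,
    area_angles: tuple[float, ...] = (30.0, 45.0, 60.0, 75.0, 90.0),
    version_rotation: np.ndarray | None = None,
) -> ImpingementResult:
    """Full sweep: onset + area-vs-flexion curve + patch location at 90 deg."""
    onset = onset_flexion(
        femur_versioned, obstacle_mesh, step=step, max_angle=max_angle
    )
    areas: dict[float, float] = {}
    patch = np.zeros(0, dtype=np.int64)
    label = "none"
    for ang in area_angles:
        a, p, lab = impingement_patch(
            femur_versioned, obstacle_solid, ang, version_rotation=version_rotation
        )
        areas[float(ang)] = a
        if ang == max(area_angles):
            patch, label = p, lab
    return ImpingementResult(onset, areas, patch, label)
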