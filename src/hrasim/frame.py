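"""Fixed pelvic coordinate frame, rotations, and anatomical direction labels.

The model lives in a single right-handed pelvic frame for a right hip:

* ``+X`` lateral-to-medial (medial positive),
* ``+Y`` posterior-to-anterior (anterior positive),
* ``+Z`` inferior-to-superior (superior positive),

with the origin at the hip center of rotation (COR).  The pelvis is fully
constrained; all poses are rigid rotations of the femur or the cup about axes
through the COR.
"""

from __future__ import annotations

from enum import Enum

import numpy as np

__all__ = [
    "AngleConvention",
    "rot_x",
    "rot_z",
    "rot_axis",
    "cup_pole_axis",
    "octant_label",
]


class AngleConvention(str, Enum):
    """Cup orientation angle convention (Murray's definitions)."""

    RADIOGRAPHIC = "radiographic"
    ANATOMIC = "anatomic"
    OPERATIVE = "operative"


def rot_x(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the pelvic X (medial-lateral) axis.

    Positive angle moves a point on +Z toward +Y, i.e. the distal femoral
    shaft swings anteriorly: this is hip flexion.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_z(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the pelvic Z (axial) axis.

    Positive angle applied to the femur increases anteversion (the distal
    neck, which points laterally, swings posteriorly).
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about an arbitrary unit axis through origin."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    k = axis / n
    a = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def cup_pole_axis(
    inclination_deg: float,
    version_deg: float,
    convention: AngleConvention | str = AngleConvention.RADIOGRAPHIC,
) -> np.ndarray:
    """Unit direction from the COR to the cup apex (pole) for a right hip.

    Radiographic convention: version is the angle between the cup opening
    axis and the coronal plane; inclination is the angle between the coronal
    projection of the opening axis and the vertical.  At (0, 0) the apex
    points superior (+Z) and the cup opens inferiorly; inclination tilts the
    opening laterally, version tilts it anteriorly.

    Anatomic/operative inputs are converted to radiographic angles first
    (tan(op) = tan(rad)/cos(inc); tan(ana) = tan(rad)/cos(inc) measured in the
    transverse plane relative to the cup face -- standard interconversions).
    """
    conv = AngleConvention(convention)
    inc = float(inclination_deg)
    ver = float(version_deg)
    if conv is AngleConvention.OPERATIVE:
        ver = np.rad2deg(np.arctan(np.tan(np.deg2rad(ver)) * np.cos(np.deg2rad(inc))))
    elif conv is AngleConvention.ANATOMIC:
        # anatomic version >= radiographic version at fixed inclination
        ver = np.rad2deg(
            np.arctan(np.tan(np.deg2rad(ver)) * np.sin(np.deg2rad(inc)))
        ) if inc > 0 else 0.0
    i = np.deg2rad(inc)
    v = np.deg2rad(ver)
    # opening axis a (out of the cup mouth): lateral/anterior/inferior
    a = np.array([-np.sin(i) * np.cos(v), np.sin(v), -np.cos(i) * np.cos(v)])
    return -a  # apex direction


_AXIS_NAMES = (
    ("anterior", "posterior"),  # +Y / -Y
    ("superior", "inferior"),  # +Z / -Z
    ("medial", "lateral"),  # +X / -X
)
_PREFIX = {
    "anterior": "antero",
    "posterior": "postero",
    "superior": "supero",
    "inferior": "infero",
    "medial": "medial",
    "lateral": "lateral",
}


def octant_label(direction: np.ndarray, threshold: float = 0.4) -> str:
    """Coarse anatomical label for a unit direction.

    Components with magnitude >= ``threshold`` (after normalisation)
    contribute, in fixed order anterior/posterior -> superior/inferior ->
    medial/lateral, joined with the usual combining forms (e.g.
    ``anteroinferior``, ``superomedial``).  A zero vector maps to ``none``.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        return "none"
    d = d / n
    comps = [d[1], d[2], d[0]]  # Y, Z, X order
    parts: list[str] = []
    for value, (pos, neg) in zip(comps, _AXIS_NAMES):
        if abs(value) >= threshold:
            parts.append(pos if value > 0 else neg)
    if not parts:
        # fall back to the single dominant axis
        idx = int(np.argmax(np.abs(comps)))
        pos, neg = _AXIS_NAMES[idx]
        parts = [pos if comps[idx] > 0 else neg]
    if len(parts) == 1:
        return parts[0]
    return "".join(_PREFIX[p] for p in parts[:-1]) + parts[-1]
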