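"""Parametric synthetic anatomy: resurfaced femur and acetabular component.

The meshes emulate a CT-derived hip-resurfacing model from its printed
dimensions alone: a Birmingham-style 54 mm femoral head on a 42 mm neck
(neck-shaft angle 125 deg, native anteversion 20 deg) articulating with a
60 mm acetabular shell whose inner bearing radius exceeds the head radius by
an 80 um radial clearance.

The femur is a surface of revolution about the neck axis -- articular
spherical cap, chamfer cone (the cylindrical/chamfer reaming of the head),
neck cylinder -- plus a shaft stub along the diaphyseal axis.  The cup is a
spherical cap about its pole plus an annular peri-acetabular "skirt"
standing in for the bone margin around the rim.  All surfaces are open
(no solids); construction is fully deterministic.

Lengths are mm, angles deg, in the fixed pelvic frame with the head center
(center of rotation, COR) at the origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .frame import rot_z

__all__ = [
    "ImplantSpec",
    "AnatomySpec",
    "MaterialProps",
    "MATERIALS",
    "LabeledMesh",
    "build_femur_mesh",
    "build_cup_mesh",
    "spherical_cap_area",
    "neck_axis_direction",
]


@dataclass(frozen=True)
class ImplantSpec:
    """Bearing and component dimensions of the resurfacing implant.

    ``cup_coverage_arc`` is the full polar arc of the cup bearing surface
    (180 = hemisphere).  The BHR shell is sub-hemispheric (mid-150s to
    mid-160s of arc depending on size); the default of 156 deg is the
    largest arc for which every studied implanted configuration (femoral
    version +-30 deg, cup 40-50 deg inclination x 15-25 deg version) is
    impingement-free in neutral stance, as the reference models are.
    ``component_wall_thickness`` sets the cylindrical ream under the
    femoral component (ream diameter = head_diameter - 2*wall), which
    bounds the articular cap of the head.
    """

    head_diameter: float = 54.0  # mm
    shell_outer_diameter: float = 60.0  # mm
    radial_clearance_um: float = 80.0  # micrometres
    cement_thickness: float = 0.5  # mm (recorded; compliance absorbed in k)
    cup_coverage_arc: float = 156.0  # deg, full arc
    stem_valgus_offset: float = -5.0  # deg, femoral component vs neck axis
    friction_coefficient: float = 0.15  # recorded; normal-spring model only
    component_wall_thickness: float = 3.0  # mm
    skirt_width: float = 5.0  # mm, peri-acetabular bone annulus

    def __post_init__(self) -> None:
        if self.head_diameter <= 0:
            raise ValueError("head_diameter must be positive")
        if self.shell_outer_diameter <= self.head_diameter:
            raise ValueError("shell must be larger than the head")
        if self.radial_clearance_um <= 0:
            raise ValueError("radial clearance must be positive")
        if not 0 < self.cup_coverage_arc <= 180:
            raise ValueError("cup_coverage_arc must be in (0, 180]")
        if not 0 < self.component_wall_thickness < self.head_radius:
            raise ValueError("component wall thickness out of range")

    @property
    def head_radius(self) -> float:
        return self.head_diameter / 2.0

    @property
    def radial_clearance_mm(self) -> float:
        return self.radial_clearance_um * 1e-3

    @property
    def cup_bearing_radius(self) -> float:
        """Inner bearing radius = head radius + radial clearance (27.08 mm)."""
        return self.head_radius + self.radial_clearance_mm

    @property
    def ream_radius(self) -> float:
        """Radius of the cylindrical head reaming (component inner cylinder)."""
        return self.head_radius - self.component_wall_thickness

    @property
    def head_cap_half_angle(self) -> float:
        """Polar extent (deg) of the articular cap of the femoral component.

        The articular sphere ends where it meets the ream cylinder, past the
        equator: 180 - arcsin(r_ream / R_head).
        """
        return 180.0 - np.rad2deg(np.arcsin(self.ream_radius / self.head_radius))


@dataclass(frozen=True)
class AnatomySpec:
    """Parametric proximal femur dimensions (native bone)."""

    neck_diameter: float = 42.0  # mm
    neck_shaft_angle: float = 125.0  # deg
    native_version: float = 20.0  # deg, anteversion positive
    neck_length: float = 35.0  # mm from head center to neck-shaft junction
    shaft_diameter: float = 30.0  # mm
    shaft_length: float = 120.0  # mm

    def __post_init__(self) -> None:
        if not 90 < self.neck_shaft_angle < 180:
            raise ValueError("neck_shaft_angle must be in (90, 180) deg")
        for name in ("neck_diameter", "neck_length", "shaft_diameter", "shaft_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def neck_radius(self) -> float:
        return self.neck_diameter / 2.0


@dataclass(frozen=True)
class MaterialProps:
    """Isotropic linear-elastic constants of one model constituent."""

    young_modulus_gpa: float
    poisson_ratio: float
    role: str

    def __post_init__(self) -> None:
        if self.young_modulus_gpa <= 0:
            raise ValueError("E must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("nu must be in [0, 0.5)")


#: Default material table (cortical/cancellous bone, CoCr implant, PMMA cement).
MATERIALS: dict[str, MaterialProps] = {
    "cortical": MaterialProps(20.0, 0.3, "cortical"),
    "cancellous": MaterialProps(1.0, 0.3, "cancellous"),
    "implant": MaterialProps(200.0, 0.3, "implant"),
    "cement": MaterialProps(2.0, 0.19, "cement"),
}


@dataclass
class LabeledMesh:
    """Triangle surface mesh with per-face part labels in the pelvic frame."""

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int
    part_labels: np.ndarray  # (m,) str

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        self.part_labels = np.asarray(self.part_labels)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if len(self.part_labels) != len(self.faces):
            raise ValueError("one label per face required")

    # -- geometry ---------------------------------------------------------
    def triangles(self, mask: np.ndarray | None = None) -> np.ndarray:
        f = self.faces if mask is None else self.faces[mask]
        return self.vertices[f]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1
        )

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def label_mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.part_labels, labels)

    def submesh(self, mask: np.ndarray) -> "LabeledMesh":
        return LabeledMesh(self.vertices.copy(), self.faces[mask], self.part_labels[mask])

    def transformed(self, rotation: np.ndarray) -> "LabeledMesh":
        return LabeledMesh(self.vertices @ rotation.T, self.faces, self.part_labels)

    def area(self, *labels: str) -> float:
        if labels:
            return float(self.face_areas()[self.label_mask(*labels)].sum())
        return float(self.face_areas().sum())

    # -- I/O --------------------------------------------------------------
    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def export(self, path: str | Path) -> None:
        """Write STL or PLY plus a sidecar JSON with per-face labels."""
        path = Path(path)
        self.to_trimesh().export(path)
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        sidecar.write_text(json.dumps({"part_labels": self.part_labels.tolist()}))

    @classmethod
    def load(cls, path: str | Path) -> "LabeledMesh":
        import trimesh

        path = Path(path)
        tm = trimesh.load_mesh(path, process=False)
        sidecar = path.with_suffix(path.suffix + ".labels.json")
        if sidecar.exists():
            labels = np.asarray(json.loads(sidecar.read_text())["part_labels"])
        else:
            labels = np.full(len(tm.faces), "unlabelled")
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), labels)


def spherical_cap_area(radius: float, half_angle_deg: float) -> float:
    """Area of a spherical cap: 2*pi*R^2*(1 - cos(theta))."""
    return 2.0 * np.pi * radius**2 * (1.0 - np.cos(np.deg2rad(half_angle_deg)))


def neck_axis_direction(anatomy: AnatomySpec) -> np.ndarray:
    """Unit vector from the head center toward the neck-shaft junction.

    With zero version the neck lies in the coronal plane pointing
    lateral-inferior; the native anteversion then rotates the distal neck
    posteriorly about the axial axis.
    """
    elev = np.deg2rad(anatomy.neck_shaft_angle - 90.0)  # elevation above horizontal
    d0 = np.array([-np.cos(elev), 0.0, -np.sin(elev)])  # proximal -> distal
    return rot_z(anatomy.native_version) @ d0


# ---------------------------------------------------------------------------
# mesh construction helpers
# ---------------------------------------------------------------------------


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic pair of unit vectors orthogonal to ``axis``."""
    a = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, a)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return u, v


def _revolve(
    axis: np.ndarray,
    profile_t: np.ndarray,
    profile_r: np.ndarray,
    n_seg: int,
    label_per_band: list[str],
) -> LabeledMesh:
    """Revolve a piecewise profile (t = coordinate along axis, r = radius)
    about ``axis`` through the origin.  ``label_per_band`` labels each band
    between consecutive profile samples.  Rings with r == 0 collapse to an
    apex vertex and produce triangle fans.
    """
    axis = axis / np.linalg.norm(axis)
    u, v = _orthonormal_basis(axis)
    theta = np.linspace(0.0, 2.0 * np.pi, n_seg, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    ring_start: list[int] = []  # vertex index of first ring vertex (or apex)
    ring_is_apex: list[bool] = []
    verts: list[np.ndarray] = []
    for t, r in zip(profile_t, profile_r):
        center = t * axis
        if r <= 1e-12:
            ring_start.append(len(verts))
            ring_is_apex.append(True)
            verts.append(center)
        else:
            ring_start.append(len(verts))
            ring_is_apex.append(False)
            ring = center[None, :] + r * (
                cos_t[:, None] * u[None, :] + sin_t[:, None] * v[None, :]
            )
            verts.extend(ring)

    faces: list[tuple[int, int, int]] = []
    labels: list[str] = []
    for b in range(len(profile_t) - 1):
        s0, s1 = ring_start[b], ring_start[b + 1]
        a0, a1 = ring_is_apex[b], ring_is_apex[b + 1]
        lab = label_per_band[b]
        for j in range(n_seg):
            jn = (j + 1) % n_seg
            if a0 and a1:
                continue  # degenerate band
            if a0:
                faces.append((s0, s1 + j, s1 + jn))
                labels.append(lab)
            elif a1:
                faces.append((s0 + j, s1, s0 + jn))
                labels.append(lab)
            else:
                faces.append((s0 + j, s1 + j, s1 + jn))
                faces.append((s0 + j, s1 + jn, s0 + jn))
                labels.extend((lab, lab))
    return LabeledMesh(np.asarray(verts), np.asarray(faces), np.asarray(labels))


def _merge(meshes: list[LabeledMesh]) -> LabeledMesh:
    offset = 0
    vs, fs, ls = [], [], []
    for m in meshes:
        vs.append(m.vertices)
        fs.append(m.faces + offset)
        ls.append(m.part_labels)
        offset += len(m.vertices)
    return LabeledMesh(np.vstack(vs), np.vstack(fs), np.concatenate(ls))


def build_femur_mesh(
    anatomy: AnatomySpec = AnatomySpec(),
    implant: ImplantSpec = ImplantSpec(),
    resolution: float = 1.0,
) -> LabeledMesh:
    """Parametric resurfaced femur in the pelvic frame, head center at origin.

    Surface of revolution about the (versioned) neck axis: articular
    spherical cap of the component (radius = head radius, polar extent set by
    the cylindrical ream), chamfer cone down to the bone neck, neck cylinder
    to the neck-shaft junction; plus a shaft stub with a hemispherical end
    along the diaphyseal (inferior) axis.  Face labels: ``head_bearing``,
    ``neck`` (chamfer + neck), ``shaft``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if anatomy.neck_diameter >= implant.head_diameter:
        raise ValueError(
            "neck diameter must be smaller than head diameter "
            "(resurfacing geometrically infeasible)"
        )
    R = implant.head_radius
    r_neck = anatomy.neck_radius
    r_ream = implant.ream_radius
    axis = neck_axis_direction(anatomy)

    # articular cap: polar angle 0 .. cap_half (past the equator)
    cap_half = np.deg2rad(implant.head_cap_half_angle)
    n_cap = max(8, int(np.ceil(R * cap_half / resolution)))
    polar = np.linspace(0.0, cap_half, n_cap + 1)
    # profile coordinate along +axis measured from head center; the cap pole
    # is at -axis (pointing into the cup), so t = -R*cos(polar).
    cap_t = -R * np.cos(polar)
    cap_r = R * np.sin(polar)

    # chamfer cone: from cap edge (t_c, r_ream) to neck junction (t_n, r_neck)
    t_c = float(cap_t[-1])
    t_n = float(np.sqrt(R**2 - r_neck**2))  # neck emerges from the head sphere
    n_ch = max(2, int(np.ceil(abs(t_n - t_c) / resolution)))
    ch_t = np.linspace(t_c, t_n, n_ch + 1)[1:]
    ch_r = np.linspace(r_ream, r_neck, n_ch + 1)[1:]

    # neck cylinder to the neck-shaft junction
    n_nk = max(2, int(np.ceil((anatomy.neck_length - t_n) / resolution)))
    nk_t = np.linspace(t_n, anatomy.neck_length, n_nk + 1)[1:]
    nk_r = np.full(n_nk, r_neck)

    profile_t = np.concatenate([cap_t, ch_t, nk_t])
    profile_r = np.concatenate([cap_r, ch_r, nk_r])
    labels = (
        ["head_bearing"] * n_cap + ["neck"] * n_ch + ["neck"] * n_nk
    )
    n_seg = max(12, int(np.ceil(2.0 * np.pi * R / resolution)))
    prox = _revolve(axis, profile_t, profile_r, n_seg, labels)

    # shaft stub: cylinder + hemispherical end along inferior axis from the
    # neck-shaft junction
    junction = anatomy.neck_length * axis
    shaft_axis = np.array([0.0, 0.0, -1.0])
    r_sh = anatomy.shaft_diameter / 2.0
    L = anatomy.shaft_length
    n_len = max(2, int(np.ceil(L / resolution)))
    sh_t = np.linspace(0.0, L, n_len + 1)
    sh_r = np.full(n_len + 1, r_sh)
    # hemispherical distal end
    n_hemi = max(3, int(np.ceil(r_sh * (np.pi / 2) / resolution)))
    hemi_pol = np.linspace(0.0, np.pi / 2, n_hemi + 1)[1:]
    hemi_t = L + r_sh * np.sin(hemi_pol)
    hemi_r = r_sh * np.cos(hemi_pol)
    n_seg_sh = max(10, int(np.ceil(2.0 * np.pi * r_sh / resolution)))
    shaft = _revolve(
        shaft_axis,
        np.concatenate([sh_t, hemi_t]),
        np.concatenate([sh_r, hemi_r]),
        n_seg_sh,
        ["shaft"] * (n_len + n_hemi),
    )
    shaft.vertices = shaft.vertices + junction

    mesh = _merge([prox, shaft])
    areas = mesh.face_areas()
    keep = areas > 1e-12  # drop degenerate slivers from apex bands
    return mesh.submesh(keep)


def build_cup_mesh(
    implant: ImplantSpec = ImplantSpec(), resolution: float = 1.0
) -> LabeledMesh:
    """Acetabular component + bone-skirt surface, pole along +Z (unposed).

    The inner bearing surface is a spherical cap of radius
    ``cup_bearing_radius`` about the pole, polar span ``cup_coverage_arc/2``
    (label ``cup_bearing``).  The peri-acetabular bone margin is an annulus
    in the rim plane extending the rim radially outward by ``skirt_width``
    (label ``cup_rim``).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    Rb = implant.cup_bearing_radius
    half = np.deg2rad(implant.cup_coverage_arc / 2.0)
    if half <= 0:
        raise ValueError("cup coverage arc must be positive")
    pole = np.array([0.0, 0.0, 1.0])

    n_cap = max(8, int(np.ceil(Rb * half / resolution)))
    polar = np.linspace(0.0, half, n_cap + 1)
    cap_t = Rb * np.cos(polar)  # along +Z from center
    cap_r = Rb * np.sin(polar)

    # skirt annulus in the rim plane (t = const), radially outward
    rim_r = float(cap_r[-1])
    rim_t = float(cap_t[-1])
    n_sk = max(2, int(np.ceil(implant.skirt_width / resolution)))
    sk_r = np.linspace(rim_r, rim_r + implant.skirt_width, n_sk + 1)[1:]
    sk_t = np.full(n_sk, rim_t)

    profile_t = np.concatenate([cap_t, sk_t])
    profile_r = np.concatenate([cap_r, sk_r])
    labels = ["cup_bearing"] * n_cap + ["cup_rim"] * n_sk
    n_seg = max(12, int(np.ceil(2.0 * np.pi * Rb / resolution)))
    mesh = _revolve(pole, profile_t, profile_r, n_seg, labels)
    keep = mesh.face_areas() > 1e-12
    return mesh.submesh(keep)


def specs_to_dict(anatomy: AnatomySpec, implant: ImplantSpec) -> dict:
    return {"anatomy": asdict(anatomy), "implant": asdict(implant)}
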