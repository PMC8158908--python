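"""Elastic-foundation (discrete-element) bearing contact model.

The conformal metal-on-metal bearing is represented as a bed of independent
compressive springs on the inner acetabular cup surface.  With the head and
cup treated as rigid conforming spheres separated by the radial clearance
``c``, a head-center displacement ``u`` produces at a cup element with
outward unit direction ``e_i`` the overclosure ``u . e_i - c``; the element
pressure is ``p_i = k * max(0, u . e_i - c)`` with foundation stiffness
``k`` (MPa/mm).  Static equilibrium determines ``u`` from the applied joint
force ``F``:

    sum_i p_i A_i e_i = F.

An element can only carry pressure where both bearing surfaces exist: on
the cup this is the posed coverage cap; on the femoral side the articular
cap of the resurfacing head (finite because of the cylindrical/chamfer
reaming), which is how femoral version and flexion enter the otherwise
spherically symmetric problem.

``k`` may be taken physically (supporting-layer modulus / thickness) or
calibrated once against a documented reference pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .frame import octant_label
from .geometry import ImplantSpec, MATERIALS, spherical_cap_area
from .kinematics import CupPose

__all__ = [
    "BearingDiscretization",
    "FoundationModel",
    "ContactSolution",
    "discretize_bearing",
    "physical_foundation",
    "solve_contact",
    "closed_form_polar",
    "calibrate_stiffness",
    "contact_metrics",
]


@dataclass(frozen=True)
class BearingDiscretization:
    """Quasi-uniform element layout over the posed cup bearing cap."""

    directions: np.ndarray  # (n, 3) unit vectors COR -> element center
    areas: np.ndarray  # (n,) mm^2
    radius: float  # mm, cup inner bearing radius
    pole: np.ndarray  # (3,) posed cup pole

    @property
    def n(self) -> int:
        return len(self.directions)

    @property
    def normals(self) -> np.ndarray:
        """Inward unit normals (toward the COR)."""
        return -self.directions


@dataclass(frozen=True)
class FoundationModel:
    """Elastic-foundation parameters.

    ``stiffness``: contact pressure per unit overclosure, MPa/mm.
    ``clearance``: radial clearance of the bearing, mm.
    ``source``: 'physical' (modulus/thickness) or 'calibrated'.
    """

    stiffness: float
    clearance: float
    source: str = "physical"

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or self.clearance <= 0:
            raise ValueError("stiffness and clearance must be positive")


def physical_foundation(
    implant: ImplantSpec = ImplantSpec(),
    support_thickness: float = 5.0,
    modulus_gpa: float | None = None,
) -> FoundationModel:
    """Foundation stiffness from the supporting-layer elasticity.

    Default: cancellous-bone modulus over a configurable support thickness
    (k = E / t), the dominant compliance beneath the thin metal shells.
    """
    E = (modulus_gpa if modulus_gpa is not None else MATERIALS["cancellous"].young_modulus_gpa) * 1e3
    return FoundationModel(E / support_thickness, implant.radial_clearance_mm, "physical")


@dataclass
class ContactSolution:
    """Converged equilibrium of one contact solve."""

    displacement: np.ndarray  # (3,) mm head-center displacement
    pressures: np.ndarray  # (n,) MPa
    peak_pressure: float  # MPa
    contact_area: float  # mm^2
    patch_centroid_octant: str
    equilibrium_residual: float  # N
    load: np.ndarray  # (3,) N
    centroid_direction: np.ndarray | None = None  # pressure-weighted, pelvic frame


def _fibonacci_cap(n: int, half_angle_rad: float) -> np.ndarray:
    """Deterministic quasi-uniform directions on a spherical cap about +Z."""
    i = np.arange(n, dtype=float) + 0.5
    # equal-area in cos(theta) over the cap
    cos_t = 1.0 - (1.0 - np.cos(half_angle_rad)) * (i / n)
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n, dtype=float)
    return np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1)


def discretize_bearing(
    implant: ImplantSpec,
    pose: CupPose,
    n_target: int = 20_000,
) -> BearingDiscretization:
    """Equal-area Fibonacci-spiral elements over the posed coverage cap."""
    if n_target < 100:
        raise ValueError("need at least 100 elements")
    half = implant.cup_coverage_arc / 2.0
    if half <= 0:
        raise ValueError("zero cup coverage")
    dirs_local = _fibonacci_cap(n_target, np.deg2rad(half))
    # rotate +Z onto the posed pole
    z = np.array([0.0, 0.0, 1.0])
    p = pose.pole
    v = np.cross(z, p)
    s = np.linalg.norm(v)
    c = float(z @ p)
    if s < 1e-14:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    dirs = dirs_local @ R.T
    Rb = implant.cup_bearing_radius
    total = spherical_cap_area(Rb, half)
    areas = np.full(n_target, total / n_target)
    return BearingDiscretization(dirs, areas, Rb, p)


def solve_contact(
    bearing: BearingDiscretization,
    foundation: FoundationModel,
    load: np.ndarray,
    *,
    head_cap: tuple[np.ndarray, float] | None = None,
    tol_rel: float = 1e-10,
    max_iter: int = 200,
) -> ContactSolution:
    """Solve the discrete-element contact equilibrium for one load vector.

    ``head_cap = (pole_direction, half_angle_deg)`` restricts load-bearing
    elements to those also covered by the femoral articular cap; ``None``
    treats the head as a full sphere.

    Damped Newton on the head-center displacement; raises ``RuntimeError``
    if no equilibrium exists (load directed outside the supported cap).
    """
    F = np.asarray(load, dtype=float)
    Fmag = float(np.linalg.norm(F))
    k = foundation.stiffness
    c = foundation.clearance
    e = bearing.directions
    A = bearing.areas
    avail = np.ones(bearing.n, dtype=bool)
    if head_cap is not None:
        pole, half_deg = head_cap
        pole = np.asarray(pole, dtype=float)
        pole = pole / np.linalg.norm(pole)
        avail = e @ pole >= np.cos(np.deg2rad(half_deg))
        if not avail.any():
            raise RuntimeError(
                "femoral articular cap does not overlap the cup cap"
            )

    if Fmag == 0.0:
        p = np.zeros(bearing.n)
        return ContactSolution(
            np.zeros(3), p, 0.0, 0.0, "none", 0.0, F
        )

    def residual(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        over = e @ u - c
        over[~avail] = -1.0
        act = over > 0
        p = np.where(act, k * over, 0.0)
        r = (p * A) @ e - F
        return r, act

    # start just past the clearance along the load direction
    u = (c * 1.01) * F / Fmag
    r, act = residual(u)
    for _ in range(max_iter):
        if np.linalg.norm(r) <= tol_rel * Fmag:
            break
        if not act.any():
            u = (c * 1.01) * F / Fmag
            r, act = residual(u)
            continue
        ea = e[act]
        J = (k * A[act])[:, None, None] * ea[:, :, None] * ea[:, None, :]
        J = J.sum(axis=0)
        try:
            du = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError:
            du = np.linalg.lstsq(J, -r, rcond=None)[0]
        # backtracking line search
        step = 1.0
        rn = np.linalg.norm(r)
        for _ls in range(60):
            u_new = u + step * du
            r_new, act_new = residual(u_new)
            if np.linalg.norm(r_new) < rn:
                u, r, act = u_new, r_new, act_new
                break
            step *= 0.5
        else:
            raise RuntimeError(
                "contact solver stalled: no equilibrium reachable "
                "(load may be directed outside the supported bearing cap)"
            )
    else:
        raise RuntimeError(
            "contact solver did not converge: load is likely directed "
            "outside the supported bearing cap (no equilibrium exists)"
        )

    over = e @ u - c
    over[~avail] = -1.0
    p = np.where(over > 0, k * over, 0.0)
    area = float(A[p > 0].sum())
    centroid = None
    if area > 0:
        centroid = ((p * A)[:, None] * e).sum(axis=0)
        oct_lab = octant_label(centroid)
    else:
        oct_lab = "none"
    return ContactSolution(
        u,
        p,
        float(p.max()),
        area,
        oct_lab,
        float(np.linalg.norm(r)),
        F,
        centroid,
    )


def closed_form_polar(
    foundation: FoundationModel,
    cup_radius: float,
    axial_load: float,
    coverage_half_angle_deg: float = 90.0,
) -> tuple[float, float]:
    """Axisymmetric closed form for a load along the cup pole axis.

    For polar loads the displacement is axial (u along the pole) and the
    equilibrium integral has an exact antiderivative: with x = cos(theta),

        F(u) = 2 pi R^2 k [ u (1 - x1^3)/3 - c (1 - x1^2)/2 ],

    where x1 = max(c/u, cos(theta_max)).  ``u`` is found by bracketed root
    finding; returns ``(peak_pressure MPa, contact half-angle deg)``.
    """
    if axial_load < 0:
        raise ValueError("axial load must be >= 0")
    k, c = foundation.stiffness, foundation.clearance
    R = cup_radius
    x_max = np.cos(np.deg2rad(coverage_half_angle_deg))

    def force(u: float) -> float:
        if u <= c:
            return 0.0
        x1 = max(c / u, x_max)
        return 2 * np.pi * R**2 * k * (u * (1 - x1**3) / 3.0 - c * (1 - x1**2) / 2.0)

    if axial_load == 0.0:
        return 0.0, 0.0
    hi = c * 2.0
    while force(hi) < axial_load:
        hi *= 2.0
        if hi > 1e6 * c:
            raise RuntimeError("polar closed form failed to bracket the load")
    u = brentq(lambda uu: force(uu) - axial_load, c, hi, xtol=1e-14, rtol=1e-15)
    peak = k * (u - c)
    half_angle = np.rad2deg(np.arccos(np.clip(c / u, -1.0, 1.0)))
    return float(peak), float(half_angle)


def calibrate_stiffness(
    reference_solve,
    target_peak: float,
    *,
    clearance: float,
    k_bounds: tuple[float, float] = (1.0, 1e5),
    rtol: float = 1e-10,
) -> FoundationModel:
    """Bisect the foundation stiffness so a reference case hits a target peak.

    ``reference_solve(foundation) -> peak MPa`` runs the documented
    reference configuration; the peak is strictly increasing in ``k`` so the
    calibrated stiffness is unique.  Returns a model marked
    ``source='calibrated'``.
    """
    if target_peak <= 0:
        raise ValueError("target peak must be positive")

    def f(log_k: float) -> float:
        fm = FoundationModel(float(np.exp(log_k)), clearance, "calibrated")
        return reference_solve(fm) - target_peak

    lo, hi = np.log(k_bounds[0]), np.log(k_bounds[1])
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"target peak {target_peak} MPa unreachable within stiffness "
            f"bounds {k_bounds} MPa/mm"
        )
    log_k = brentq(f, lo, hi, rtol=rtol)
    return FoundationModel(float(np.exp(log_k)), clearance, "calibrated")


def contact_metrics(
    solution: ContactSolution,
    depose_rotation: np.ndarray | None = None,
) -> tuple[float, float, str]:
    """(peak pressure MPa, contact area mm^2, patch octant label).

    With ``depose_rotation`` (the femoral pose rotation) the octant is
    re-expressed in the femur-fixed anatomical frame, locating the patch on
    the bone-implant interface rather than in the pelvic frame.
    """
    label = solution.patch_centroid_octant
    if depose_rotation is not None and solution.centroid_direction is not None:
        label = octant_label(depose_rotation.T @ solution.centroid_direction)
    return (solution.peak_pressure, solution.contact_area, label)
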