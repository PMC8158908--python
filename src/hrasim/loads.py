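"""In-vivo hip joint load cases.

Three peak hip contact forces (Bergmann-type in-vivo data) define the
functional loading conditions: single-leg stance during walking at
1.09 m/s (0 deg hip flexion), stair climbing (45 deg), and sitting
(90 deg).  Components are magnitudes along +X (medial), +Y (anterior),
+Z (superior) in the pelvic frame, so the resultant pushes the femoral
head into the superomedial cup.  Magnitudes are cross-checked against the
tabulated percent-of-body-weight values (reference weight 836 N).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "LoadCase",
    "REFERENCE_WEIGHT_N",
    "LOAD_CASES",
    "get_load_case",
    "validate_pct_bw",
]

REFERENCE_WEIGHT_N: float = 836.0


@dataclass(frozen=True)
class LoadCase:
    """One static peak joint force with %BW bookkeeping."""

    name: str
    flexion: float  # deg of hip flexion for the activity
    pct_bw: int  # tabulated percent of body weight
    force: tuple[float, float, float]  # N, (Fx, Fy, Fz) pelvic frame
    reference_weight: float = REFERENCE_WEIGHT_N

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.force, dtype=float)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


LOAD_CASES: dict[str, LoadCase] = {
    "flex0": LoadCase("flex0", 0.0, 238, (443.0, 266.0, 1920.0)),
    "flex45": LoadCase("flex45", 45.0, 251, (492.0, 510.0, 1974.0)),
    "flex90": LoadCase("flex90", 90.0, 156, (359.0, 6.0, 1253.0)),
}


def get_load_case(flexion: float) -> LoadCase:
    """Return the printed load case for 0, 45 or 90 deg of hip flexion.

    Only the three tabulated activities are defined; no interpolation.
    """
    for case in LOAD_CASES.values():
        if case.flexion == flexion:
            return case
    raise ValueError(
        f"no load case defined at {flexion} deg flexion; "
        "only 0, 45 and 90 deg are tabulated (no interpolation)"
    )


def validate_pct_bw(case: LoadCase) -> int:
    """Percent of body weight implied by the force vector, integer-rounded.

    Raises ``ValueError`` if it disagrees with the stored tabulated value.
    """
    pct = int(round(100.0 * case.magnitude / case.reference_weight))
    if case.pct_bw is not None and pct != case.pct_bw:
        raise ValueError(
            f"load case {case.name}: |F| = {case.magnitude:.1f} N implies "
            f"{pct}%BW but table states {case.pct_bw}%BW"
        )
    return pct


def custom_load_case(name: str, flexion: float, force: tuple[float, float, float]) -> LoadCase:
    """Build a user load case (sensitivity studies); %BW derived, not asserted."""
    mag = float(np.linalg.norm(force))
    return LoadCase(name, flexion, int(round(100 * mag / REFERENCE_WEIGHT_N)), force)
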