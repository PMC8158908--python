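"""Triangle-mesh proximity and collision detection.

Narrow phase: the exact distance between two triangles is the minimum over
the 9 edge-edge segment distances and the 6 vertex-triangle distances,
except when the triangles intersect, in which case one triangle's edge
pierces the other's interior and the distance is zero; the edge-piercing
test (Moller-Trumbore restricted to the segment) handles that case.  All
candidate computations are vectorised over pairs.

Broad phase: candidate face pairs are pruned with a cKDTree on face
centroids using per-face circumradii, which is conservative (never discards
a pair within tolerance).  The brute-force all-pairs route through the same
narrow phase is kept as the oracle for the pruning.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import LabeledMesh

__all__ = ["detect_contact", "triangle_pair_distances"]

_EPS = 1e-12


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points p to segments ab (all (k,3))."""
    ab = b - a
    t = np.einsum("ij,ij->i", p - a, ab)
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.divide(t, denom, out=np.zeros_like(t), where=denom > _EPS), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(p - closest, axis=1)


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from points p (k,3) to triangles tri (k,3,3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    n = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", n, n)
    # signed projection onto the plane
    dist_plane = np.einsum("ij,ij->i", p - a, n)
    proj = p - (np.divide(dist_plane, nn, out=np.zeros_like(nn), where=nn > _EPS))[
        :, None
    ] * n
    # barycentric test of the projection
    v0, v1, v2 = c - a, b - a, proj - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d02 = np.einsum("ij,ij->i", v0, v2)
    d12 = np.einsum("ij,ij->i", v1, v2)
    denom = d00 * d11 - d01 * d01
    u = np.divide(d11 * d02 - d01 * d12, denom, out=np.full_like(denom, -1.0), where=np.abs(denom) > _EPS)
    v = np.divide(d00 * d12 - d01 * d02, denom, out=np.full_like(denom, -1.0), where=np.abs(denom) > _EPS)
    inside = (u >= 0) & (v >= 0) & (u + v <= 1)
    d_edges = np.minimum.reduce(
        [
            _point_segment_distance(p, a, b),
            _point_segment_distance(p, b, c),
            _point_segment_distance(p, c, a),
        ]
    )
    d_inside = np.abs(dist_plane) / np.sqrt(np.maximum(nn, _EPS))
    return np.where(inside, np.minimum(d_inside, d_edges), d_edges)


def _segment_segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Distance between segments p1q1 and p2q2 (all (k,3)); Ericson's method."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(
        denom > _EPS,
        np.clip(np.divide(b * f - c * e, denom, out=np.zeros_like(denom), where=denom > _EPS), 0.0, 1.0),
        0.0,
    )
    t = np.divide(b * s + f, e, out=np.zeros_like(e), where=e > _EPS)
    # re-clamp t, then recompute s for clamped t
    t_cl = np.clip(t, 0.0, 1.0)
    s = np.where(
        t != t_cl,
        np.clip(np.divide(b * t_cl - c, a, out=np.zeros_like(a), where=a > _EPS), 0.0, 1.0),
        s,
    )
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t_cl[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1)


def _segment_pierces_triangle(
    p: np.ndarray, q: np.ndarray, tri: np.ndarray
) -> np.ndarray:
    """True where segment pq crosses the (open) interior of triangle."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    d = q - p
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > _EPS
    inv = np.divide(1.0, det, out=np.zeros_like(det), where=ok)
    s = p - a
    u = np.einsum("ij,ij->i", s, h) * inv
    qv = np.cross(s, e1)
    v = np.einsum("ij,ij->i", d, qv) * inv
    t = np.einsum("ij,ij->i", e2, qv) * inv
    return ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t >= 0) & (t <= 1)


def triangle_pair_distances(tri_a: np.ndarray, tri_b: np.ndarray) -> np.ndarray:
    """Exact distances between paired triangles (k,3,3) vs (k,3,3)."""
    tri_a = np.asarray(tri_a, dtype=float)
    tri_b = np.asarray(tri_b, dtype=float)
    k = len(tri_a)
    if k == 0:
        return np.zeros(0)
    d = np.full(k, np.inf)
    # vertex-triangle candidates
    for i in range(3):
        d = np.minimum(d, _point_triangle_distance(tri_a[:, i], tri_b))
        d = np.minimum(d, _point_triangle_distance(tri_b[:, i], tri_a))
    # edge-edge candidates
    for i in range(3):
        p1, q1 = tri_a[:, i], tri_a[:, (i + 1) % 3]
        for j in range(3):
            p2, q2 = tri_b[:, j], tri_b[:, (j + 1) % 3]
            d = np.minimum(d, _segment_segment_distance(p1, q1, p2, q2))
    # piercing => intersecting => distance zero
    pierce = np.zeros(k, dtype=bool)
    for i in range(3):
        pierce |= _segment_pierces_triangle(
            tri_a[:, i], tri_a[:, (i + 1) % 3], tri_b
        )
        pierce |= _segment_pierces_triangle(
            tri_b[:, i], tri_b[:, (i + 1) % 3], tri_a
        )
    d[pierce] = 0.0
    return d


def _face_bounds(mesh: LabeledMesh, mask: np.ndarray | None):
    tris = mesh.triangles(mask)
    cent = tris.mean(axis=1)
    rad = np.linalg.norm(tris - cent[:, None, :], axis=2).max(axis=1)
    return tris, cent, rad


def detect_contact(
    mesh_a: LabeledMesh,
    mesh_b: LabeledMesh,
    tolerance: float = 0.0,
    *,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
    broad_phase: bool = True,
    find_all: bool = True,
    _chunk: int = 200_000,
) -> tuple[bool, np.ndarray]:
    """Detect triangle pairs of two meshes within ``tolerance`` (mm).

    ``tolerance = 0`` detects touching/interpenetrating pairs.  Returns
    ``(contacting, face_pairs)`` with pairs indexed into the (masked) face
    lists.  ``broad_phase=False`` runs the brute-force all-pairs oracle.
    ``find_all=False`` stops at the first offending chunk (onset sweeps).
    """
    if len(mesh_a.faces) == 0 or len(mesh_b.faces) == 0:
        raise ValueError("detect_contact requires non-empty meshes")
    tris_a, cent_a, rad_a = _face_bounds(mesh_a, mask_a)
    tris_b, cent_b, rad_b = _face_bounds(mesh_b, mask_b)
    if len(tris_a) == 0 or len(tris_b) == 0:
        raise ValueError("mask selects no faces")

    if broad_phase:
        tree_b = cKDTree(cent_b)
        rb_max = float(rad_b.max())
        neighbours = tree_b.query_ball_point(
            cent_a, rad_a + rb_max + tolerance, workers=-1
        )
        ia = np.concatenate(
            [np.full(len(nb), i, dtype=np.int64) for i, nb in enumerate(neighbours)]
        ) if any(len(nb) for nb in neighbours) else np.zeros(0, dtype=np.int64)
        ib = (
            np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neighbours])
            if ia.size
            else np.zeros(0, dtype=np.int64)
        )
        if ia.size:
            # tighten with exact per-pair bounding radii
            keep = (
                np.linalg.norm(cent_a[ia] - cent_b[ib], axis=1)
                <= rad_a[ia] + rad_b[ib] + tolerance
            )
            ia, ib = ia[keep], ib[keep]
    else:
        ia, ib = np.meshgrid(
            np.arange(len(tris_a)), np.arange(len(tris_b)), indexing="ij"
        )
        ia, ib = ia.ravel(), ib.ravel()

    hits_a: list[np.ndarray] = []
    hits_b: list[np.ndarray] = []
    for start in range(0, ia.size, _chunk):
        sl = slice(start, start + _chunk)
        d = triangle_pair_distances(tris_a[ia[sl]], tris_b[ib[sl]])
        hit = d <= tolerance
        if hit.any():
            hits_a.append(ia[sl][hit])
            hits_b.append(ib[sl][hit])
            if not find_all:
                break
    if hits_a:
        pairs = np.stack([np.concatenate(hits_a), np.concatenate(hits_b)], axis=1)
        return True, pairs
    return False, np.zeros((0, 2), dtype=np.int64)
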