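"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's BVH/kernel code paths:
distances use a vectorised closest-point-on-boundary-or-plane formulation,
intersection uses a plane-crossing + barycentric containment formulation,
and segment-segment distance is bounded by dense parameter sampling.
"""

from __future__ import annotations

import numpy as np

BARY_EPS = 1e-9  # same contact convention as the implementation


def _seg_point_d2(p: np.ndarray, s: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Squared distances from point p (3,) to segments s->e ((m, 3) each)."""
    d = e - s
    ll = np.einsum("ij,ij->i", d, d)
    t = np.einsum("ij,ij->i", p[None, :] - s, d) / np.where(ll > 0, ll, 1.0)
    t = np.clip(t, 0.0, 1.0)
    q = s + t[:, None] * d
    diff = p[None, :] - q
    return np.einsum("ij,ij->i", diff, diff)


def brute_min_distance(mesh, p) -> float:
    """Exact point-to-mesh distance by testing every triangle: the closest
    point is either the in-plane projection (when its barycentric
    coordinates are non-negative) or lies on one of the three edges."""
    p = np.asarray(p, dtype=np.float64)
    a, b, c = mesh.triangle_vertices()
    d2 = np.minimum.reduce(
        [_seg_point_d2(p, a, b), _seg_point_d2(p, b, c), _seg_point_d2(p, c, a)]
    )
    n = np.cross(b - a, c - a)
    nn = np.einsum("ij,ij->i", n, n)
    t = np.einsum("ij,ij->i", p[None, :] - a, n) / np.where(nn > 0, nn, 1.0)
    proj = p[None, :] - t[:, None] * n
    # barycentric containment of the projection
    v0 = b - a
    v1 = c - a
    v2 = proj - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    u = (d11 * d20 - d01 * d21) / denom
    v = (d00 * d21 - d01 * d20) / denom
    inside = (u >= 0) & (v >= 0) & (u + v <= 1) & (nn > 0)
    plane_d2 = t * t * nn
    d2 = np.where(inside, np.minimum(d2, plane_d2), d2)
    return float(np.sqrt(d2.min()))


def brute_segment_intersects(mesh, p0, p1) -> bool:
    """Segment-mesh intersection by plane crossing + containment, applied to
    every triangle, with the implementation's contact epsilon."""
    p0 = np.asarray(p0, dtype=np.float64)
    p1 = np.asarray(p1, dtype=np.float64)
    a, b, c = mesh.triangle_vertices()
    n = np.cross(b - a, c - a)
    h0 = np.einsum("ij,ij->i", p0[None, :] - a, n)
    h1 = np.einsum("ij,ij->i", p1[None, :] - a, n)
    denom = h0 - h1
    parallel = np.abs(np.einsum("ij,j->i", n, p1 - p0)) < 1e-12 * np.linalg.norm(n, axis=1).clip(min=1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(np.abs(denom) > 0, h0 / np.where(denom != 0, denom, 1.0), np.inf)
    x = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    v0 = b - a
    v1 = c - a
    v2 = x - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    det = d00 * d11 - d01 * d01
    det = np.where(np.abs(det) > 0, det, 1.0)
    u = (d11 * d20 - d01 * d21) / det
    v = (d00 * d21 - d01 * d20) / det
    hits = (
        ~parallel
        & (t >= -BARY_EPS)
        & (t <= 1.0 + BARY_EPS)
        & (u >= -BARY_EPS)
        & (v >= -BARY_EPS)
        & (u + v <= 1.0 + BARY_EPS)
    )
    return bool(hits.any())


def sampled_segment_distance(a, b, n: int = 400) -> float:
    """Upper bound on the segment-segment distance from an n x n parameter
    grid; converges to the true value as n grows."""
    p = np.asarray(a[0], float) + np.linspace(0, 1, n)[:, None] * (np.asarray(a[1], float) - np.asarray(a[0], float))
    q = np.asarray(b[0], float) + np.linspace(0, 1, n)[:, None] * (np.asarray(b[1], float) - np.asarray(b[0], float))
    d = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    return float(d.min())


def interleave_oracle(x: int, y: int, z: int) -> int:
    """Morton interleaving by explicit bit-string weaving (x lowest)."""
    bits = []
    for k in range(10):
        bits.append((x >> k) & 1)
        bits.append((y >> k) & 1)
        bits.append((z >> k) & 1)
    return sum(bit << i for i, bit in enumerate(bits))


def analytic_shell_membership(points, r_inner: float, r_outer: float) -> np.ndarray:
    """True where a point lies strictly inside the spherical shell."""
    r = np.linalg.norm(np.atleast_2d(points), axis=1)
    return (r > r_inner) & (r < r_outer)
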