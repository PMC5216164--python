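"""Compiled geometry kernels for BVH traversal.

All kernels operate on the flat node arrays produced by
:func:`seegplan.bvh.build_bvh`:

* ``bb_min``, ``bb_max`` — (n_nodes, 3) node AABBs
* ``left``, ``right`` — child indices (-1 for leaves)
* ``tri`` — leaf triangle index (-1 for internal nodes)
* ``tv0``, ``tv1``, ``tv2`` — (n_faces, 3) triangle corner coordinates

Children always carry a larger index than their parent (construction order),
which the bottom-up AABB pass in the builder relies on; the kernels only need
the parent->child pointers.

Numerical conventions (fixed, see docs/methods.md): the segment-triangle test
uses an epsilon of 1e-9 on the barycentric and parameter bounds, so touching
(edge/vertex) contact counts as intersection; exactly coplanar segments are
treated as misses (watertight arithmetic is not attempted).  Point-triangle
distance is exact (Ericson's region-based closest point).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BARY_EPS = 1e-9


# ---------------------------------------------------------------------------
# scalar primitives


@njit(cache=True, error_model="numpy")
def _point_tri_dist2(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Squared distance from point P to triangle ABC (closest-point regions)."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        qx, qy, qz = ax + t * abx - px, ay + t * aby - py, az + t * abz - pz
        return qx * qx + qy * qy + qz * qz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        qx, qy, qz = ax + t * acx - px, ay + t * acy - py, az + t * acz - pz
        return qx * qx + qy * qy + qz * qz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        qx = bx + t * (cx - bx) - px
        qy = by + t * (cy - by) - py
        qz = bz + t * (cz - bz) - pz
        return qx * qx + qy * qy + qz * qz
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    qx = ax + abx * v + acx * w - px
    qy = ay + aby * v + acy * w - py
    qz = az + abz * v + acz * w - pz
    return qx * qx + qy * qy + qz * qz


@njit(cache=True, error_model="numpy")
def _seg_tri_intersects(p0x, p0y, p0z, p1x, p1y, p1z, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Moller-Trumbore for the closed segment P0P1; touching contact hits."""
    dx, dy, dz = p1x - p0x, p1y - p0y, p1z - p0z
    e1x, e1y, e1z = bx - ax, by - ay, bz - az
    e2x, e2y, e2z = cx - ax, cy - ay, cz - az
    hx = dy * e2z - dz * e2y
    hy = dz * e2x - dx * e2z
    hz = dx * e2y - dy * e2x
    det = e1x * hx + e1y * hy + e1z * hz
    if -1e-12 < det < 1e-12:
        return False  # parallel / coplanar: treated as miss
    f = 1.0 / det
    sx, sy, sz = p0x - ax, p0y - ay, p0z - az
    u = f * (sx * hx + sy * hy + sz * hz)
    if u < -BARY_EPS or u > 1.0 + BARY_EPS:
        return False
    qx = sy * e1z - sz * e1y
    qy = sz * e1x - sx * e1z
    qz = sx * e1y - sy * e1x
    v = f * (dx * qx + dy * qy + dz * qz)
    if v < -BARY_EPS or u + v > 1.0 + BARY_EPS:
        return False
    t = f * (e2x * qx + e2y * qy + e2z * qz)
    return -BARY_EPS <= t <= 1.0 + BARY_EPS


@njit(cache=True, error_model="numpy")
def _seg_aabb_hit(p0, p1, bmin, bmax):
    """Slab test: does the closed segment intersect the AABB?"""
    t0 = 0.0
    t1 = 1.0
    for k in range(3):
        d = p1[k] - p0[k]
        if -1e-300 < d < 1e-300:
            if p0[k] < bmin[k] - 1e-12 or p0[k] > bmax[k] + 1e-12:
                return False
        else:
            inv = 1.0 / d
            ta = (bmin[k] - p0[k]) * inv
            tb = (bmax[k] - p0[k]) * inv
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
            if t0 > t1 + 1e-12:
                return False
    return True


@njit(cache=True, error_model="numpy")
def _point_aabb_dist2(p, bmin, bmax):
    d2 = 0.0
    for k in range(3):
        if p[k] < bmin[k]:
            d = bmin[k] - p[k]
            d2 += d * d
        elif p[k] > bmax[k]:
            d = p[k] - bmax[k]
            d2 += d * d
    return d2


@njit(cache=True, error_model="numpy")
def _ray_aabb_hit(p, dinv, bmin, bmax):
    """Does the ray p + t*d (t >= 0) hit the AABB?  dinv = 1/d componentwise."""
    t0 = 0.0
    t1 = np.inf
    for k in range(3):
        if np.isinf(dinv[k]):
            if p[k] < bmin[k] - 1e-12 or p[k] > bmax[k] + 1e-12:
                return False
        else:
            ta = (bmin[k] - p[k]) * dinv[k]
            tb = (bmax[k] - p[k]) * dinv[k]
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
            if t0 > t1 + 1e-12:
                return False
    return True


# ---------------------------------------------------------------------------
# BVH traversals


@njit(cache=True, error_model="numpy")
def segment_intersects_kernel(bb_min, bb_max, left, right, tri, tv0, tv1, tv2, p0, p1):
    """Stack traversal; returns (hit, leaf_tests)."""
    n_nodes = left.shape[0]
    stack = np.empty(n_nodes + 1, dtype=np.int64)
    top = 0
    stack[0] = 0
    leaf_tests = 0
    while top >= 0:
        node = stack[top]
        top -= 1
        if not _seg_aabb_hit(p0, p1, bb_min[node], bb_max[node]):
            continue
        t = tri[node]
        if t >= 0:
            leaf_tests += 1
            if _seg_tri_intersects(
                p0[0], p0[1], p0[2], p1[0], p1[1], p1[2],
                tv0[t, 0], tv0[t, 1], tv0[t, 2],
                tv1[t, 0], tv1[t, 1], tv1[t, 2],
                tv2[t, 0], tv2[t, 1], tv2[t, 2],
            ):
                return True, leaf_tests
        else:
            top += 1
            stack[top] = left[node]
            top += 1
            stack[top] = right[node]
    return False, leaf_tests


@njit(cache=True, error_model="numpy")
def _heap_push(keys, vals, size, key, val):
    i = size
    keys[i] = key
    vals[i] = val
    while i > 0:
        parent = (i - 1) >> 1
        if keys[parent] <= keys[i]:
            break
        keys[parent], keys[i] = keys[i], keys[parent]
        vals[parent], vals[i] = vals[i], vals[parent]
        i = parent
    return size + 1


@njit(cache=True, error_model="numpy")
def _heap_pop(keys, vals, size):
    key = keys[0]
    val = vals[0]
    size -= 1
    keys[0] = keys[size]
    vals[0] = vals[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        smallest = i
        if l < size and keys[l] < keys[smallest]:
            smallest = l
        if r < size and keys[r] < keys[smallest]:
            smallest = r
        if smallest == i:
            break
        keys[smallest], keys[i] = keys[i], keys[smallest]
        vals[smallest], vals[i] = vals[i], vals[smallest]
        i = smallest
    return key, val, size


@njit(cache=True, error_model="numpy")
def min_distance_kernel(bb_min, bb_max, left, right, tri, tv0, tv1, tv2, p):
    """Best-first traversal ordered by AABB distance; returns (dist, tri_idx).

    The frontier is a priority queue keyed by squared AABB distance; a node is
    expanded only while its key beats the best exact triangle distance so far
    (the pruning rule f_bb < f_j).  Exact point-triangle distance at leaves.
    """
    n_nodes = left.shape[0]
    keys = np.empty(n_nodes + 1, dtype=np.float64)
    vals = np.empty(n_nodes + 1, dtype=np.int64)
    size = 0
    size = _heap_push(keys, vals, size, _point_aabb_dist2(p, bb_min[0], bb_max[0]), 0)
    best = np.inf  # squared
    best_tri = -1
    while size > 0:
        key, node, size = _heap_pop(keys, vals, size)
        if key >= best:
            break
        t = tri[node]
        if t >= 0:
            d2 = _point_tri_dist2(
                p[0], p[1], p[2],
                tv0[t, 0], tv0[t, 1], tv0[t, 2],
                tv1[t, 0], tv1[t, 1], tv1[t, 2],
                tv2[t, 0], tv2[t, 1], tv2[t, 2],
            )
            if d2 < best:
                best = d2
                best_tri = t
        else:
            for child in (left[node], right[node]):
                ck = _point_aabb_dist2(p, bb_min[child], bb_max[child])
                if ck < best:
                    size = _heap_push(keys, vals, size, ck, child)
    return np.sqrt(best), best_tri


@njit(cache=True, error_model="numpy")
def min_distance_batch_kernel(bb_min, bb_max, left, right, tri, tv0, tv1, tv2, pts):
    n = pts.shape[0]
    dists = np.empty(n, dtype=np.float64)
    idx = np.empty(n, dtype=np.int64)
    for i in range(n):
        d, t = min_distance_kernel(bb_min, bb_max, left, right, tri, tv0, tv1, tv2, pts[i])
        dists[i] = d
        idx[i] = t
    return dists, idx


@njit(cache=True, error_model="numpy")
def ray_parity_kernel(bb_min, bb_max, left, right, tri, tv0, tv1, tv2, p, d):
    """Count ray-triangle crossings for the ray p + t*d, t > 0.

    Returns (crossings, suspicious).  ``suspicious`` is set when a hit grazes
    a triangle edge/vertex, starts on the surface, or the ray is parallel to a
    nearby triangle plane — callers should retry with a different direction.
    """
    n_nodes = left.shape[0]
    stack = np.empty(n_nodes + 1, dtype=np.int64)
    top = 0
    stack[0] = 0
    dinv = np.empty(3, dtype=np.float64)
    for k in range(3):
        dinv[k] = np.inf if d[k] == 0.0 else 1.0 / d[k]
    count = 0
    suspicious = False
    while top >= 0:
        node = stack[top]
        top -= 1
        if not _ray_aabb_hit(p, dinv, bb_min[node], bb_max[node]):
            continue
        t = tri[node]
        if t < 0:
            top += 1
            stack[top] = left[node]
            top += 1
            stack[top] = right[node]
            continue
        ax, ay, az = tv0[t, 0], tv0[t, 1], tv0[t, 2]
        bx, by, bz = tv1[t, 0], tv1[t, 1], tv1[t, 2]
        cx, cy, cz = tv2[t, 0], tv2[t, 1], tv2[t, 2]
        e1x, e1y, e1z = bx - ax, by - ay, bz - az
        e2x, e2y, e2z = cx - ax, cy - ay, cz - az
        hx = d[1] * e2z - d[2] * e2y
        hy = d[2] * e2x - d[0] * e2z
        hz = d[0] * e2y - d[1] * e2x
        det = e1x * hx + e1y * hy + e1z * hz
        if -1e-12 < det < 1e-12:
            continue
        f = 1.0 / det
        sx, sy, sz = p[0] - ax, p[1] - ay, p[2] - az
        u = f * (sx * hx + sy * hy + sz * hz)
        if u < -BARY_EPS or u > 1.0 + BARY_EPS:
            continue
        qx = sy * e1z - sz * e1y
        qy = sz * e1x - sx * e1z
        qz = sx * e1y - sy * e1x
        v = f * (d[0] * qx + d[1] * qy + d[2] * qz)
        if v < -BARY_EPS or u + v > 1.0 + BARY_EPS:
            continue
        tpar = f * (e2x * qx + e2y * qy + e2z * qz)
        if tpar <= 1e-9:
            if tpar > -1e-9:
                suspicious = True  # origin on the surface
            continue
        if u < 1e-7 or v < 1e-7 or u + v > 1.0 - 1e-7:
            suspicious = True  # edge/vertex grazing
        count += 1
    return count, suspicious
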