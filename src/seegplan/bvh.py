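"""Linear bounding-volume hierarchy over one anatomical structure.

Construction follows the Morton-code (Z-order) recipe: every triangle is
assigned a 30-bit code by quantising its centroid to 10 bits per axis over
the structure's (slightly inflated) bounding box and bit-interleaving the
three integers (x in the lowest bits).  Triangles are sorted by code and the
hierarchy is built by recursively splitting each sorted run at the highest
bit in which its codes differ, until every leaf holds exactly one triangle.
Runs of identical codes are split at their index midpoint.  Node AABBs are
the exact triangle box at leaves and the union of the children elsewhere.

Two query types serve the planner: segment-structure intersection (stack
traversal, exact segment-triangle test at leaves) and point-structure
nearest distance (best-first traversal ordered by AABB distance with
pruning).  Both are exact up to the documented epsilon conventions in
:mod:`seegplan._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .mesh import TriangleMesh

__all__ = [
    "Bvh",
    "morton_code",
    "build_bvh",
    "segment_intersects",
    "min_distance",
    "min_distance_batch",
    "min_distance_crit",
    "min_distance_crit_batch",
    "signed_shell_distance",
]


def _expand_bits_10(v: np.ndarray) -> np.ndarray:
    """Spread the low 10 bits of each value so consecutive bits land 3 apart."""
    v = v.astype(np.uint32) & np.uint32(0x3FF)
    v = (v | (v << np.uint32(16))) & np.uint32(0x030000FF)
    v = (v | (v << np.uint32(8))) & np.uint32(0x0300F00F)
    v = (v | (v << np.uint32(4))) & np.uint32(0x030C30C3)
    v = (v | (v << np.uint32(2))) & np.uint32(0x09249249)
    return v


def quantize(points: np.ndarray, scene_bbox: np.ndarray) -> np.ndarray:
    """Affine map of each coordinate to an integer in [0, 1023] over the
    bbox extent.  A degenerate (zero-extent) axis quantises to 0."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    bmin = np.asarray(scene_bbox[0], dtype=np.float64)
    extent = np.asarray(scene_bbox[1], dtype=np.float64) - bmin
    q = np.zeros(points.shape, dtype=np.int64)
    for k in range(3):
        if extent[k] > 0:
            u = (points[:, k] - bmin[k]) / extent[k]
            q[:, k] = np.clip(np.floor(u * 1024.0), 0, 1023).astype(np.int64)
    return q


def morton_code(p: np.ndarray, scene_bbox: np.ndarray) -> int:
    """30-bit Morton code of a point: 10 bits per axis, x interleaved lowest."""
    return int(morton_codes(np.asarray(p, dtype=np.float64)[None, :], scene_bbox)[0])


def morton_codes(points: np.ndarray, scene_bbox: np.ndarray) -> np.ndarray:
    q = quantize(points, scene_bbox)
    x = _expand_bits_10(q[:, 0])
    y = _expand_bits_10(q[:, 1])
    z = _expand_bits_10(q[:, 2])
    return (x | (y << np.uint32(1)) | (z << np.uint32(2))).astype(np.int64)


@dataclass
class Bvh:
    """Morton-ordered hierarchy with per-node AABBs over one structure.

    ``left``/``right`` are -1 at leaves; ``tri_index`` is -1 at internal
    nodes.  Children always have a larger node index than their parent.
    """

    structure_name: str
    scene_bbox: np.ndarray  # (2, 3) box used for Morton quantisation
    bb_min: np.ndarray  # (n_nodes, 3)
    bb_max: np.ndarray
    left: np.ndarray  # (n_nodes,) int64
    right: np.ndarray
    tri_index: np.ndarray
    tv0: np.ndarray  # (n_faces, 3) triangle corners
    tv1: np.ndarray
    tv2: np.ndarray

    @property
    def n_nodes(self) -> int:
        return int(self.left.shape[0])

    @property
    def leaf_count(self) -> int:
        return int((self.tri_index >= 0).sum())


def _find_split(codes: np.ndarray, lo: int, hi: int) -> int:
    """Last index of the left child range for sorted codes[lo..hi]."""
    c_lo = int(codes[lo])
    c_hi = int(codes[hi])
    if c_lo == c_hi:
        return (lo + hi) // 2  # identical codes: midpoint split
    bit = (c_lo ^ c_hi).bit_length() - 1  # highest differing bit
    prefix = c_lo >> bit
    # binary search for the last index sharing c_lo's prefix above `bit`
    a, b = lo, hi
    while a + 1 < b:
        mid = (a + b) // 2
        if int(codes[mid]) >> bit == prefix:
            a = mid
        else:
            b = mid
    return a


def build_bvh(mesh: TriangleMesh, name: str | None = None) -> Bvh:
    """Build the hierarchy for ``mesh``; one triangle per leaf."""
    mesh.validate()
    v0, v1, v2 = mesh.triangle_vertices()
    m = mesh.n_faces
    centroids = (v0 + v1 + v2) / 3.0
    bounds = mesh.bounds()
    pad = 1e-6 * max(float((bounds[1] - bounds[0]).max()), 1.0)
    scene_bbox = np.vstack([bounds[0] - pad, bounds[1] + pad])
    codes = morton_codes(centroids, scene_bbox)
    order = np.lexsort((np.arange(m), codes))
    codes_sorted = codes[order]

    n_nodes = 2 * m - 1
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    tri = np.full(n_nodes, -1, dtype=np.int64)
    next_free = 1
    stack = [(0, m - 1, 0)]
    while stack:
        lo, hi, node = stack.pop()
        if lo == hi:
            tri[node] = order[lo]
            continue
        split = _find_split(codes_sorted, lo, hi)
        li, ri = next_free, next_free + 1
        next_free += 2
        left[node] = li
        right[node] = ri
        stack.append((lo, split, li))
        stack.append((split + 1, hi, ri))

    bb_min = np.empty((n_nodes, 3))
    bb_max = np.empty((n_nodes, 3))
    tri_min = np.minimum(np.minimum(v0, v1), v2)
    tri_max = np.maximum(np.maximum(v0, v1), v2)
    for node in range(n_nodes - 1, -1, -1):  # children have larger indices
        t = tri[node]
        if t >= 0:
            bb_min[node] = tri_min[t]
            bb_max[node] = tri_max[t]
        else:
            bb_min[node] = np.minimum(bb_min[left[node]], bb_min[right[node]])
            bb_max[node] = np.maximum(bb_max[left[node]], bb_max[right[node]])

    return Bvh(
        structure_name=name if name is not None else mesh.name,
        scene_bbox=scene_bbox,
        bb_min=bb_min,
        bb_max=bb_max,
        left=left,
        right=right,
        tri_index=tri,
        tv0=np.ascontiguousarray(v0),
        tv1=np.ascontiguousarray(v1),
        tv2=np.ascontiguousarray(v2),
    )


def segment_intersects(bvh: Bvh, segment, return_stats: bool = False):
    """True iff the closed segment (p0, p1) intersects any triangle."""
    p0 = np.ascontiguousarray(segment[0], dtype=np.float64)
    p1 = np.ascontiguousarray(segment[1], dtype=np.float64)
    hit, leaf_tests = _k.segment_intersects_kernel(
        bvh.bb_min, bvh.bb_max, bvh.left, bvh.right, bvh.tri_index,
        bvh.tv0, bvh.tv1, bvh.tv2, p0, p1,
    )
    if return_stats:
        return bool(hit), int(leaf_tests)
    return bool(hit)


def min_distance(bvh: Bvh, p) -> tuple[float, int]:
    """Exact minimum Euclidean distance from ``p`` to the structure surface
    and the index of the nearest triangle."""
    p = np.ascontiguousarray(p, dtype=np.float64)
    d, t = _k.min_distance_kernel(
        bvh.bb_min, bvh.bb_max, bvh.left, bvh.right, bvh.tri_index,
        bvh.tv0, bvh.tv1, bvh.tv2, p,
    )
    return float(d), int(t)


def min_distance_batch(bvh: Bvh, pts) -> tuple[np.ndarray, np.ndarray]:
    pts = np.ascontiguousarray(pts, dtype=np.float64).reshape(-1, 3)
    return _k.min_distance_batch_kernel(
        bvh.bb_min, bvh.bb_max, bvh.left, bvh.right, bvh.tri_index,
        bvh.tv0, bvh.tv1, bvh.tv2, pts,
    )


def min_distance_crit(bvhs: list[Bvh], p) -> tuple[float, str]:
    """f_crit(p): minimum over the listed (blood-vessel) structures of the
    point-surface distance, with the nearest structure's label.  Ties are
    broken by list order.  Sulci must not be passed here."""
    if not bvhs:
        raise ValueError("min_distance_crit: empty structure list (risk undefined)")
    best = np.inf
    label = bvhs[0].structure_name
    for b in bvhs:
        d, _ = min_distance(b, p)
        if d < best:
            best = d
            label = b.structure_name
    return float(best), label


def min_distance_crit_batch(bvhs: list[Bvh], pts) -> tuple[np.ndarray, np.ndarray]:
    """Vector f_crit over sample points; returns (distances, structure index
    into ``bvhs`` of the nearest structure, first-listed on ties)."""
    if not bvhs:
        raise ValueError("min_distance_crit: empty structure list (risk undefined)")
    pts = np.ascontiguousarray(pts, dtype=np.float64).reshape(-1, 3)
    all_d = np.empty((len(bvhs), len(pts)))
    for j, b in enumerate(bvhs):
        all_d[j], _ = min_distance_batch(b, pts)
    which = all_d.argmin(axis=0)  # argmin takes the first on ties
    return all_d[which, np.arange(len(pts))], which


def signed_shell_distance(gm, p) -> float:
    """Signed distance to the grey-matter shell: negative iff ``p`` lies
    between the outer (pial) and inner (white) surfaces.  Delegates to
    :meth:`seegplan.gm.GmModel.signed_distance`."""
    return float(gm.signed_distance(p))
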