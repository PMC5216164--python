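"""Grey-matter shell model: two nested closed surfaces with signed distance.

The shell is bounded by the outer (pial) and inner (white-matter) surfaces.
The signed shell distance is

    f_gm(p) = max(sd_outer(p), -sd_inner(p))

where sd_X is negative inside the closed surface X; f_gm is negative exactly
when p lies in the grey-matter shell, i.e. inside the pial surface but
outside the white surface.  Inside/outside is decided by ray-crossing parity
along a fixed oblique direction (retried along a second direction when the
first ray grazes an edge), magnitude by the exact BVH nearest distance.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as _k
from .bvh import Bvh, build_bvh, min_distance_batch
from .mesh import MeshValidationError, TriangleMesh

# fixed oblique parity rays; chosen off-axis to dodge axis-aligned geometry
_RAY_1 = np.array([1.0, 0.7, 0.3]) / np.linalg.norm([1.0, 0.7, 0.3])
_RAY_2 = np.array([-0.33, 0.54, 0.77]) / np.linalg.norm([-0.33, 0.54, 0.77])
_RAY_3 = np.array([0.21, -0.83, 0.51]) / np.linalg.norm([0.21, -0.83, 0.51])


def _contains(bvh: Bvh, p: np.ndarray) -> bool:
    for ray in (_RAY_1, _RAY_2, _RAY_3):
        count, suspicious = _k.ray_parity_kernel(
            bvh.bb_min, bvh.bb_max, bvh.left, bvh.right, bvh.tri_index,
            bvh.tv0, bvh.tv1, bvh.tv2, p, ray,
        )
        if not suspicious:
            return bool(count % 2 == 1)
    return bool(count % 2 == 1)  # all rays grazed: accept the last parity


class GmModel:
    """Nested pial/white surface pair with their BVHs.

    Raises :class:`MeshValidationError` if either surface is not closed or
    the inner surface is not (sampled check) strictly inside the outer one.
    """

    def __init__(self, outer: TriangleMesh, inner: TriangleMesh, check_nesting: bool = True):
        for m, which in ((outer, "outer"), (inner, "inner")):
            m.validate()
            if not m.is_closed():
                raise MeshValidationError(
                    f"GM {which} surface {m.name!r} is not a closed, "
                    "consistently wound surface"
                )
        self.outer = outer
        self.inner = inner
        self.outer_bvh = build_bvh(outer, name="gm_outer")
        self.inner_bvh = build_bvh(inner, name="gm_inner")
        if check_nesting:
            rng = np.random.default_rng(0)
            sample = inner.vertices[rng.choice(inner.n_vertices, size=min(32, inner.n_vertices), replace=False)]
            # pull sample points slightly toward the inner centroid so the
            # check probes strict interiority rather than surface grazing
            sample = sample + 1e-6 * (inner.centroid() - sample)
            for p in sample:
                if not _contains(self.outer_bvh, np.ascontiguousarray(p)):
                    raise MeshValidationError(
                        "GM inner surface is not strictly inside the outer surface"
                    )

    def signed_distance(self, p) -> float:
        return float(self.signed_distance_batch(np.asarray(p, dtype=np.float64))[0])

    def signed_distance_batch(self, pts) -> np.ndarray:
        """f_gm for each point: negative inside the grey-matter shell."""
        pts = np.ascontiguousarray(pts, dtype=np.float64).reshape(-1, 3)
        d_out, _ = min_distance_batch(self.outer_bvh, pts)
        d_in, _ = min_distance_batch(self.inner_bvh, pts)
        out = np.empty(len(pts))
        for i, p in enumerate(pts):
            sd_o = -d_out[i] if _contains(self.outer_bvh, p) else d_out[i]
            sd_i = -d_in[i] if _contains(self.inner_bvh, p) else d_in[i]
            out[i] = max(sd_o, -sd_i)
        return out

    def tissue(self, pts) -> list[str]:
        """Classify each point as ``GM`` (in the shell), ``WM`` (inside the
        white surface) or ``outside`` (outside the pial surface)."""
        pts = np.ascontiguousarray(pts, dtype=np.float64).reshape(-1, 3)
        labels = []
        for p in pts:
            if _contains(self.inner_bvh, p):
                labels.append("WM")
            elif _contains(self.outer_bvh, p):
                labels.append("GM")
            else:
                labels.append("outside")
        return labels
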