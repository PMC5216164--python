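"""Triangle-mesh and target-list I/O for trajectory-planning scenes.

All coordinates are millimetres in a single co-registered patient (or phantom)
space.  STL and PLY files carry no unit metadata; values are taken verbatim.
STL stores a triangle soup, so meshes are always welded on load: coordinates
are rounded to :data:`WELD_DECIMALS` decimals (1e-6 mm) and exact duplicates
merged.  The rounding makes the canonical form idempotent, so
save -> load -> save is byte-identical.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh as _tm

WELD_DECIMALS = 6  # vertex welding tolerance on load, in decimal digits of mm

_FORMATS = ("stl", "ply")


class MeshValidationError(ValueError):
    """A mesh violates a structural invariant (empty, bad indices, ...)."""


class TargetValidationError(ValueError):
    """A target list is malformed (duplicate names, non-numeric rows, ...)."""


@dataclass
class TriangleMesh:
    """An indexed triangle surface in millimetres.

    Parameters
    ----------
    vertices : (n, 3) float64 array
    faces : (m, 3) int64 array of indices into ``vertices``
    name : structure label, e.g. ``skull``, ``template``, ``vessel:3``,
        ``sulcus:0``, ``gm_outer``, ``gm_inner``
    vertex_normals : optional (n, 3) array of outward unit normals
    normals_valid : optional (n,) bool mask; False marks vertices with no
        incident face, which are excluded from entry candidacy
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = "mesh"
    vertex_normals: np.ndarray | None = None
    normals_valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError(f"{self.name}: vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError(f"{self.name}: faces must be (m, 3)")

    # -- basic queries -----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def bounds(self) -> np.ndarray:
        """(2, 3) axis-aligned bounding box [min; max]."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def triangle_vertices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-face corner arrays (v0, v1, v2), each (m, 3)."""
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_normals_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit face normals (m, 3) and face areas (m,)."""
        a, b, c = self.triangle_vertices()
        cr = np.cross(b - a, c - a)
        dbl = np.linalg.norm(cr, axis=1)
        areas = dbl / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            normals = np.where(dbl[:, None] > 0, cr / dbl[:, None], 0.0)
        return normals, areas

    def is_closed(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces and
        every directed edge appears exactly once (consistent winding)."""
        if self.n_faces == 0:
            return False
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        # consistent orientation: no directed edge repeats
        _, counts_d = np.unique(directed, axis=0, return_counts=True)
        if counts_d.max() > 1:
            return False
        und = np.sort(directed, axis=1)
        _, counts = np.unique(und, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def signed_volume(self) -> float:
        """Signed volume by divergence theorem; positive for outward winding."""
        a, b, c = self.triangle_vertices()
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def validate(self) -> None:
        """Raise :class:`MeshValidationError` on any invariant violation."""
        if self.n_vertices == 0 or self.n_faces == 0:
            raise MeshValidationError(f"{self.name}: empty mesh")
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshValidationError(f"{self.name}: face index out of range")
        _, areas = self.face_normals_areas()
        if (areas <= 0).any():
            raise MeshValidationError(f"{self.name}: zero-area face present")
        if self.vertex_normals is not None:
            valid = (
                self.normals_valid
                if self.normals_valid is not None
                else np.ones(self.n_vertices, bool)
            )
            lens = np.linalg.norm(self.vertex_normals[valid], axis=1)
            if lens.size and np.abs(lens - 1.0).max() > 1e-9:
                raise MeshValidationError(f"{self.name}: non-unit vertex normal")


def _weld(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Round to the welding tolerance, merge duplicate vertices, drop
    degenerate faces and unreferenced vertices."""
    v = np.round(np.asarray(vertices, dtype=np.float64), WELD_DECIMALS) + 0.0
    uniq, inverse = np.unique(v, axis=0, return_inverse=True)
    f = inverse[np.asarray(faces, dtype=np.int64)]
    # drop faces with repeated indices
    ok = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    f = f[ok]
    if len(f):
        a, b, c = uniq[f[:, 0]], uniq[f[:, 1]], uniq[f[:, 2]]
        areas = np.linalg.norm(np.cross(b - a, c - a), axis=1) / 2.0
        f = f[areas > 1e-12]
    if len(f):
        # drop duplicate faces (same vertex triple, any winding), keep first
        key = np.sort(f, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        f = f[np.sort(first)]
    # drop unreferenced vertices, remap
    used = np.unique(f)
    remap = np.full(len(uniq), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return uniq[used], remap[f]


def load_mesh(path: str | os.PathLike, fmt: str | None = None) -> TriangleMesh:
    """Read an STL (binary or ASCII) or PLY mesh and return a welded,
    cleaned :class:`TriangleMesh`.

    Raises ``OSError`` for missing/unreadable/unparsable files and
    :class:`MeshValidationError` if nothing remains after cleaning.
    """
    path = os.fspath(path)
    fmt = _infer_format(path, fmt)
    if not os.path.isfile(path):
        raise OSError(f"mesh file not found: {path}")
    if os.path.getsize(path) == 0:
        raise OSError(f"mesh file is empty (zero bytes): {path}")
    try:
        raw = _tm.load_mesh(path, file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - parser failures become I/O errors
        raise OSError(f"could not parse {fmt.upper()} file {path}: {exc}") from exc
    if isinstance(raw, _tm.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshValidationError(f"{path}: no geometry after cleaning")
        raw = _tm.util.concatenate(geoms)
    vertices, faces = _weld(np.asarray(raw.vertices), np.asarray(raw.faces))
    if len(vertices) == 0 or len(faces) == 0:
        raise MeshValidationError(f"{path}: empty mesh after cleaning")
    name = os.path.splitext(os.path.basename(path))[0]
    return TriangleMesh(vertices, faces, name=name)


def save_mesh(mesh: TriangleMesh, path: str | os.PathLike, fmt: str | None = None) -> str:
    """Write ``mesh`` as binary STL or ASCII PLY; returns the path written."""
    path = os.fspath(path)
    fmt = _infer_format(path, fmt)
    mesh.validate()
    if os.path.isdir(path):
        raise OSError(f"cannot write mesh to a directory: {path}")
    tm = _tm.Trimesh(mesh.vertices, mesh.faces, process=False)
    if fmt == "stl":
        data = tm.export(file_type="stl")
    else:
        data = _tm.exchange.ply.export_ply(tm, encoding="ascii")
    if isinstance(data, str):
        data = data.encode()
    try:
        with open(path, "wb") as fh:
            fh.write(data)
    except OSError:
        raise
    return path


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def compute_vertex_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy of ``mesh`` carrying outward unit vertex normals.

    Each vertex normal is the area-weighted mean of its incident face
    normals, renormalised.  For closed meshes outwardness is enforced
    globally: if the winding encloses negative volume all normals are
    flipped.  Vertices with no incident face get an invalid flag and are
    excluded from entry candidacy downstream.
    """
    fn, areas = mesh.face_normals_areas()
    weighted = fn * areas[:, None]
    acc = np.zeros_like(mesh.vertices)
    counts = np.zeros(mesh.n_vertices, dtype=np.int64)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], weighted)
        np.add.at(counts, mesh.faces[:, k], 1)
    lens = np.linalg.norm(acc, axis=1)
    valid = (counts > 0) & (lens > 1e-300)
    normals = np.zeros_like(acc)
    normals[valid] = acc[valid] / lens[valid, None]
    if mesh.is_closed() and mesh.signed_volume() < 0:
        normals = -normals
    return replace(mesh, vertex_normals=normals, normals_valid=valid)


# ---------------------------------------------------------------------------
# target lists


@dataclass
class TargetList:
    """Named intracerebral target points (mm), order-preserving."""

    names: list[str]
    points: np.ndarray  # (N, 3) float64
    max_targets: int = 32

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.names) != len(self.points):
            raise TargetValidationError("names and points length mismatch")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise TargetValidationError(f"duplicate target names: {dupes}")
        if not 1 <= len(self.names) <= self.max_targets:
            raise TargetValidationError(
                f"target count {len(self.names)} outside [1, {self.max_targets}]"
            )

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.points))


def load_targets(path: str | os.PathLike, max_targets: int = 32) -> TargetList:
    """Read targets from CSV (header ``name,x,y,z``) or a JSON array of
    ``{"name":..., "x":..., "y":..., "z":...}`` objects."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        names, pts = [], []
        for i, row in enumerate(rows):
            try:
                names.append(str(row["name"]))
                pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
            except (KeyError, TypeError, ValueError) as exc:
                raise TargetValidationError(f"{path}: bad entry at index {i}: {exc}") from exc
        return TargetList(names, np.asarray(pts, dtype=np.float64), max_targets=max_targets)
    df = pd.read_csv(path, dtype={"name": str})
    expected = ["name", "x", "y", "z"]
    if list(df.columns) != expected:
        raise TargetValidationError(f"{path}: header must be exactly {expected}")
    pts = np.empty((len(df), 3))
    for j, col in enumerate(("x", "y", "z")):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            raise TargetValidationError(
                f"{path}: non-numeric {col!r} at data row {int(bad[0]) + 1}"
            )
        pts[:, j] = vals.to_numpy(dtype=np.float64)
    return TargetList(list(df["name"]), pts, max_targets=max_targets)


def save_targets(targets: TargetList, path: str | os.PathLike) -> str:
    """Write targets as CSV with header ``name,x,y,z``."""
    path = os.fspath(path)
    buf = io.StringIO()
    buf.write("name,x,y,z\n")
    for name, p in targets:
        buf.write(f"{name},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return path
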