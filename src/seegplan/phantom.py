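"""Seeded synthetic head phantoms with known ground truth.

A phantom stands in for a segmented patient study: a closed quasi-spherical
skull with an admissible-entry template submesh (a polar cap minus a "face"
patch), tubular vessel trees of 0.5-2 mm radius swept along smooth random
space curves, thin inward-folded sulcal sheets hanging from the pial
surface, a nested two-surface grey-matter shell, and named intracerebral
targets.  Everything is generated from a single seeded random stream, so a
given (spec, seed) pair reproduces byte-identical meshes.

The phantoms reproduce the topology and scale of the clinical inputs, not
their anatomy: no atlas shapes, no imaging artefacts, no segmentation error.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from functools import cached_property

import numpy as np
import trimesh as _tm
from scipy.interpolate import CubicSpline

from .gm import GmModel
from .bvh import Bvh, build_bvh
from .mesh import (
    TriangleMesh,
    TargetList,
    compute_vertex_normals,
    load_mesh,
    load_targets,
    save_mesh,
    save_targets,
    _weld,
)

__all__ = ["PhantomSpec", "Scene", "generate_phantom", "make_tube", "planted_conflict_scene", "icosphere"]


@dataclass
class PhantomSpec:
    """Generator parameters; defaults emulate the clinical study conditions
    (skull entry set of 2000-10000 vertices, vessels of 0.5-2 mm radius,
    a 70/55 mm grey-matter shell inside an 85 mm skull, 8 targets)."""

    seed: int = 0
    skull_radius: float = 85.0
    skull_subdivisions: int = 4  # icosphere level; 4 -> 2562 vertices
    cap_polar_deg: float = 150.0  # template cap: vertices with polar angle below
    face_patch_deg: float = 25.0  # angular radius of the excluded "face" patch
    face_direction: tuple = (1.0, 0.0, 0.25)
    n_vessels: int = 6
    vessel_radius_range: tuple = (0.5, 2.0)
    vessel_sides: int = 12
    n_sulci: int = 4
    gm_outer_radius: float = 70.0
    gm_inner_radius: float = 55.0
    gm_subdivisions: int = 3
    gm_perturb_mm: float = 1.0  # smooth radial perturbation of the GM surfaces
    n_targets: int = 8
    targets: list | None = None  # optional explicit [(name, (x, y, z)), ...]
    target_min_separation: float = 24.0

    def validate(self) -> None:
        if not 0 < self.gm_inner_radius < self.gm_outer_radius < self.skull_radius:
            raise ValueError(
                "require 0 < gm_inner_radius < gm_outer_radius < skull_radius"
            )
        if self.n_vessels < 0 or self.n_sulci < 0:
            raise ValueError("structure counts must be non-negative")
        if self.vessel_radius_range[0] <= 0:
            raise ValueError("vessel radius must be positive")
        if self.targets is None and self.n_targets < 1:
            raise ValueError("need at least one target")


@dataclass
class Scene:
    """A co-registered planning scene (mm frame) with cached BVHs."""

    skull: TriangleMesh
    template: TriangleMesh
    vessels: list
    sulci: list
    gm: GmModel
    targets: TargetList
    ground_truth: dict | None = None
    spec: PhantomSpec | None = None

    @cached_property
    def vessel_bvhs(self) -> list[Bvh]:
        return [build_bvh(m) for m in self.vessels]

    @cached_property
    def sulci_bvhs(self) -> list[Bvh]:
        return [build_bvh(m) for m in self.sulci]

    @cached_property
    def critical_bvhs(self) -> list[Bvh]:
        """Intersection-gating structures: vessels AND sulci."""
        return self.vessel_bvhs + self.sulci_bvhs

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | os.PathLike) -> str:
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        manifest = {"roles": {}, "targets": "targets.csv", "seed": self.spec.seed if self.spec else None}
        if self.spec is not None:
            manifest["spec"] = asdict(self.spec)

        def put(mesh, stem, role):
            save_mesh(mesh, os.path.join(directory, stem + ".stl"))
            manifest["roles"][stem + ".stl"] = role

        put(self.skull, "skull", "skull")
        put(self.template, "template", "template")
        for i, v in enumerate(self.vessels):
            put(v, f"vessel_{i:02d}", "vessel")
        for i, s in enumerate(self.sulci):
            put(s, f"sulcus_{i:02d}", "sulcus")
        put(self.gm.outer, "gm_outer", "gm_outer")
        put(self.gm.inner, "gm_inner", "gm_inner")
        save_targets(self.targets, os.path.join(directory, "targets.csv"))
        if self.ground_truth is not None:
            manifest["ground_truth"] = _jsonable(self.ground_truth)
        with open(os.path.join(directory, "scene.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return directory

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "Scene":
        directory = os.fspath(directory)
        with open(os.path.join(directory, "scene.json")) as fh:
            manifest = json.load(fh)
        by_role: dict[str, list] = {}
        for fname, role in sorted(manifest["roles"].items()):
            mesh = load_mesh(os.path.join(directory, fname))
            mesh.name = os.path.splitext(fname)[0] if role in ("vessel", "sulcus") else role
            by_role.setdefault(role, []).append(mesh)
        template = compute_vertex_normals(by_role["template"][0])
        spec = None
        if "spec" in manifest:
            raw = dict(manifest["spec"])
            for key in ("face_direction", "vessel_radius_range"):
                if key in raw and raw[key] is not None:
                    raw[key] = tuple(raw[key])
            spec = PhantomSpec(**raw)
        return cls(
            skull=by_role["skull"][0],
            template=template,
            vessels=by_role.get("vessel", []),
            sulci=by_role.get("sulcus", []),
            gm=GmModel(by_role["gm_outer"][0], by_role["gm_inner"][0]),
            targets=load_targets(os.path.join(directory, manifest["targets"])),
            ground_truth=manifest.get("ground_truth"),
            spec=spec,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# primitive builders


def icosphere(subdivisions: int, radius: float, name: str = "sphere") -> TriangleMesh:
    """Geodesic sphere centred at the origin (outward winding)."""
    tm = _tm.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v, f = _weld(np.asarray(tm.vertices) * radius, np.asarray(tm.faces))
    return TriangleMesh(v, f, name=name)


def _smooth_radial_field(rng: np.random.Generator, n_terms: int = 3):
    """Smooth O(1) function on the unit sphere: sum of plane-wave sines."""
    axes = rng.normal(size=(n_terms, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    freqs = rng.uniform(1.0, 3.0, size=n_terms)
    phases = rng.uniform(0, 2 * np.pi, size=n_terms)
    amps = rng.uniform(0.5, 1.0, size=n_terms)
    amps /= amps.sum()

    def field_fn(unit_dirs: np.ndarray) -> np.ndarray:
        acc = np.zeros(len(unit_dirs))
        for a, fq, ph, amp in zip(axes, freqs, phases, amps):
            acc += amp * np.sin(fq * np.pi * (unit_dirs @ a) + ph)
        return acc

    return field_fn


def _perturbed_sphere(subdivisions: int, radius: float, amp_mm: float, field_fn, name: str) -> TriangleMesh:
    base = icosphere(subdivisions, 1.0, name)
    dirs = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    r = radius + amp_mm * field_fn(dirs)
    return TriangleMesh(dirs * r[:, None], base.faces, name=name)


def make_tube(curve, radius: float, sides: int = 12, name: str = "tube") -> TriangleMesh:
    """Closed capped tube of circular cross-section swept along a polyline.

    Ring frames are parallel-transported along the curve so the tube does
    not twist.  A self-intersecting curve tighter than the tube radius
    triggers a validation warning (the mesh is still returned)."""
    curve = np.asarray(curve, dtype=np.float64)
    if curve.ndim != 2 or len(curve) < 2:
        raise ValueError("tube curve needs at least 2 points")
    if radius <= 0:
        raise ValueError("tube radius must be positive")
    n = len(curve)
    # pinch warning: samples far apart along the curve but closer in space
    # than the tube diameter (a legitimate smooth bend cannot do this)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(curve, axis=0), axis=1))])
    min_arc_gap = np.pi * radius + 2 * radius
    pinched = False
    for i in range(n):
        for j in range(i + 1, n):
            if arc[j] - arc[i] <= min_arc_gap:
                continue
            if np.linalg.norm(curve[i] - curve[j]) < 2 * radius:
                pinched = True
                break
        if pinched:
            break
    if pinched:
        warnings.warn("tube curve self-approaches tighter than its radius")

    tangents = np.gradient(curve, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial normal: any vector orthogonal to the first tangent
    ref = np.array([0.0, 0.0, 1.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normal = np.cross(tangents[0], ref)
    normal /= np.linalg.norm(normal)
    theta = 2 * np.pi * np.arange(sides) / sides
    rings = np.empty((n, sides, 3))
    for i in range(n):
        if i > 0:  # parallel transport: re-project the previous normal
            normal = normal - (normal @ tangents[i]) * tangents[i]
            normal /= np.linalg.norm(normal)
        binormal = np.cross(tangents[i], normal)
        rings[i] = (
            curve[i][None, :]
            + radius * np.cos(theta)[:, None] * normal[None, :]
            + radius * np.sin(theta)[:, None] * binormal[None, :]
        )
    verts = [rings.reshape(-1, 3), curve[0][None, :], curve[-1][None, :]]
    vertices = np.vstack(verts)
    c0 = n * sides  # start-cap centre index
    c1 = n * sides + 1
    faces = []
    for i in range(n - 1):
        for k in range(sides):
            a = i * sides + k
            b = i * sides + (k + 1) % sides
            c = (i + 1) * sides + k
            d = (i + 1) * sides + (k + 1) % sides
            faces.append([a, b, d])
            faces.append([a, d, c])
    for k in range(sides):  # start cap, wound to face outward (-tangent)
        faces.append([c0, (k + 1) % sides, k])
    base = (n - 1) * sides
    for k in range(sides):  # end cap (+tangent)
        faces.append([c1, base + k, base + (k + 1) % sides])
    v, f = _weld(vertices, np.asarray(faces))
    return TriangleMesh(v, f, name=name)


def _sulcus_sheet(rng: np.random.Generator, gm_radius: float, name: str) -> TriangleMesh:
    """Thin folded open ribbon attached to the pial surface, dipping inward."""
    u0 = _random_unit(rng, max_polar_deg=120.0)
    t0 = np.cross(u0, _random_unit(rng))
    t0 /= np.linalg.norm(t0)
    arc_len = rng.uniform(30.0, 50.0)
    depth = rng.uniform(10.0, 15.0)
    fold = rng.uniform(1.0, 3.0)
    n_u, n_v = 16, 6
    s = np.linspace(0, arc_len / gm_radius, n_u)
    verts = np.empty((n_u, n_v, 3))
    for i, si in enumerate(s):
        d = u0 * np.cos(si) + t0 * np.sin(si)
        d /= np.linalg.norm(d)
        tang = -u0 * np.sin(si) + t0 * np.cos(si)
        lateral = np.cross(d, tang)
        lateral /= np.linalg.norm(lateral)
        for jv, v in enumerate(np.linspace(0.0, 1.0, n_v)):
            r = gm_radius + 1.0 - v * (depth + 1.0)
            wobble = fold * np.sin(np.pi * v) * np.sin(3.0 * si * gm_radius / arc_len)
            verts[i, jv] = d * r + lateral * wobble
    faces = []
    for i in range(n_u - 1):
        for jv in range(n_v - 1):
            a = i * n_v + jv
            b = a + 1
            c = (i + 1) * n_v + jv
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    v, f = _weld(verts.reshape(-1, 3), np.asarray(faces))
    return TriangleMesh(v, f, name=name)


def _random_unit(rng: np.random.Generator, max_polar_deg: float = 180.0) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            continue
        v = v / norm
        if np.degrees(np.arccos(np.clip(v[2], -1, 1))) <= max_polar_deg:
            return v


def _vessel_curve(rng: np.random.Generator, r_start: float) -> np.ndarray:
    """Smooth space curve from just under the pial surface toward deep brain."""
    start = _random_unit(rng, max_polar_deg=100.0) * r_start
    end = _random_unit(rng) * rng.uniform(25.0, 40.0)
    ctrl = [start]
    for t in (0.25, 0.5, 0.75):
        p = start + t * (end - start)
        ctrl.append(p + rng.normal(scale=6.0, size=3))
    ctrl.append(end)
    ctrl = np.asarray(ctrl)
    spline = CubicSpline(np.linspace(0, 1, len(ctrl)), ctrl, axis=0)
    return spline(np.linspace(0, 1, 24))


def _template_submesh(skull: TriangleMesh, spec: PhantomSpec) -> TriangleMesh:
    """Admissible-entry submesh: polar cap minus the "face" patch, realised
    as the faces whose three vertices are all admissible."""
    v = skull.vertices
    dirs = v / np.linalg.norm(v, axis=1, keepdims=True)
    polar = np.degrees(np.arccos(np.clip(dirs[:, 2], -1, 1)))
    face_dir = np.asarray(spec.face_direction, dtype=np.float64)
    face_dir /= np.linalg.norm(face_dir)
    ang_face = np.degrees(np.arccos(np.clip(dirs @ face_dir, -1, 1)))
    admissible = (polar < spec.cap_polar_deg) & (ang_face > spec.face_patch_deg)
    keep_faces = admissible[skull.faces].all(axis=1)
    faces = skull.faces[keep_faces]
    used = np.unique(faces)
    remap = np.full(skull.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = TriangleMesh(v[used], remap[faces], name="template")
    return compute_vertex_normals(sub)


def _entry_feasibility_count(template: TriangleMesh, p: np.ndarray,
                             d_length: float = 80.0, d_angle: float = 25.0) -> int:
    """How many template vertices satisfy the hard entry constraints for a
    prospective target (used to avoid planting unreachable targets)."""
    d = p[None, :] - template.vertices
    lengths = np.linalg.norm(d, axis=1)
    ok_len = (lengths < d_length) & (lengths > 0)
    with np.errstate(invalid="ignore"):
        u = d / np.where(lengths[:, None] > 0, lengths[:, None], 1.0)
    cos_ang = -np.einsum("ij,ij->i", u, template.vertex_normals)
    ok = ok_len & (cos_ang > np.cos(np.radians(d_angle))) & template.normals_valid
    return int(ok.sum())


def _place_targets(rng: np.random.Generator, spec: PhantomSpec, template: TriangleMesh) -> TargetList:
    r_lo = spec.gm_inner_radius + 3.0
    r_hi = spec.gm_outer_radius - 4.0
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < spec.n_targets:
        tries += 1
        if tries > 20000:
            raise RuntimeError("could not place targets with the requested separation")
        d = _random_unit(rng, max_polar_deg=75.0)
        p = d * rng.uniform(r_lo, r_hi)
        if any(np.linalg.norm(p - q) < spec.target_min_separation for q in pts):
            continue
        if _entry_feasibility_count(template, p) < 3:
            continue  # angle cone misses the admissible template region
        pts.append(p)
    names = [f"T{i + 1}" for i in range(len(pts))]
    return TargetList(names, np.asarray(pts))


def generate_phantom(spec: PhantomSpec) -> Scene:
    """Build a deterministic scene from ``spec`` (one seeded stream)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    skull = icosphere(spec.skull_subdivisions, spec.skull_radius, name="skull")
    skull = compute_vertex_normals(skull)
    template = _template_submesh(skull, spec)

    field_fn = _smooth_radial_field(rng)
    gm_outer = _perturbed_sphere(spec.gm_subdivisions, spec.gm_outer_radius, spec.gm_perturb_mm, field_fn, "gm_outer")
    gm_inner = _perturbed_sphere(spec.gm_subdivisions, spec.gm_inner_radius, spec.gm_perturb_mm, field_fn, "gm_inner")
    gm = GmModel(gm_outer, gm_inner)

    vessels = []
    for i in range(spec.n_vessels):
        curve = _vessel_curve(rng, spec.gm_outer_radius + 2.0)
        radius = rng.uniform(*spec.vessel_radius_range)
        vessels.append(make_tube(curve, radius, sides=spec.vessel_sides, name=f"vessel:{i}"))

    sulci = [_sulcus_sheet(rng, spec.gm_outer_radius, f"sulcus:{i}") for i in range(spec.n_sulci)]

    if spec.targets is not None:
        names = [t[0] for t in spec.targets]
        pts = np.asarray([t[1] for t in spec.targets], dtype=np.float64)
        targets = TargetList(names, pts)
    else:
        targets = _place_targets(rng, spec, template)
    skull_r = np.linalg.norm(skull.vertices, axis=1).min()
    if (np.linalg.norm(targets.points, axis=1) >= skull_r).any():
        raise ValueError("a target lies outside the skull")

    return Scene(
        skull=skull,
        template=template,
        vessels=vessels,
        sulci=sulci,
        gm=gm,
        targets=targets,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# planted-conflict construction


def planted_conflict_scene(seed: int = 0) -> Scene:
    """Scene where the two targets' independently best (STP) trajectories
    are forced through one narrow opening and therefore conflict, while a
    second, moderately riskier corridor exists for target B.

    A spherical "shield" sheet at 75 mm (labelled as a sulcus, so it gates
    intersection without contributing risk) blocks every approach except a
    4 mm hole on the axis shared by both targets and a second hole over B's
    alternative corridor; a vessel runs alongside the alternative corridor
    at ~6 mm so its risk lands in a higher stratified bin.  ground_truth
    records the planted conflict-free assignment."""
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(seed=seed, n_vessels=1, n_sulci=1, n_targets=2, gm_perturb_mm=0.0)

    A = np.array([-6.0, 0.0, 21.0])
    B = np.array([6.0, 0.0, 21.0])
    d_shared = np.array([0.0, 0.0, 1.0])  # both head for the axial hole
    d_alt = np.array([0.40, 0.0, 1.0])
    d_alt /= np.linalg.norm(d_alt)

    skull = compute_vertex_normals(icosphere(4, spec.skull_radius, name="skull"))
    template = _template_submesh(skull, spec)
    gm = GmModel(
        icosphere(3, spec.gm_outer_radius, "gm_outer"),
        icosphere(3, spec.gm_inner_radius, "gm_inner"),
    )

    shield_r = 75.0
    hole_main = _ray_sphere_point((A + B) / 2.0, d_shared, shield_r)
    hole_alt = _ray_sphere_point(B, d_alt, shield_r)
    shield = _shield_sheet(shield_r, holes=[(hole_main, 4.0), (hole_alt, 6.0)])

    # vessel parallel to the alternative corridor, offset 6 mm in +y
    offset = np.array([0.0, 6.0, 0.0])
    curve = np.array([B + 15.0 * d_alt + offset, B + 60.0 * d_alt + offset])
    curve = np.linspace(curve[0], curve[1], 12) + rng.normal(scale=1e-9, size=(12, 3))
    vessel = make_tube(curve, radius=1.0, sides=24, name="vessel:0")

    targets = TargetList(["A", "B"], np.vstack([A, B]))
    ground_truth = {
        "conflict_pair": ["A", "B"],
        "planted_directions": {"A": d_shared, "B_primary": d_shared, "B_alternative": d_alt},
        "resolution": "advance B to its alternative corridor",
        "hole_main_mm": hole_main,
        "hole_alt_mm": hole_alt,
    }
    return Scene(
        skull=skull,
        template=template,
        vessels=[vessel],
        sulci=[shield],
        gm=gm,
        targets=targets,
        ground_truth=ground_truth,
        spec=spec,
    )


def _ray_sphere_point(origin: np.ndarray, direction: np.ndarray, radius: float) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    b = origin @ d
    t = -b + np.sqrt(b * b - (origin @ origin - radius * radius))
    return origin + t * d


def _shield_sheet(radius: float, holes: list) -> TriangleMesh:
    """Open spherical sheet with circular openings (labelled as a sulcus)."""
    base = icosphere(5, radius, name="sulcus:shield")
    a, b, c = base.triangle_vertices()
    centroids = (a + b + c) / 3.0
    cd = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    keep = np.ones(base.n_faces, dtype=bool)
    # open the bottom so the sheet is not a closed surface
    keep &= cd[:, 2] > np.cos(np.radians(150.0))
    for centre, hole_radius in holes:
        hd = centre / np.linalg.norm(centre)
        ang = np.arccos(np.clip(cd @ hd, -1, 1))
        keep &= ang > hole_radius / radius
    faces = base.faces[keep]
    used = np.unique(faces)
    remap = np.full(base.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(base.vertices[used], remap[faces], name="sulcus:shield")
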