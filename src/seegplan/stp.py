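"""Single-trajectory planning (STP) for one intracerebral target.

Pipeline: entry-candidate search on the skull template under the two hard
constraints (trajectory length < d_length, entry angle < d_angle), removal
of trajectories intersecting any critical structure (arteries, veins or
sulci), cumulative vessel-proximity risk scoring, grey-matter sampling
(GM-WM ratio), and stratified ranking.

Risk model.  Along the trajectory, sampled at ``n_samples`` evenly spaced
points, the distance to the nearest blood vessel f_crit(x) is accumulated as

    S_crit = ∫ d_risk − clamp(f_crit(x), d_safety, d_risk) dx

(composite trapezoid over the samples) and normalised to

    R = S_crit / ((d_risk − d_safety) · length) ∈ [0, 1].

A trajectory whose sampled f_crit ever drops below the safety margin
d_safety scores R = 1 outright; one that stays beyond the risk zone d_risk
everywhere scores R = 0.  Sulci gate the intersection test but are excluded
from f_crit.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .bvh import Bvh, min_distance_crit_batch, segment_intersects
from .gm import GmModel

__all__ = [
    "PlanningConfig",
    "TrajectoryCandidate",
    "RiskProfile",
    "CandidateSet",
    "EntrySearchError",
    "TargetUnreachableError",
    "find_entry_candidates",
    "sample_trajectory",
    "reject_intersecting",
    "risk_profile",
    "risk_score",
    "gm_wm_ratio",
    "stratified_rank",
    "plan_single",
    "export_profile_csv",
]


class EntrySearchError(RuntimeError):
    """No template vertex satisfies the hard entry constraints."""


class TargetUnreachableError(RuntimeError):
    """Every entry candidate was eliminated before ranking."""

    def __init__(self, target_id: str, counts: dict[str, int]):
        self.target_id = target_id
        self.counts = counts
        stages = ", ".join(f"{k}={v}" for k, v in counts.items())
        super().__init__(f"target {target_id!r} unreachable ({stages})")


@dataclass
class PlanningConfig:
    """Planner parameters.  Defaults are the clinically validated values:
    d_length 80 mm (longest electrode), d_angle 25 deg (drillable angle),
    d_safety 3 mm (safety margin, R=1 below), d_risk 10 mm (risk zone, R=0
    above), d_traj 10 mm (electrode-conflict distance), 10 contacts at 6 mm
    intervals from the tip with sampling radius 1.2 mm, K=10 risk bins, and
    128 samples along each trajectory."""

    d_length: float = 80.0  # mm, maximum electrode length
    d_angle: float = 25.0  # degrees, maximum drilling angle vs skull normal
    d_safety: float = 3.0  # mm, safety margin
    d_risk: float = 10.0  # mm, risk zone
    d_traj: float = 10.0  # mm, minimum inter-electrode distance
    contacts: int = 10  # J, electrode contact count
    contact_spacing: float = 6.0  # mm between contact centres, from the tip
    contact_radius: float = 1.2  # mm, c_r sampling radius
    risk_bins: int = 10  # K, stratified-ranking histogram bins
    n_samples: int = 128  # samples along the trajectory
    risk_integrand: str = "clamped"  # "clamped" | "literal"
    ranking: str = "stratified"  # "stratified" | "risk_only"
    max_pool_expansions: int = 100_000  # MTP livelock guard

    def __post_init__(self) -> None:
        if not 0 < self.d_safety < self.d_risk:
            raise ValueError("require 0 < d_safety < d_risk")
        if self.d_length <= 0:
            raise ValueError("d_length must be positive")
        if not 0 < self.d_angle < 90:
            raise ValueError("d_angle must lie in (0, 90) degrees")
        if self.contacts < 1 or self.risk_bins < 1 or self.n_samples < 2:
            raise ValueError("require contacts >= 1, risk_bins >= 1, n_samples >= 2")
        if self.risk_integrand not in ("clamped", "literal"):
            raise ValueError("risk_integrand must be 'clamped' or 'literal'")
        if self.ranking not in ("stratified", "risk_only"):
            raise ValueError("ranking must be 'stratified' or 'risk_only'")


@dataclass
class RiskProfile:
    """f_crit sampled along one trajectory, entry (arc 0) to target."""

    arc_positions: np.ndarray  # (n,) mm in [0, length]
    f_crit_values: np.ndarray  # (n,) mm; +inf when no vessels exist
    nearest_labels: list[str]
    s_crit: float  # mm^2 accumulated risk integral
    safety_violated: bool

    @property
    def length(self) -> float:
        return float(self.arc_positions[-1])


@dataclass
class TrajectoryCandidate:
    """One admissible electrode trajectory for a target."""

    target_id: str
    T: np.ndarray
    E: np.ndarray
    entry_vertex: int
    length: float
    angle: float  # degrees vs inward template normal
    R: float
    G: float
    rank: int = 0  # 1-based stratified rank a_i; 0 before ranking

    @property
    def segment(self) -> tuple[np.ndarray, np.ndarray]:
        return self.E, self.T


@dataclass
class CandidateSet:
    """All ranked candidates for one target, rank 1 first."""

    target_id: str
    candidates: list[TrajectoryCandidate]
    elimination: dict[str, int] = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.candidates)

    def __getitem__(self, i: int) -> TrajectoryCandidate:
        return self.candidates[i]


# ---------------------------------------------------------------------------
# pipeline stages


def find_entry_candidates(template, T, cfg: PlanningConfig) -> np.ndarray:
    """Indices of template vertices passing the length and angle hard
    constraints (both strict).  These cheap tests run before any BVH work."""
    if template.vertex_normals is None:
        raise ValueError("template mesh needs vertex normals (compute_vertex_normals)")
    T = np.asarray(T, dtype=np.float64)
    valid = (
        template.normals_valid
        if template.normals_valid is not None
        else np.ones(template.n_vertices, bool)
    )
    d = T - template.vertices
    lengths = np.linalg.norm(d, axis=1)
    pass_len = (lengths < cfg.d_length) & (lengths > 0)
    with np.errstate(invalid="ignore"):
        u = d / np.where(lengths[:, None] > 0, lengths[:, None], 1.0)
    # angle between E->T and the inward normal (-n_outward) at E
    cos_ang = -np.einsum("ij,ij->i", u, template.vertex_normals)
    pass_ang = cos_ang > math.cos(math.radians(cfg.d_angle))
    idx = np.nonzero(valid & pass_len & pass_ang)[0]
    if len(idx) == 0:
        n_len = int((valid & pass_len).sum())
        blocker = "entry angle" if n_len else "trajectory length"
        raise EntrySearchError(
            f"no feasible entry: all {template.n_vertices} template vertices "
            f"eliminated; last surviving constraint was {blocker} "
            f"({n_len} passed the length test)"
        )
    return idx


def sample_trajectory(E, T, n: int) -> np.ndarray:
    """n points evenly spaced from E (entry) to T (target), inclusive."""
    E = np.asarray(E, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.array_equal(E, T):
        raise ValueError("degenerate trajectory: entry equals target")
    t = np.linspace(0.0, 1.0, n)
    return E[None, :] + t[:, None] * (T - E)[None, :]


def reject_intersecting(entries: np.ndarray, template, T, critical_bvhs: list[Bvh]) -> np.ndarray:
    """Keep only entry vertices whose trajectory to T intersects no critical
    structure (arteries, veins AND sulci all gate here)."""
    T = np.asarray(T, dtype=np.float64)
    keep = []
    for e in entries:
        seg = (template.vertices[e], T)
        if not any(segment_intersects(b, seg) for b in critical_bvhs):
            keep.append(e)
    return np.asarray(keep, dtype=np.int64)


def risk_profile(E, T, vessel_bvhs: list[Bvh], cfg: PlanningConfig) -> RiskProfile:
    """Evaluate f_crit at the sample points and accumulate S_crit.

    Only blood vessels are passed here (sulci are excluded from f_crit).
    With no vessel structures at all the profile is risk-free (f_crit = inf,
    S_crit = 0)."""
    pts = sample_trajectory(E, T, cfg.n_samples)
    length = float(np.linalg.norm(np.asarray(T, float) - np.asarray(E, float)))
    if vessel_bvhs:
        f, which = min_distance_crit_batch(vessel_bvhs, pts)
        labels = [vessel_bvhs[j].structure_name for j in which]
    else:
        f = np.full(cfg.n_samples, np.inf)
        labels = ["none"] * cfg.n_samples
    safety_violated = bool((f < cfg.d_safety).any())
    if cfg.risk_integrand == "clamped":
        integrand = cfg.d_risk - np.clip(f, cfg.d_safety, cfg.d_risk)
    else:  # literal variant, upper clamp only (for comparison)
        integrand = cfg.d_risk - (np.minimum(f, cfg.d_risk) - cfg.d_safety)
    dx = length / (cfg.n_samples - 1)
    s_crit = float(np.trapezoid(integrand, dx=dx))
    arc = np.linspace(0.0, length, cfg.n_samples)
    return RiskProfile(arc, f, labels, s_crit, safety_violated)


def risk_score(profile: RiskProfile, cfg: PlanningConfig) -> float:
    """Normalised risk R in [0, 1] (clamped integrand); R = 1 on safety
    violation."""
    if profile.length <= 0:
        raise ValueError("zero-length trajectory has no defined risk")
    if profile.safety_violated:
        return 1.0
    return float(profile.s_crit / ((cfg.d_risk - cfg.d_safety) * profile.length))


def gm_wm_ratio(E, T, gm: GmModel, cfg: PlanningConfig) -> float:
    """Fraction of contact evaluation points inside the grey-matter shell.

    Contact centres sit at (j-1)*contact_spacing from the tip T toward E;
    each contributes three axial evaluation points c_j - c_r, c_j, c_j + c_r.
    Points beyond the entry (short trajectories) count as non-GM."""
    E = np.asarray(E, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    length = np.linalg.norm(E - T)
    if length <= 0:
        raise ValueError("degenerate trajectory: entry equals target")
    u = (E - T) / length  # tip toward entry
    offsets = []
    for j in range(cfg.contacts):
        c = (j) * cfg.contact_spacing
        offsets.extend([c - cfg.contact_radius, c, c + cfg.contact_radius])
    pts = T[None, :] + np.asarray(offsets)[:, None] * u[None, :]
    f = gm.signed_distance_batch(pts)
    return float((f < 0).sum() / (3.0 * cfg.contacts))


def stratified_rank(candidates: list[TrajectoryCandidate], K: int) -> list[TrajectoryCandidate]:
    """Order candidates by K equal-width risk bins over [0, 1] (ascending),
    then by GM-WM ratio descending within each bin; assign ranks 1..M.

    Ties are broken by entry-vertex index for determinism."""
    def bin_of(r: float) -> int:
        return min(int(r * K), K - 1)

    ordered = sorted(candidates, key=lambda c: (bin_of(c.R), -c.G, c.entry_vertex))
    for i, c in enumerate(ordered):
        c.rank = i + 1
    return ordered


def _risk_only_rank(candidates: list[TrajectoryCandidate]) -> list[TrajectoryCandidate]:
    ordered = sorted(candidates, key=lambda c: (c.R, c.entry_vertex))
    for i, c in enumerate(ordered):
        c.rank = i + 1
    return ordered


def plan_single(target, scene, cfg: PlanningConfig | None = None, target_id: str | None = None) -> CandidateSet:
    """Run the full STP pipeline for one target point.

    ``scene`` must expose ``template`` (with normals), ``critical_bvhs``
    (vessels + sulci), ``vessel_bvhs`` and ``gm``.  The STP answer is the
    rank-1 candidate of the returned set."""
    cfg = cfg or PlanningConfig()
    T = np.asarray(target, dtype=np.float64)
    tid = target_id or "target"
    counts: dict[str, int] = {"template_vertices": scene.template.n_vertices}
    try:
        entries = find_entry_candidates(scene.template, T, cfg)
    except EntrySearchError:
        counts.update({"after_length_angle": 0, "after_intersection": 0, "ranked": 0})
        raise TargetUnreachableError(tid, counts)
    counts["after_length_angle"] = len(entries)
    entries = reject_intersecting(entries, scene.template, T, scene.critical_bvhs)
    counts["after_intersection"] = len(entries)
    if len(entries) == 0:
        counts["ranked"] = 0
        raise TargetUnreachableError(tid, counts)

    candidates = []
    for e in entries:
        E = scene.template.vertices[e]
        prof = risk_profile(E, T, scene.vessel_bvhs, cfg)
        R = risk_score(prof, cfg)
        G = gm_wm_ratio(E, T, scene.gm, cfg)
        u = (T - E) / np.linalg.norm(T - E)
        cos_ang = float(np.clip(-np.dot(u, scene.template.vertex_normals[e]), -1.0, 1.0))
        candidates.append(
            TrajectoryCandidate(
                target_id=tid,
                T=T,
                E=E.copy(),
                entry_vertex=int(e),
                length=float(np.linalg.norm(T - E)),
                angle=math.degrees(math.acos(cos_ang)),
                R=R,
                G=G,
            )
        )
    if cfg.ranking == "stratified":
        ordered = stratified_rank(candidates, cfg.risk_bins)
    else:
        ordered = _risk_only_rank(candidates)
    counts["ranked"] = len(ordered)
    return CandidateSet(tid, ordered, elimination=counts)


def export_profile_csv(E, T, scene, cfg: PlanningConfig, path: str | os.PathLike | None = None) -> str:
    """Per-trajectory profile: arc position, f_crit, nearest structure and
    tissue class (GM/WM/outside) at each sample.  Returns the CSV text, and
    writes it to ``path`` when given."""
    cfg = cfg or PlanningConfig()
    prof = risk_profile(E, T, scene.vessel_bvhs, cfg)
    pts = sample_trajectory(E, T, cfg.n_samples)
    tissue = scene.gm.tissue(pts)
    buf = io.StringIO()
    buf.write("arc_mm,f_crit_mm,nearest_structure,tissue\n")
    for a, f, lab, tis in zip(prof.arc_positions, prof.f_crit_values, prof.nearest_labels, tissue):
        fs = "inf" if np.isinf(f) else f"{f:.6f}"
        buf.write(f"{a:.6f},{fs},{lab},{tis}\n")
    text = buf.getvalue()
    if path is not None:
        with open(os.fspath(path), "w") as fh:
            fh.write(text)
    return text
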