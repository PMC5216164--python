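"""Multiple-trajectory planning (MTP): joint, conflict-aware selection.

Given a stratified-ranked candidate set per target, MTP returns one
trajectory per target minimising the mean risk

    R_total = (1/N) Σ R_{i,a_i}   s.t.   D(seg_i, seg_j) > d_traj  ∀ i ≠ j,

where D is the minimum Euclidean distance between two electrode segments.
The search is a depth-first iterative deepening over electrodes with a
dynamic-programming pool of low-risk partial plans per depth.  At depth n
the incumbent best (n-1)-plan is extended with the new target's rank-1
candidate; while the lowest-mean-risk plan in the depth-n pool has a
conflict (i, n), three successors are enqueued: the next-best unused
alternative from the depth-i pool re-extended greedily through depths
i+1..n, the variant advancing the newest electrode's candidate (a_n + 1),
and the variant advancing the other conflict participant (a_i + 1).  Pools
persist across depths to serve the retrieval steps and are consumed
destructively; every pop is recorded in the audit log.  The first
conflict-free pool minimum at depth N is returned (feasibility guaranteed;
global optimality is monitored against the exhaustive oracle in tests, not
claimed).
"""

from __future__ import annotations

import heapq
import itertools
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .stp import CandidateSet, PlanningConfig, TrajectoryCandidate

__all__ = [
    "Plan",
    "ConflictReport",
    "PlannerState",
    "UnplannableError",
    "min_segment_distance",
    "detect_conflict",
    "plan_multiple",
    "exhaustive_plan",
    "plan_to_dict",
]


class UnplannableError(RuntimeError):
    """No conflict-free assignment could be constructed."""

    def __init__(self, message: str, target_id: str | None = None, blocking=None):
        super().__init__(message)
        self.target_id = target_id
        self.blocking = blocking or []


@dataclass(frozen=True)
class ConflictReport:
    """Closest violating electrode pair (indices into the target order)."""

    i: int
    j: int
    distance: float


@dataclass
class Plan:
    """One selected candidate per target (indices are 0-based into each
    target's ranked candidate list; rank a_i = selection + 1)."""

    target_ids: tuple[str, ...]
    selections: tuple[int, ...]
    mean_risk: float
    conflict_free: bool
    n: int
    expansions: int = 0
    conflicts_resolved: int = 0

    def candidate(self, sets: list[CandidateSet], i: int) -> TrajectoryCandidate:
        return sets[i][self.selections[i]]


@dataclass
class PlannerState:
    """Pools of partial plans per depth plus the audit log of pops."""

    pools: dict[int, list] = field(default_factory=dict)
    seen: dict[int, set] = field(default_factory=dict)
    expansions: int = 0
    audit: list[dict] = field(default_factory=list)


def min_segment_distance(a, b) -> float:
    """Exact minimum Euclidean distance between two closed 3-D segments
    (clamped closest-point parametrisation).  Degenerate segments are
    treated as points."""
    p1 = np.asarray(a[0], dtype=np.float64)
    q1 = np.asarray(a[1], dtype=np.float64)
    p2 = np.asarray(b[0], dtype=np.float64)
    q2 = np.asarray(b[1], dtype=np.float64)
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    aa = float(d1 @ d1)
    ee = float(d2 @ d2)
    ff = float(d2 @ r)
    EPS = 1e-14
    if aa <= EPS and ee <= EPS:
        return float(np.linalg.norm(r))
    if aa <= EPS:
        s = 0.0
        t = min(1.0, max(0.0, ff / ee))
    else:
        cc = float(d1 @ r)
        if ee <= EPS:
            t = 0.0
            s = min(1.0, max(0.0, -cc / aa))
        else:
            bb = float(d1 @ d2)
            denom = aa * ee - bb * bb
            s = min(1.0, max(0.0, (bb * ff - cc * ee) / denom)) if denom > EPS else 0.0
            t = (bb * s + ff) / ee
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -cc / aa))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (bb - cc) / aa))
    closest1 = p1 + s * d1
    closest2 = p2 + t * d2
    return float(np.linalg.norm(closest1 - closest2))


class _PairCache:
    """Lazy pairwise segment distances between candidates of different targets."""

    def __init__(self, sets: list[CandidateSet]):
        self.sets = sets
        self._cache: dict[tuple[int, int, int, int], float] = {}

    def dist(self, i: int, ai: int, j: int, aj: int) -> float:
        if i > j:
            i, ai, j, aj = j, aj, i, ai
        key = (i, ai, j, aj)
        d = self._cache.get(key)
        if d is None:
            d = min_segment_distance(self.sets[i][ai].segment, self.sets[j][aj].segment)
            self._cache[key] = d
        return d


def detect_conflict(plan, sets: list[CandidateSet], d_traj: float, _cache: _PairCache | None = None) -> ConflictReport | None:
    """Minimum-distance electrode pair violating D > d_traj, or None.

    ``plan`` may be a :class:`Plan` or a bare selection tuple."""
    sel = plan.selections if isinstance(plan, Plan) else tuple(plan)
    cache = _cache or _PairCache(sets)
    worst = None
    for i in range(len(sel)):
        for j in range(i + 1, len(sel)):
            d = cache.dist(i, sel[i], j, sel[j])
            if d <= d_traj and (worst is None or d < worst.distance):
                worst = ConflictReport(i, j, d)
    return worst


def _mean_risk(sel: tuple[int, ...], sets: list[CandidateSet]) -> float:
    return float(np.mean([sets[i][a].R for i, a in enumerate(sel)]))


def _pool_push(state: PlannerState, depth: int, sel: tuple[int, ...], sets) -> None:
    seen = state.seen.setdefault(depth, set())
    if sel in seen:
        return
    seen.add(sel)
    heapq.heappush(state.pools.setdefault(depth, []), (_mean_risk(sel, sets), sel))


def _pool_pop(state: PlannerState, depth: int, reason: str):
    pool = state.pools.get(depth)
    if not pool:
        return None
    risk, sel = heapq.heappop(pool)
    state.audit.append({"depth": depth, "selection": sel, "mean_risk": risk, "reason": reason})
    return risk, sel


def _conflict_free_prefix(sel, cache: _PairCache, d_traj: float) -> bool:
    n = len(sel)
    for i in range(n):
        for j in range(i + 1, n):
            if cache.dist(i, sel[i], j, sel[j]) <= d_traj:
                return False
    return True


def _greedy_extend(sel, depth_to: int, sets, cache: _PairCache, d_traj: float):
    """Extend a partial plan one target at a time with each target's best
    candidate that conflicts with nothing already chosen."""
    sel = list(sel)
    for t in range(len(sel), depth_to):
        chosen = None
        for a in range(sets[t].M):
            if all(cache.dist(i, sel[i], t, a) > d_traj for i in range(len(sel))):
                chosen = a
                break
        if chosen is None:
            return None
        sel.append(chosen)
    return tuple(sel)


def plan_multiple(sets: list[CandidateSet], cfg: PlanningConfig | None = None, return_state: bool = False):
    """Depth-first search with DP pools; returns the first conflict-free
    complete plan (deterministic given deterministic candidate ranks)."""
    cfg = cfg or PlanningConfig()
    if not sets:
        raise ValueError("no candidate sets supplied")
    for s in sets:
        if s.M == 0:
            raise UnplannableError(f"target {s.target_id!r} has no candidates", s.target_id)
    N = len(sets)
    cache = _PairCache(sets)
    state = PlannerState()
    conflicts_resolved = 0
    _pool_push(state, 1, (0,), sets)
    committed: dict[int, tuple[int, ...]] = {}

    for n in range(1, N + 1):
        if n >= 2:
            _pool_push(state, n, committed[n - 1] + (0,), sets)
        while True:
            popped = _pool_pop(state, n, reason="select")
            if popped is None:
                raise UnplannableError(
                    f"candidates exhausted at depth {n} (target {sets[n - 1].target_id!r}): "
                    "every reachable combination conflicts",
                    sets[n - 1].target_id,
                )
            _, sel = popped
            conflict = detect_conflict(sel, sets, cfg.d_traj, _cache=cache)
            if conflict is None:
                committed[n] = sel
                break
            conflicts_resolved += 1
            state.expansions += 1
            if state.expansions > cfg.max_pool_expansions:
                raise UnplannableError(
                    f"pool expansion cap {cfg.max_pool_expansions} hit at depth {n}",
                    sets[n - 1].target_id,
                    blocking=[conflict],
                )
            i, j = conflict.i, conflict.j
            # (a) revive the best unused alternative sub-plan at depth i+1
            alt = _pool_pop(state, i + 1, reason=f"alternative for conflict ({i},{j})")
            while alt is not None and not _conflict_free_prefix(alt[1], cache, cfg.d_traj):
                alt = _pool_pop(state, i + 1, reason="discard conflicted alternative")
            if alt is not None:
                ext = _greedy_extend(alt[1], n, sets, cache, cfg.d_traj)
                if ext is not None:
                    _pool_push(state, n, ext, sets)
            # (b) advance the newest electrode of the conflicting pair
            if sel[j] + 1 < sets[j].M:
                _pool_push(state, n, sel[:j] + (sel[j] + 1,) + sel[j + 1:], sets)
            # (c) advance the other participant (keeps depth-1 targets movable)
            if sel[i] + 1 < sets[i].M:
                _pool_push(state, n, sel[:i] + (sel[i] + 1,) + sel[i + 1:], sets)

    sel = committed[N]
    plan = Plan(
        target_ids=tuple(s.target_id for s in sets),
        selections=sel,
        mean_risk=_mean_risk(sel, sets),
        conflict_free=True,
        n=N,
        expansions=state.expansions,
        conflicts_resolved=conflicts_resolved,
    )
    if return_state:
        return plan, state
    return plan


def exhaustive_plan(sets: list[CandidateSet], cfg: PlanningConfig | None = None, caps: int | list[int] | None = None) -> Plan:
    """Test oracle: enumerate every selection vector (optionally truncated to
    ``caps`` candidates per target), filter by pairwise D > d_traj, return
    the minimum-mean-risk survivor (ties by lexicographic vector)."""
    cfg = cfg or PlanningConfig()
    if caps is None:
        caps_list = [s.M for s in sets]
    elif isinstance(caps, int):
        caps_list = [min(caps, s.M) for s in sets]
    else:
        caps_list = [min(c, s.M) for c, s in zip(caps, sets)]
    if any(c == 0 for c in caps_list):
        raise UnplannableError("a target has no candidates")
    total = 1
    for c in caps_list:
        total *= c
    if total > 10**6:
        raise ValueError(f"{total} combinations exceed the enumeration cap of 1e6")
    cache = _PairCache(sets)
    best_sel = None
    best_risk = np.inf
    for sel in itertools.product(*(range(c) for c in caps_list)):
        if not _conflict_free_prefix(sel, cache, cfg.d_traj):
            continue
        risk = _mean_risk(sel, sets)
        if risk < best_risk - 1e-15 or (abs(risk - best_risk) <= 1e-15 and sel < best_sel):
            best_risk = risk
            best_sel = sel
    if best_sel is None:
        raise UnplannableError("no conflict-free combination exists")
    return Plan(
        target_ids=tuple(s.target_id for s in sets),
        selections=best_sel,
        mean_risk=float(best_risk),
        conflict_free=True,
        n=len(sets),
    )


def plan_to_dict(plan: Plan, sets: list[CandidateSet]) -> dict:
    """JSON-ready plan report: one entry per electrode plus plan-level
    summary (mean risk, minimum pairwise distance, search statistics)."""
    electrodes = []
    segs = []
    for i, a in enumerate(plan.selections):
        c = sets[i][a]
        segs.append(c.segment)
        electrodes.append(
            {
                "name": c.target_id,
                "entry_xyz_mm": [round(float(x), 6) for x in c.E],
                "target_xyz_mm": [round(float(x), 6) for x in c.T],
                "length_mm": round(c.length, 6),
                "angle_deg": round(c.angle, 6),
                "risk": round(c.R, 9),
                "gm_ratio": round(c.G, 9),
                "rank_used": c.rank,
            }
        )
    min_pair = min(
        (min_segment_distance(segs[i], segs[j]) for i in range(len(segs)) for j in range(i + 1, len(segs))),
        default=float("inf"),
    )
    return {
        "electrodes": electrodes,
        "mean_risk": round(plan.mean_risk, 9),
        "min_pairwise_distance_mm": round(min_pair, 6) if np.isfinite(min_pair) else None,
        "conflicts_resolved": plan.conflicts_resolved,
        "expansions": plan.expansions,
    }


def save_plan_json(plan: Plan, sets: list[CandidateSet], path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "w") as fh:
        json.dump(plan_to_dict(plan, sets), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
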