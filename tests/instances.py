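"""Random small MTP instances with geometric conflict structure.

Each instance is a list of CandidateSets whose segments are real 3-D
geometry (targets separated enough that a conflict-free assignment can
exist, entries scattered on an 85 mm sphere), so pairwise feasibility masks
arise from actual segment distances.  Risks increase with rank so candidate
order mirrors the planner's ranked input.  Only instances with at least one
conflict-free combination (verified by exhaustive enumeration) are yielded.
"""

from __future__ import annotations

import numpy as np

import seegplan as sp
from seegplan.stp import CandidateSet, TrajectoryCandidate
from seegplan.mtp import UnplannableError, exhaustive_plan


def random_instance(rng: np.random.Generator, n_targets=None, max_cands=8):
    n = int(n_targets if n_targets is not None else rng.integers(2, 5))
    # targets on a deep shell, pairwise separation > d_traj
    targets = []
    while len(targets) < n:
        p = rng.normal(size=3)
        p = p / np.linalg.norm(p) * rng.uniform(35, 55)
        if all(np.linalg.norm(p - q) > 14.0 for q in targets):
            targets.append(p)
    sets = []
    for i, T in enumerate(targets):
        m = int(rng.integers(3, max_cands + 1))
        cands = []
        risks = np.sort(rng.uniform(0, 0.6, size=m))  # R increases with rank
        for a in range(m):
            d = T / np.linalg.norm(T) + rng.normal(scale=0.35, size=3)
            d /= np.linalg.norm(d)
            E = d * 85.0
            cands.append(
                TrajectoryCandidate(
                    target_id=f"T{i + 1}", T=T, E=E, entry_vertex=a,
                    length=float(np.linalg.norm(E - T)), angle=10.0,
                    R=float(risks[a]), G=float(rng.random()), rank=a + 1,
                )
            )
        sets.append(CandidateSet(f"T{i + 1}", cands))
    return sets


def feasible_instances(seed: int, count: int, cfg=None, **kwargs):
    """Yield `count` instances that each admit a conflict-free plan."""
    cfg = cfg or sp.PlanningConfig()
    rng = np.random.default_rng(seed)
    produced = 0
    while produced < count:
        sets = random_instance(rng, **kwargs)
        try:
            oracle = exhaustive_plan(sets, cfg)
        except UnplannableError:
            continue
        produced += 1
        yield sets, oracle
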