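"""Single-trajectory planning: hard constraints, risk, GM ratio, ranking."""

import numpy as np
import pytest

import seegplan as sp
from seegplan.stp import EntrySearchError, TargetUnreachableError, TrajectoryCandidate
from conftest import make_parallel_cylinder_bvh
from oracles import analytic_shell_membership

CFG = sp.PlanningConfig()


def _template_with_normals(vertices, normals):
    """Tiny template mesh with hand-set outward normals (exact arithmetic)."""
    vertices = np.asarray(vertices, float)
    mesh = sp.TriangleMesh(vertices, np.array([[0, 1, 2]]), name="template")
    mesh.vertex_normals = np.asarray(normals, float)
    mesh.normals_valid = np.ones(len(vertices), bool)
    return mesh


class TestEntrySearch:
    def test_length_and_angle_rules(self):
        # target at the origin; radial normals -> angle 0 for radial vertices
        template = _template_with_normals(
            [[75.0, 0, 0], [0, 79.0, 0], [0, 0, 80.0]],
            [[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]],
        )
        idx = sp.find_entry_candidates(template, [0, 0, 0], CFG)
        # exact length 80 is excluded by the strictly-less rule
        assert list(idx) == [0, 1]

    def test_vertex_beyond_max_length_excluded(self):
        template = _template_with_normals(
            [[90.0, 0, 0], [70.0, 0, 0], [60.0, 0, 0]],
            [[1.0, 0, 0]] * 3,
        )
        idx = sp.find_entry_candidates(template, [0, 0, 0], CFG)
        assert 0 not in idx

    @pytest.mark.parametrize("tilt_deg,expected", [(30.0, False), (20.0, True)])
    def test_angle_threshold(self, tilt_deg, expected):
        t = np.radians(tilt_deg)
        normal = [np.cos(t), np.sin(t), 0.0]
        template = _template_with_normals(
            [[50.0, 0, 0], [55.0, 0, 0], [0, 55.0, 0]],
            [normal, [1.0, 0, 0], [0, 1.0, 0]],
        )
        idx = sp.find_entry_candidates(template, [0, 0, 0], CFG)
        assert (0 in idx) == expected

    def test_all_eliminated_raises(self):
        template = _template_with_normals([[90.0, 0, 0], [95.0, 0, 0], [0, 99.0, 0]], [[1.0, 0, 0]] * 3)
        with pytest.raises(EntrySearchError, match="length"):
            sp.find_entry_candidates(template, [0, 0, 0], CFG)


class TestSampleTrajectory:
    def test_two_points_are_endpoints(self):
        pts = sp.sample_trajectory([0, 0, 0], [1, 0, 0], 2)
        assert np.allclose(pts, [[0, 0, 0], [1, 0, 0]])

    def test_midpoint_included_for_three(self):
        pts = sp.sample_trajectory([0, 0, 0], [1, 0, 0], 3)
        assert np.allclose(pts[1], [0.5, 0, 0])

    def test_uniform_spacing_128(self):
        pts = sp.sample_trajectory([0, 0, 0], [1, 0, 0], 128)
        gaps = np.diff(pts[:, 0])
        assert np.allclose(gaps, 1.0 / 127)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            sp.sample_trajectory([1, 2, 3], [1, 2, 3], 10)


class TestRejectIntersecting:
    @pytest.fixture(scope="class")
    def template(self):
        mesh = sp.TriangleMesh(
            np.array([[0.0, 0, 50], [30.0, 0, 50], [0, 30.0, 50.0]]),
            np.array([[0, 1, 2]]),
            name="template",
        )
        return mesh

    def test_vessel_and_sulcus_both_gate(self, template):
        vessel = sp.build_bvh(
            sp.make_tube(np.linspace([-10, 0, 25], [40, 0, 25], 5), 2.0, sides=12)
        )
        sheet = sp.TriangleMesh(
            np.array([[20.0, -20, 25.0], [40.0, 20, 25.0], [20.0, 20, 25.0]]),
            np.array([[0, 1, 2]]),
            name="sulcus:0",
        )
        sulcus = sp.build_bvh(sheet)
        entries = np.array([0, 1, 2])
        # vertex 0's descent to (0,0,0) crosses the vessel; vertex 1's crosses the sheet
        kept = sp.reject_intersecting(entries, template, [0, 0, 0], [vessel])
        assert 0 not in kept
        kept2 = sp.reject_intersecting(entries, template, [30, 10, 0], [sulcus])
        assert 1 not in kept2

    def test_clear_trajectory_kept(self, template):
        far = sp.icosphere(2, 3.0, "vessel:far")
        far.vertices = far.vertices + 500.0
        vessel = sp.build_bvh(far)
        kept = sp.reject_intersecting(np.array([0, 1, 2]), template, [0, 0, 0], [vessel])
        assert list(kept) == [0, 1, 2]


class TestRiskScore:
    E = np.array([0.0, 0, 0])
    T = np.array([60.0, 0, 0])

    def test_no_risk_beyond_risk_zone(self):
        bvh = make_parallel_cylinder_bvh(15.0)
        prof = sp.risk_profile(self.E, self.T, [bvh], CFG)
        assert prof.s_crit == 0.0
        assert sp.risk_score(prof, CFG) == 0.0

    def test_safety_violation_saturates_to_one(self):
        bvh = make_parallel_cylinder_bvh(2.0)  # surface 2 mm < d_safety
        prof = sp.risk_profile(self.E, self.T, [bvh], CFG)
        assert prof.safety_violated
        assert sp.risk_score(prof, CFG) == 1.0

    @pytest.mark.parametrize("d", [3.0, 5.0, 7.0, 10.0])
    def test_closed_form_parallel_cylinder(self, d):
        """Constant f_crit = d gives R = (d_risk - d)/(d_risk - d_safety)."""
        bvh = make_parallel_cylinder_bvh(d)
        prof = sp.risk_profile(self.E, self.T, [bvh], CFG)
        R = sp.risk_score(prof, CFG)
        expected = (CFG.d_risk - d) / (CFG.d_risk - CFG.d_safety)
        assert abs(R - expected) <= 0.01 * max(expected, 0.05)

    def test_integral_value_mid_band(self):
        """f_crit = 6.5 mm over 60 mm: S_crit = (10 - 6.5) * 60 = 210 mm^2."""
        bvh = make_parallel_cylinder_bvh(6.5)
        prof = sp.risk_profile(self.E, self.T, [bvh], CFG)
        assert abs(prof.s_crit - 210.0) < 2.1

    def test_literal_integrand_variant_is_larger(self):
        cfg_lit = sp.PlanningConfig(risk_integrand="literal")
        bvh = make_parallel_cylinder_bvh(6.5)
        r_clamped = sp.risk_score(sp.risk_profile(self.E, self.T, [bvh], CFG), CFG)
        r_literal = sp.risk_score(sp.risk_profile(self.E, self.T, [bvh], cfg_lit), cfg_lit)
        # literal text adds d_safety/(d_risk - d_safety) everywhere in-band
        assert abs((r_literal - r_clamped) - CFG.d_safety / (CFG.d_risk - CFG.d_safety)) < 0.01

    def test_no_vessels_means_no_risk(self):
        prof = sp.risk_profile(self.E, self.T, [], CFG)
        assert sp.risk_score(prof, CFG) == 0.0

    def test_zero_length_rejected(self):
        prof = sp.RiskProfile(np.zeros(4), np.full(4, 20.0), ["x"] * 4, 0.0, False)
        with pytest.raises(ValueError):
            sp.risk_score(prof, CFG)

    def test_risk_monotone_as_vessel_approaches(self):
        rs = [
            sp.risk_score(sp.risk_profile(self.E, self.T, [make_parallel_cylinder_bvh(d)], CFG), CFG)
            for d in (9.0, 7.0, 5.0, 3.5)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(rs, rs[1:]))


class TestGmWmRatio:
    def test_all_contacts_inside_shell(self, nested_gm):
        T = np.array([60.0, -28.0, 0.0])
        E = np.array([60.0, 40.0, 0.0])
        assert sp.gm_wm_ratio(E, T, nested_gm, CFG) == 1.0

    def test_trajectory_outside_gm(self, nested_gm):
        T = np.array([80.0, 0, 0])
        E = np.array([160.0, 0, 0])
        assert sp.gm_wm_ratio(E, T, nested_gm, CFG) == 0.0

    def test_radial_trajectory_matches_analytic_membership(self, nested_gm):
        """Tip at radius 58: contacts at 58, 64, 70, 76, ... - agreement with
        the analytic shell-membership oracle on all 30 evaluation points."""
        u = np.array([1.0, 0.3, 0.2])
        u /= np.linalg.norm(u)
        T = 58.0 * u
        E = 130.0 * u
        offsets = []
        for j in range(CFG.contacts):
            c = j * CFG.contact_spacing
            offsets += [c - CFG.contact_radius, c, c + CFG.contact_radius]
        pts = T[None, :] + np.asarray(offsets)[:, None] * u[None, :]
        expected = analytic_shell_membership(pts, 55.0, 70.0).sum() / (3 * CFG.contacts)
        assert sp.gm_wm_ratio(E, T, nested_gm, CFG) == pytest.approx(expected, abs=1e-12)

    def test_random_trajectories_match_analytic_membership(self, nested_gm):
        """20 random margin-safe trajectories: exact agreement with the
        analytic oracle (all points kept > 0.5 mm from the shell surfaces,
        beyond the icosphere faceting error)."""
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 20:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            tip_r = rng.uniform(30.0, 68.0)
            T = tip_r * d
            perp = np.cross(d, [0, 0, 1.0])
            if np.linalg.norm(perp) < 0.1:
                continue
            perp /= np.linalg.norm(perp)
            E = T + rng.uniform(60, 79) * (d * 0.9 + perp * 0.44)
            u = (E - T) / np.linalg.norm(E - T)
            offsets = []
            for j in range(CFG.contacts):
                c = j * CFG.contact_spacing
                offsets += [c - CFG.contact_radius, c, c + CFG.contact_radius]
            pts = T[None, :] + np.asarray(offsets)[:, None] * u[None, :]
            radii = np.linalg.norm(pts, axis=1)
            if (np.abs(radii - 55.0) < 0.5).any() or (np.abs(radii - 70.0) < 0.5).any():
                continue  # too close to a faceted surface to compare exactly
            expected = analytic_shell_membership(pts, 55.0, 70.0).sum() / (3 * CFG.contacts)
            assert sp.gm_wm_ratio(E, T, nested_gm, CFG) == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_invariant_under_rigid_motion(self):
        angle = 0.7
        Rm = np.array(
            [[np.cos(angle), -np.sin(angle), 0], [np.sin(angle), np.cos(angle), 0], [0, 0, 1.0]]
        )
        shift = np.array([5.0, -3.0, 11.0])
        outer = sp.icosphere(2, 70.0, "gm_outer")
        inner = sp.icosphere(2, 55.0, "gm_inner")
        gm1 = sp.GmModel(outer, inner)
        outer2 = sp.TriangleMesh(outer.vertices @ Rm.T + shift, outer.faces, "gm_outer")
        inner2 = sp.TriangleMesh(inner.vertices @ Rm.T + shift, inner.faces, "gm_inner")
        gm2 = sp.GmModel(outer2, inner2)
        T = np.array([58.0, 6.0, 3.0])
        E = np.array([120.0, 14.0, 9.0])
        g1 = sp.gm_wm_ratio(E, T, gm1, CFG)
        g2 = sp.gm_wm_ratio(Rm @ E + shift, Rm @ T + shift, gm2, CFG)
        assert g1 == g2


def _cand(R, G, entry=0):
    return TrajectoryCandidate(
        target_id="t", T=np.zeros(3), E=np.ones(3), entry_vertex=entry,
        length=10.0, angle=5.0, R=R, G=G,
    )


class TestStratifiedRank:
    def test_same_bin_orders_by_gm_ratio(self):
        out = sp.stratified_rank([_cand(0.05, 0.2, 0), _cand(0.08, 0.9, 1)], K=10)
        assert [c.entry_vertex for c in out] == [1, 0]
        assert [c.rank for c in out] == [1, 2]

    def test_lower_bin_wins_despite_lower_gm(self):
        out = sp.stratified_rank([_cand(0.05, 0.2, 0), _cand(0.15, 0.9, 1)], K=10)
        assert [c.entry_vertex for c in out] == [0, 1]

    def test_single_bin_is_pure_gm_descending(self):
        cands = [_cand(0.9, 0.1, 0), _cand(0.1, 0.5, 1), _cand(0.5, 0.9, 2)]
        out = sp.stratified_rank(cands, K=1)
        assert [c.entry_vertex for c in out] == [2, 1, 0]

    def test_risk_one_lands_in_last_bin(self):
        out = sp.stratified_rank([_cand(1.0, 1.0, 0), _cand(0.95, 0.0, 1)], K=10)
        # both in bin 10; ordered by G
        assert [c.entry_vertex for c in out] == [0, 1]

    def test_ranks_are_contiguous(self):
        rng = np.random.default_rng(5)
        cands = [_cand(r, g, i) for i, (r, g) in enumerate(rng.random((25, 2)))]
        out = sp.stratified_rank(cands, K=10)
        assert [c.rank for c in out] == list(range(1, 26))


class TestPlanSingle:
    def test_no_critical_structures_gives_zero_risk(self, small_scene):
        scene = small_scene
        bare = sp.Scene(
            skull=scene.skull, template=scene.template, vessels=[], sulci=[],
            gm=scene.gm, targets=scene.targets,
        )
        name, T = scene.targets.names[0], scene.targets.points[0]
        cs = sp.plan_single(T, bare, CFG, target_id=name)
        assert all(c.R == 0.0 for c in cs.candidates)
        assert cs[0].G == max(c.G for c in cs.candidates)

    def test_candidate_invariants(self, small_scene):
        cs = sp.plan_single(small_scene.targets.points[1], small_scene, CFG, target_id="T2")
        for c in cs.candidates:
            assert c.length < CFG.d_length
            assert c.angle < CFG.d_angle
            assert 0.0 <= c.R <= 1.0
            assert 0.0 <= c.G <= 1.0
        assert [c.rank for c in cs.candidates] == list(range(1, cs.M + 1))

    def test_rank_one_uses_planted_corridor(self, planted_scene, planted_sets):
        """The lowest-risk entry must sit inside the only unblocked corridor."""
        hole = np.asarray(planted_scene.ground_truth["hole_main_mm"])
        for cs in planted_sets:
            T = dict(planted_scene.targets)[cs.target_id]
            best = cs[0]
            # the trajectory passes within the 4 mm opening at the shield radius
            direction = (best.E - T) / np.linalg.norm(best.E - T)
            crossing = T + direction * (np.linalg.norm(hole) - np.linalg.norm(T))
            assert np.linalg.norm(crossing - hole) < 8.0

    def test_blocked_target_unreachable_with_stage_counts(self, small_scene):
        T = small_scene.targets.points[0]
        shell = sp.icosphere(2, 8.0, "sulcus:block")
        shell.vertices = shell.vertices + T
        blocked = sp.Scene(
            skull=small_scene.skull, template=small_scene.template,
            vessels=small_scene.vessels, sulci=[shell], gm=small_scene.gm,
            targets=small_scene.targets,
        )
        with pytest.raises(TargetUnreachableError) as err:
            sp.plan_single(T, blocked, CFG, target_id="T1")
        assert err.value.counts["after_intersection"] == 0
        assert err.value.counts["after_length_angle"] > 0

    def test_saturated_scene_all_risk_one_still_ranked(self, small_scene):
        """A vessel grazing the target saturates every trajectory to R = 1;
        the ranking must still be total."""
        T = small_scene.targets.points[0]
        curve = np.linspace(T + [2.0, -30.0, 0.0], T + [2.0, 30.0, 0.0], 8)
        vessel = sp.make_tube(curve, 0.5, sides=12, name="vessel:graze")
        scene = sp.Scene(
            skull=small_scene.skull, template=small_scene.template,
            vessels=[vessel], sulci=[], gm=small_scene.gm, targets=small_scene.targets,
        )
        cs = sp.plan_single(T, scene, CFG, target_id="T1")
        assert all(c.R == 1.0 for c in cs.candidates)
        gs = [c.G for c in cs.candidates]
        assert gs == sorted(gs, reverse=True)


class TestProfileExport:
    def test_csv_schema_and_tissue(self, small_scene):
        name, T = small_scene.targets.names[0], small_scene.targets.points[0]
        cs = sp.plan_single(T, small_scene, CFG, target_id=name)
        text = sp.export_profile_csv(cs[0].E, cs[0].T, small_scene, CFG)
        lines = text.strip().split("\n")
        assert lines[0] == "arc_mm,f_crit_mm,nearest_structure,tissue"
        assert len(lines) == 1 + CFG.n_samples
        tissues = {line.split(",")[3] for line in lines[1:]}
        assert tissues <= {"GM", "WM", "outside"}
        # entry (arc 0) sits on the skull, outside the pial surface
        assert lines[1].split(",")[3] == "outside"
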