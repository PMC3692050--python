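import numpy as np
import pytest

from foldkit import fixtures
from foldkit.bioio import CaTrace, Template
from foldkit.restraints import (AddDirective, DeleteDirective, DirectiveError,
                                DistanceRestraint, RestraintConfig,
                                RestraintError, RestraintSet, apply_edits,
                                collect_pair_stats,
                                generate_consensus_restraints,
                                generate_single_template_restraints,
                                parse_edit_directives, restraint_energy,
                                satisfaction_fraction, select_regime)


def template_from(coords, resids=None, source="t"):
    coords = np.asarray(coords, float)
    if resids is None:
        resids = np.arange(1, len(coords) + 1)
    return Template(trace=CaTrace(coords=coords, resids=np.asarray(resids)),
                    source=source)


def brute_force_stats(templates, min_obs):
    """Direct per-pair loop oracle over templates (population sigma)."""
    import math
    obs = {}
    for t in templates:
        tr = t.trace
        for a in range(len(tr)):
            for b in range(a + 1, len(tr)):
                key = (int(tr.resids[a]), int(tr.resids[b]))
                dx, dy, dz = (tr.coords[b] - tr.coords[a]).tolist()
                obs.setdefault(key, []).append(
                    math.sqrt(dx * dx + dy * dy + dz * dz))
    out = {}
    for key, ds in obs.items():
        if len(ds) >= min_obs:
            m = sum(ds) / len(ds)
            var = sum((d - m) ** 2 for d in ds) / len(ds)
            out[key] = (min(ds), max(ds), m, var ** 0.5, len(ds))
    return out


def random_templates(rng, n_templates, n_res):
    """Noisy partial copies of a random fold; a core block of the first
    five residues is always covered so every pair overlaps."""
    base = rng.normal(size=(n_res, 3)) * 6
    templates = []
    core = np.arange(min(5, n_res))
    for k in range(n_templates):
        coords = base + rng.normal(scale=1.0, size=base.shape)
        extra = rng.choice(n_res, size=rng.integers(max(3, n_res // 2),
                                                    n_res + 1),
                           replace=False)
        keep = np.sort(np.union1d(core, extra))
        templates.append(template_from(coords[keep], resids=keep + 1,
                                       source=f"t{k}"))
    return templates


class TestPairStats:
    def test_single_template_degenerate_stats(self):
        t = template_from(np.diag([5.0, 9.0, 14.0]))
        stats = {(s.i, s.j): s for s in collect_pair_stats([t])}
        s = stats[(1, 2)]
        assert s.d_min == s.d_max == s.mean
        assert s.sigma == 0.0 and s.n_obs == 1

    def test_two_template_hand_example(self):
        # pair (2,7) at 5.0 A in one template, 9.0 A in the other
        def with_distance(d):
            coords = np.zeros((2, 3))
            coords[1, 0] = d
            return template_from(coords, resids=[2, 7])
        stats = collect_pair_stats([with_distance(5.0), with_distance(9.0)],
                                   min_obs=2)
        (s,) = stats
        assert (s.i, s.j) == (2, 7)
        assert (s.d_min, s.d_max, s.mean, s.sigma) == (5.0, 9.0, 7.0, 2.0)

    def test_min_obs_filters_partially_covered_pairs(self):
        a = template_from(np.diag([4.0, 8.0, 12.0]))
        b = template_from(np.diag([4.0, 8.0, 0.0])[:2], resids=[1, 2])
        stats = collect_pair_stats([a, b], min_obs=2)
        assert {(s.i, s.j) for s in stats} == {(1, 2)}

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            templates = random_templates(rng, int(rng.integers(2, 6)),
                                         int(rng.integers(8, 21)))
            for min_obs in (1, 2, len(templates)):
                oracle = brute_force_stats(templates, min_obs)
                got = {(s.i, s.j): s for s in
                       collect_pair_stats(templates, min_obs=min_obs)}
                assert set(got) == set(oracle)
                for key, (dmin, dmax, mean, sigma, n) in oracle.items():
                    s = got[key]
                    assert s.d_min == dmin and s.d_max == dmax
                    assert abs(s.mean - mean) < 1e-9
                    assert abs(s.sigma - sigma) < 1e-9
                    assert s.n_obs == n

    def test_empty_template_list_is_an_error(self):
        with pytest.raises(RestraintError):
            collect_pair_stats([])


class TestRegimeSelection:
    def test_identical_templates_choose_minmax(self, helix30):
        t = helix30.templates[0]
        assert select_regime([t, t]) == "minmax"

    def test_dissimilar_pair_forces_distribution(self, helix30):
        rng = np.random.default_rng(0)
        t1 = helix30.templates[0]
        scrambled = template_from(rng.normal(size=(30, 3)) * 12)
        # similar pair exists, but one dissimilar pair gates the set
        assert select_regime([t1, t1, scrambled]) == "distribution"

    def test_single_template_is_routed_elsewhere(self, helix30):
        with pytest.raises(RestraintError, match="single-template"):
            select_regime([helix30.templates[0]])


class TestConsensusRestraints:
    def test_identical_templates_pin_ranges_to_observed_distance(self,
                                                                 helix30):
        t = helix30.templates[0]
        rs, regime = generate_consensus_restraints([t, t])
        assert regime == "minmax"
        assert len(rs) > 0
        for r in rs:
            d = np.linalg.norm(t.trace.coords[r.j - 1] -
                               t.trace.coords[r.i - 1])
            assert np.isclose(r.dmin, d) and np.isclose(r.dmax, d)

    def test_minmax_and_distribution_ranges_match_stats_oracle(self):
        rng = np.random.default_rng(21)
        base = fixtures.helix_trace(20)
        mild = [template_from(base + rng.normal(scale=0.3, size=base.shape))
                for _ in range(3)]
        rs, regime = generate_consensus_restraints(mild)
        assert regime == "minmax"
        oracle = brute_force_stats(mild, min_obs=3)
        for r in rs:
            dmin, dmax, mean, _, _ = oracle[(r.i, r.j)]
            assert np.isclose(r.dmin, dmin) and np.isclose(r.dmax, dmax)

        wild = [mild[0],
                template_from(rng.normal(size=(20, 3)) * 12, source="far")]
        rs, regime = generate_consensus_restraints(wild)
        assert regime == "distribution"
        oracle = brute_force_stats(wild, min_obs=2)
        config = RestraintConfig()
        for r in rs:
            _, _, mean, sigma, _ = oracle[(r.i, r.j)]
            assert np.isclose(r.dmin, max(3.0, mean - sigma), atol=1e-9)
            assert np.isclose(r.dmax, mean + sigma, atol=1e-9)
            assert r.j - r.i >= config.s_min and mean <= config.d_cap

    def test_every_template_satisfies_minmax_restraints(self):
        rng = np.random.default_rng(3)
        base = fixtures.helix_trace(18)
        templates = [template_from(base + rng.normal(scale=0.3,
                                                     size=base.shape))
                     for _ in range(4)]
        rs, regime = generate_consensus_restraints(templates)
        assert regime == "minmax"
        for t in templates:
            assert restraint_energy(t.trace.coords, rs) == 0.0


class TestSingleTemplateRestraints:
    def test_uncovered_residues_stay_free(self):
        base = fixtures.helix_trace(30)
        t = template_from(base[:20], resids=np.arange(1, 21))
        rs = generate_single_template_restraints(t)
        assert len(rs) > 0
        for r in rs:
            assert r.i <= 20 and r.j <= 20

    def test_band_built_around_template_distance(self):
        coords = np.zeros((2, 3))
        coords[1, 0] = 6.0
        t = template_from(coords, resids=[1, 8])
        rs = generate_single_template_restraints(
            t, RestraintConfig(tau=0.5, s_min=5))
        (r,) = list(rs)
        assert (r.dmin, r.dmax) == (5.5, 6.5)

    def test_restraint_count_matches_pair_enumeration_oracle(self):
        base = fixtures.helix_trace(16)
        t = template_from(base)
        config = RestraintConfig(s_min=4, d_cap=18.0)
        rs = generate_single_template_restraints(t, config)
        expected = sum(
            1 for i in range(16) for j in range(i + 4, 16)
            if np.linalg.norm(base[j] - base[i]) <= config.d_cap)
        assert len(rs) == expected


class TestEditDirectives:
    def test_add_directive_semantics(self):
        (d,) = parse_edit_directives("A 3 14 7.8 10.12")
        assert isinstance(d, AddDirective)
        r = d.restraint
        assert (r.i, r.j, r.dmin, r.dmax) == (3, 14, 7.8, 10.12)

    @pytest.mark.parametrize("text", ["D 55,58,120–160", "D 55,58,120-160"])
    def test_delete_directive_expands_ranges_both_dash_kinds(self, text):
        (d,) = parse_edit_directives(text)
        assert isinstance(d, DeleteDirective)
        assert d.residues == frozenset({55, 58} | set(range(120, 161)))

    def test_add_normalizes_residue_order(self):
        (d,) = parse_edit_directives("A 5 2 3.0 4.0")
        assert (d.restraint.i, d.restraint.j) == (2, 5)

    @pytest.mark.parametrize("bad", [
        "A 3 14 10.0 7.8",   # inverted range
        "A 3 14 7.8",        # missing field
        "D ",                # empty delete set
        "D 10-5",            # inverted residue range
        "Q 1 2 3 4",         # unknown kind
        "D a,b",             # non-numeric
    ])
    def test_malformed_lines_raise_with_line_number(self, bad):
        with pytest.raises(DirectiveError, match="line 1"):
            parse_edit_directives(bad)


class TestApplyEdits:
    def seeded_set(self):
        rs = RestraintSet()
        rs.add(DistanceRestraint(3, 14, 7.0, 9.0), "consensus-minmax")
        rs.add(DistanceRestraint(10, 130, 11.0, 12.0), "consensus-minmax")
        return rs

    def test_delete_removes_any_restraint_touching_the_residues(self):
        rs = self.seeded_set()
        out = apply_edits(rs, parse_edit_directives("D 55,58,120–160"))
        assert set(out.restraints) == {(3, 14)}

    def test_add_into_empty_set(self):
        out = apply_edits(RestraintSet(),
                          parse_edit_directives("A 3 14 7.8 10.12"))
        assert len(out) == 1
        assert out.provenance[(3, 14)] == "user"

    def test_add_replaces_existing_pair(self):
        out = apply_edits(self.seeded_set(),
                          parse_edit_directives("A 3 14 1.0 2.0"))
        assert out.restraints[(3, 14)].dmax == 2.0
        assert out.provenance[(3, 14)] == "user"

    def test_delete_is_idempotent_and_input_set_untouched(self):
        rs = self.seeded_set()
        d = parse_edit_directives("D 10")
        once = apply_edits(rs, d)
        twice = apply_edits(once, d)
        assert set(once.restraints) == set(twice.restraints) == {(3, 14)}
        assert set(rs.restraints) == {(3, 14), (10, 130)}

    def test_deletes_apply_before_adds_regardless_of_file_order(self):
        out = apply_edits(self.seeded_set(),
                          parse_edit_directives("A 10 130 5.0 6.0\nD 130"))
        # the delete runs first, then the add re-creates the pair
        assert out.restraints[(10, 130)].dmin == 5.0


class TestRestraintEnergy:
    def test_flat_bottom_zero_inside_quadratic_outside(self):
        rs = RestraintSet()
        rs.add(DistanceRestraint(1, 2, 4.0, 6.0, weight=1.0), "user")
        coords = np.zeros((2, 3))
        coords[1, 0] = 5.0
        assert restraint_energy(coords, rs) == 0.0
        coords[1, 0] = 8.0  # exceeds dmax by 2
        assert np.isclose(restraint_energy(coords, rs), 4.0)
        coords[1, 0] = 3.0  # below dmin by 1
        assert np.isclose(restraint_energy(coords, rs), 1.0)

    def test_matches_per_restraint_loop_oracle(self, rng):
        coords = rng.normal(size=(25, 3)) * 8
        rs = RestraintSet()
        for _ in range(20):
            i, j = sorted(rng.choice(25, size=2, replace=False) + 1)
            lo = float(rng.uniform(4, 10))
            rs.add(DistanceRestraint(int(i), int(j), lo,
                                     lo + float(rng.uniform(0, 4)),
                                     weight=float(rng.uniform(0.5, 2))),
                   "user")
        total = 0.0
        for r in rs:
            d = np.linalg.norm(coords[r.j - 1] - coords[r.i - 1])
            dev = max(r.dmin - d, 0.0) + max(d - r.dmax, 0.0)
            total += r.weight * dev ** 2
        assert np.isclose(restraint_energy(coords, rs), total, atol=1e-9)

    def test_continuity_at_the_range_boundary(self):
        rs = RestraintSet()
        rs.add(DistanceRestraint(1, 2, 4.0, 6.0), "user")
        coords = np.zeros((2, 3))
        for d, expected in ((6.0 - 1e-8, 0.0), (6.0 + 1e-8, 0.0)):
            coords[1, 0] = d
            assert restraint_energy(coords, rs) == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_out_of_range_residue_index_raises(self):
        rs = RestraintSet()
        rs.add(DistanceRestraint(1, 10, 4.0, 6.0), "user")
        with pytest.raises(RestraintError):
            restraint_energy(np.zeros((5, 3)), rs)


class TestSatisfaction:
    def test_template_satisfies_its_own_restraints(self, helix30):
        t = helix30.templates[0]
        rs = generate_single_template_restraints(t)
        assert satisfaction_fraction(t.trace.coords, rs) == 1.0

    def test_empty_set_is_vacuously_satisfied_with_warning(self):
        with pytest.warns(UserWarning):
            assert satisfaction_fraction(np.zeros((5, 3)),
                                         RestraintSet()) == 1.0

    def test_half_violated_fixture(self):
        rs = RestraintSet()
        coords = np.zeros((21, 3))
        coords[:, 0] = np.arange(21) * 5.0
        for k in range(10):
            i, j = k + 1, k + 2  # distance 5.0
            lo = 4.0 if k < 5 else 6.0  # half satisfied, half violated
            rs.add(DistanceRestraint(i, j, lo, lo + 1.0), "user")
        assert satisfaction_fraction(coords, rs) == 0.5
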