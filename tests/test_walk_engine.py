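import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyforge.errors import BuildError, InputError
from polyforge.synthetic import (
    FixtureSpec,
    build_fixture,
    cyclization_spec,
    melt_spec,
)
from polyforge.walk_engine import (
    BuildEntry,
    BuildSpec,
    DistanceRestraint,
    GeomConstraint,
    MoleculeOptions,
    lj_force,
    minimum_image,
    restraint_bounds,
    sample_wlc_end_to_end,
    walk_molecule,
    wlc_mean_square_ee,
)

from .oracles import min_image_27


class TestMinimumImage:
    def test_wraps_across_boundary(self):
        d = minimum_image([0.5, 0, 0], [9.5, 0, 0], [10, 10, 10])
        assert np.linalg.norm(d) == pytest.approx(1.0)

    def test_identical_points_zero(self):
        assert np.allclose(minimum_image([3, 4, 5], [3, 4, 5], [10, 10, 10]),
                           0.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_27_image_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(1.0, 20.0, 3)
        p, q = rng.uniform(-30, 30, (2, 3))
        mine = minimum_image(p, q, box)
        oracle = min_image_27(np.mod(p, box), np.mod(q, box), box)
        assert np.linalg.norm(mine) == \
            pytest.approx(np.linalg.norm(oracle), abs=1e-9)
        assert np.all(np.abs(mine) <= box / 2 + 1e-12)


class TestLJForce:
    def test_zero_at_potential_minimum(self):
        sigma = 0.7
        assert lj_force(2 ** (1 / 6) * sigma, sigma) == pytest.approx(0.0)

    def test_value_at_sigma(self):
        # F(sigma) = 24 eps (2 - 1) / sigma
        assert lj_force(0.5, 0.5, 1.0) == pytest.approx(48.0)

    def test_zero_beyond_cutoff(self):
        assert lj_force(3 * 0.5, 0.5) == 0.0

    def test_overlap_is_an_error(self):
        with pytest.raises(InputError):
            lj_force(0.0, 0.5)


class TestRestraintBounds:
    def test_at_the_restrained_node(self):
        assert restraint_bounds(0.5, 0.1, 0, 0.47) == \
            pytest.approx((0.4, 0.6))

    def test_three_edges_remaining(self):
        assert restraint_bounds(2.0, 0.0, 3, 0.5) == pytest.approx((0.5, 3.5))

    def test_bounds_shrink_as_walk_approaches(self):
        widths = [np.diff(restraint_bounds(2.0, 0.1, g, 0.5))[0]
                  for g in (5, 3, 1, 0)]
        assert widths == sorted(widths, reverse=True)


class TestWlcSampler:
    def test_rigid_limit_reaches_contour(self, rng):
        samples = sample_wlc_end_to_end(10.0, 1e6, rng, size=500)
        assert np.allclose(samples, 10.0, rtol=1e-3)

    def test_support_bounded_by_contour(self, rng):
        samples = sample_wlc_end_to_end(63.0, 3.2, rng, size=2000)
        assert np.all(samples <= 63.0)
        assert np.all(samples > 0.0)

    def test_second_moment_matches_closed_form(self, rng):
        samples = sample_wlc_end_to_end(63.0, 3.2, rng, size=20_000)
        mean_sq = np.mean(samples ** 2)
        se = np.std(samples ** 2) / np.sqrt(samples.size)
        assert abs(mean_sq - wlc_mean_square_ee(63.0, 3.2)) <= 3 * se

    def test_closed_form_limits(self):
        assert wlc_mean_square_ee(63.0, 3.2) == pytest.approx(382.72, abs=0.01)
        L = 5.0
        assert wlc_mean_square_ee(L, 1e6 * L) == pytest.approx(L * L, rel=1e-4)
        lp = 0.5
        assert wlc_mean_square_ee(1e6 * lp, lp) == \
            pytest.approx(2 * lp * 1e6 * lp, rel=1e-4)


def _chain_graph(n, rho=0.21):
    g = nx.path_graph(n)
    nx.set_node_attributes(g, rho, "rho")
    return g


class TestWalkMolecule:
    def test_single_bead_sits_on_start(self, rng):
        g = _chain_graph(1)
        spec = BuildSpec(box=np.array([10.0, 10.0, 10.0]))
        state = walk_molecule(g, [5, 5, 5], spec, rng)
        assert np.allclose(state.positions[0], [5, 5, 5])

    def test_bonded_distances_and_exclusion(self, rng):
        g = _chain_graph(50)
        spec = BuildSpec(box=np.array([100.0, 100.0, 100.0]))
        state = walk_molecule(g, [50, 50, 50], spec, rng)
        assert len(state.positions) == 50
        box = state.box
        for u, v in g.edges:
            d = np.linalg.norm(minimum_image(state.positions[u],
                                             state.positions[v], box))
            assert d == pytest.approx(0.8 * 0.42, abs=1e-9)
        # no nonbonded pair below the fmax-equivalent distance
        from scipy.optimize import brentq

        sigma = 0.42
        r_star = brentq(lambda r: lj_force(r, sigma) - spec.fmax,
                        0.3 * sigma, 2 ** (1 / 6) * sigma)
        for i in g.nodes:
            for j in g.nodes:
                if j - i > 1:
                    d = np.linalg.norm(minimum_image(state.positions[i],
                                                     state.positions[j], box))
                    assert d >= r_star - 1e-9

    def test_branched_molecule_bfs_order(self, rng):
        g = nx.star_graph(3)
        nx.set_node_attributes(g, 0.21, "rho")
        spec = BuildSpec(box=np.array([20.0, 20.0, 20.0]))
        state = walk_molecule(g, [10, 10, 10], spec, rng)
        assert state.order[0] == 0
        assert set(state.order[1:]) == {1, 2, 3}

    def test_infeasible_restraint_detected_before_walking(self, rng):
        g = _chain_graph(5)
        spec = BuildSpec(box=np.array([20.0, 20.0, 20.0]))
        options = MoleculeOptions(
            restraints=[DistanceRestraint(0, 4, 10.0, 0.1)]
        )
        with pytest.raises(InputError, match="restraint"):
            walk_molecule(g, [10, 10, 10], spec, rng, options=options)


class TestCyclization:
    def test_end_contact_restraint_always_satisfied(self):
        satisfied = 0
        total = 40
        for seed in range(total):
            system, ctx = build_fixture(cyclization_spec(seed=seed))
            pos = system.molecules[0][1]
            d = np.linalg.norm(minimum_image(pos[0], pos[19], system.box))
            assert 0.5 - 0.1 <= d <= 0.5 + 0.1
            satisfied += 1
        assert satisfied == total


class TestBuildSystem:
    def test_two_single_bead_molecules_use_grid_points(self, bead_spring):
        fixture = FixtureSpec(name="two", library="bead_spring",
                              sequence="B:1", n_chains=2,
                              box=np.array([4.0, 4.0, 4.0]), seed=0)
        system, ctx = build_fixture(fixture)
        assert len(system.molecules) == 2
        a = system.molecules[0][1][0]
        b = system.molecules[1][1][0]
        assert not np.allclose(a, b)

    def test_determinism_bit_identical(self):
        fixture = melt_spec(5, 10, volume_fraction=0.3, seed=21)
        first, _ = build_fixture(fixture)
        second, _ = build_fixture(fixture)
        for (_, pa), (_, pb) in zip(first.molecules, second.molecules):
            for node in pa:
                assert np.array_equal(pa[node], pb[node])

    def test_density_infeasibility_detected(self):
        fixture = melt_spec(5, 10, volume_fraction=0.3, seed=0)
        fixture.box = np.array([1.0, 1.0, 1.0])
        with pytest.raises(InputError, match="volume"):
            build_fixture(fixture)

    def test_inside_sphere_constraint_holds_for_every_bead(self, rng):
        from polyforge.synthetic import materialize

        fixture = melt_spec(3, 8, volume_fraction=0.2, seed=5)
        ctx = materialize(fixture)
        sphere = GeomConstraint("sphere", True,
                                (*(ctx["spec"].box / 2), 2.5))
        ctx["spec"].entries.append(
            BuildEntry(molname="MOL", geometry=[sphere])
        )
        from polyforge.walk_engine import build_system

        system = build_system(ctx["top_model"], {"MOL": ctx["supercg"]},
                              ctx["spec"], np.random.default_rng(3))
        for _name, beads in system.molecules:
            for pos in beads.values():
                assert sphere.allows(pos)

    def test_melt_builds_robustly(self):
        failures = 0
        for seed in range(10):
            try:
                build_fixture(melt_spec(20, 20, volume_fraction=0.35,
                                        seed=seed))
            except BuildError:
                failures += 1
        assert failures == 0
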