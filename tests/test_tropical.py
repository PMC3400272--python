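"""Max-plus dominance, tropical curves, sliding modes and hybrid
integration."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from crnred.core import RHS, SignedMonomial
from crnred.fixtures import michaelis_menten_reduced_rhs
from crnred.tropical import (DegenerateManifold, TropicalPolynomial,
                             detect_fast_constraints, dominant_monomial,
                             simulate_hybrid, sliding_test, surface_for_pair,
                             tropical_manifold_2d, tropicalize)


def poly_from(terms):
    """terms: list of (sign, coeff, exponents)."""
    monos = [SignedMonomial(s, sp.Float(a), tuple(e)) for s, a, e in terms]
    return TropicalPolynomial.from_monomials(monos, {})


class TestDominance:
    def test_single_monomial_trivial(self):
        p = poly_from([(1, 2.0, (1, 0))])
        best, ties = dominant_monomial(p, np.array([3.0, 1.0]))
        assert best == 0 and ties == []

    def test_tripod_vertex_triple_tie(self):
        a, b, c = 1.0, 2.0, 3.0
        p = poly_from([(1, a, (1, 0)), (1, b, (0, 1)), (1, c, (1, 1))])
        vertex = np.exp([np.log(b / c), np.log(a / c)])
        best, ties = dominant_monomial(p, vertex, tol=1e-9)
        assert len(ties) == 2

    def test_agrees_with_exhaustive_scan(self, rng):
        exps = rng.integers(0, 4, size=(5, 3))
        coeffs = rng.uniform(0.1, 10, 5)
        signs = rng.choice([-1, 1], 5)
        p = poly_from(list(zip(signs, coeffs, [tuple(e) for e in exps])))
        for _ in range(100):
            c = rng.uniform(0.05, 20, 3)
            best, _ = dominant_monomial(p, c)
            brute = np.argmax([abs(s * a * np.prod(c ** e))
                               for s, a, e in zip(p.signs,
                                                  np.exp(p.logcoeffs),
                                                  p.exponents)])
            assert best == brute

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from([-1, 1]),
                              st.floats(0.01, 100),
                              st.tuples(st.integers(0, 3),
                                        st.integers(0, 3))),
                    min_size=1, max_size=6, unique_by=lambda t: t[2]),
           st.tuples(st.floats(0.01, 50), st.floats(0.01, 50)))
    def test_max_plus_identity(self, terms, c):
        """P^tau(c) >= |a c^alpha| for every monomial, equality for the
        dominant one."""
        p = poly_from(terms)
        c = np.array(c)
        val = p.tropical_value(c)
        mags = [a * np.prod(c ** e)
                for a, e in zip(np.exp(p.logcoeffs), p.exponents)]
        assert all(val >= m * (1 - 1e-9) for m in mags)
        assert val == pytest.approx(max(mags))


class TestManifold2D:
    def test_tripod_three_arms_one_vertex(self):
        p = poly_from([(1, 1.0, (1, 0)), (1, 2.0, (0, 1)), (1, 3.0, (1, 1))])
        man = tropical_manifold_2d(p, ["x", "y"])
        assert man.n_arms == 3
        assert len(man.vertices) == 1
        assert np.allclose(man.vertices[0],
                           [np.log(2 / 3), np.log(1 / 3)], atol=1e-9)
        assert man.cells == [0, 1, 2]

    def test_single_monomial_degenerate(self):
        p = poly_from([(1, 1.0, (1, 1))])
        with pytest.raises(DegenerateManifold):
            tropical_manifold_2d(p)

    def test_two_parallel_monomials_single_line(self):
        p = poly_from([(1, 1.0, (1, 0)), (-1, 2.0, (0, 0))])
        man = tropical_manifold_2d(p)
        assert len(man.lines) == 1 and man.n_arms == 2

    @pytest.mark.parametrize("coeffs", [(1.0, 3.0, 10.0), (0.2, 7.0, 0.5)])
    def test_cells_match_grid_coloring(self, coeffs, rng):
        """Cell set equals the distinct argmax colors on a dense grid."""
        a, b, c = coeffs
        p = poly_from([(1, a, (0, 1)), (1, b, (2, 1)), (-1, c, (1, 0))])
        man = tropical_manifold_2d(p)
        us = np.linspace(-20, 20, 120)
        colors = set()
        for u1 in us:
            for u2 in us:
                colors.add(int(np.argmax(p.log_values(np.array([u1, u2])))))
        assert set(man.cells) == colors

    def test_enzymatic_tripods_have_parallel_arms(self):
        """The S and ES tropical curves are tripods with identical arm
        slopes (exponent differences agree between the two species)."""
        field = michaelis_menten_reduced_rhs()
        params = dict(k1=1.0, km1=1e-3, k2=1.0, Etot=1e-2)
        sys_t = tropicalize(field, params)
        slopes = []
        for p in sys_t.polys:
            man = tropical_manifold_2d(p, ["S", "ES"])
            assert man.n_arms == 3 and len(man.vertices) == 1
            dirs = sorted(tuple(np.round(r[1] / np.linalg.norm(r[1]), 6))
                          for r in man.rays)
            slopes.append(dirs)
        assert slopes[0] == slopes[1]


class TestSliding:
    def test_stable_balance_point_slides(self):
        p = [SignedMonomial(1, sp.Float(2.0), (0,)),
             SignedMonomial(-1, sp.Float(1.0), (1,))]
        sys1 = tropicalize(RHS(["c"], [p]), {})
        surf = surface_for_pair(sys1, 0, (0, 1))
        assert sliding_test(sys1, surf, np.array([2.0]))

    def test_same_direction_fields_cross(self):
        # dc/dt = a + b c: both monomials positive, flow never reverses
        p = [SignedMonomial(1, sp.Float(2.0), (0,)),
             SignedMonomial(1, sp.Float(1.0), (1,))]
        sys1 = tropicalize(RHS(["c"], [p]), {})
        surf = surface_for_pair(sys1, 0, (0, 1))
        assert not sliding_test(sys1, surf, np.array([2.0]))

    def test_detected_surfaces_self_consistent(self, rng):
        """Every surface returned for a random 2-species field passes the
        sliding test at freshly sampled points."""
        for trial in range(3):
            terms = []
            for _ in range(3):
                terms.append(SignedMonomial(
                    int(rng.choice([-1, 1])),
                    sp.Float(float(rng.uniform(0.1, 10))),
                    (int(rng.integers(0, 3)), int(rng.integers(0, 3)))))
            field = RHS(["x", "y"], [terms, terms])
            sys2 = tropicalize(field, {})
            box = (np.full(2, -8.0), np.full(2, 8.0))
            for surf in detect_fast_constraints(sys2, box, seed=trial):
                assert any(ok for _, ok in surf.samples)

    def test_no_sliding_system_returns_empty(self):
        p = [SignedMonomial(-1, sp.Float(1.0), (1, 0))]
        q = [SignedMonomial(1, sp.Float(1.0), (1, 0))]
        sys2 = tropicalize(RHS(["x", "y"], [p, q]), {})
        box = (np.full(2, -5.0), np.full(2, 5.0))
        assert detect_fast_constraints(sys2, box) == []

    def test_enzymatic_arms_detected_in_both_regimes(self):
        """k2 >> k-1: the sliding arms carry k1 Etot [S] = (k-1+k2)[ES]
        (linear regime) and k1 Etot [S] = k1 [S][ES] (saturated)."""
        field = michaelis_menten_reduced_rhs()
        for km1, k2 in [(1e-3, 1.0), (1.0, 1e-3)]:
            params = dict(k1=1.0, km1=km1, k2=k2, Etot=1e-2)
            sys_t = tropicalize(field, params)
            box = (np.log(np.full(2, 1e-8)), np.log(np.full(2, 1e2)))
            surfs = [s for s in detect_fast_constraints(sys_t, box, seed=1)
                     if s.species == 1]
            normals = {tuple(s.normal) for s in surfs}
            assert (1.0, -1.0) in normals       # linear-regime arm
            assert (0.0, -1.0) in normals       # saturated arm ES = Etot
            lin = next(s for s in surfs if tuple(s.normal) == (1.0, -1.0))
            assert lin.offset == pytest.approx(
                np.log((km1 + k2) / (1.0 * 1e-2)))


class TestHybridSimulation:
    def test_one_dimensional_balance_reached_and_held(self):
        p = [SignedMonomial(1, sp.Float(2.0), (0,)),
             SignedMonomial(-1, sp.Float(1.0), (1,))]
        sys1 = tropicalize(RHS(["c"], [p]), {})
        traj = simulate_hybrid(sys1, np.array([0.1]), 10.0)
        assert traj.c[-1, 0] == pytest.approx(2.0, rel=1e-6)
        assert len(traj.sliding_intervals) == 1
        t0, t1, _ = traj.sliding_intervals[0]
        assert t1 == pytest.approx(10.0)

    def test_single_monomial_system_matches_smooth_solution(self):
        # x' = -x, y' = +x: no discontinuities anywhere
        field = RHS(["x", "y"],
                    [[SignedMonomial(-1, sp.Float(1.0), (1, 0))],
                     [SignedMonomial(1, sp.Float(1.0), (1, 0))]])
        sys2 = tropicalize(field, {})
        c0 = np.array([1.0, 0.5])
        traj = simulate_hybrid(sys2, c0, 3.0)
        sol = solve_ivp(lambda t, c: [-c[0], c[0]], (0, 3.0), c0,
                        rtol=1e-10, atol=1e-12, dense_output=True)
        ref = sol.sol(traj.t).T
        assert np.abs(traj.c - ref).max() < 1e-5
        assert traj.events == []

    def test_enzymatic_tropicalization_shadows_smooth_flow(self):
        """With separated constants the tropicalized trajectory slides on
        the attracting arm and stays within log 10 of the smooth flow
        after the initial layer."""
        field = michaelis_menten_reduced_rhs()
        params = dict(k1=1.0, km1=1e-3, k2=1.0, Etot=1e-2)
        sys_t = tropicalize(field, params)
        c0 = np.array([1.0, 1e-6])
        horizon = 400.0

        def smooth(_t, c):
            S, ES = c
            return [-params["k1"] * params["Etot"] * S
                    + params["k1"] * S * ES + params["km1"] * ES,
                    params["k1"] * params["Etot"] * S
                    - params["k1"] * S * ES
                    - (params["km1"] + params["k2"]) * ES]
        sol = solve_ivp(smooth, (0, horizon), c0, method="LSODA",
                        rtol=1e-10, atol=1e-14, dense_output=True)
        traj = simulate_hybrid(sys_t, c0, horizon)
        assert traj.sliding_intervals, "expected a sliding mode"
        mask = traj.t > 5.0
        ref = np.maximum(sol.sol(traj.t[mask]).T, 1e-30)
        d = np.abs(np.log(np.maximum(traj.c[mask], 1e-30)) - np.log(ref))
        assert d.max() < np.log(10.0)
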