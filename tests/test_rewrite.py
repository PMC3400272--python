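"""Fast stoichiometry, kernel pools, elementary modes and QSS/QE
network rewriting."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

from crnred.core import (NetworkError, Reaction, ReactionNetwork, Species,
                         stoichiometric_matrix)
from crnred.fixtures import build_michaelis_menten
from crnred.rewrite import (FastSubsystem, dominance_simplify,
                            effective_parameters, elementary_modes,
                            enumerate_modes_bruteforce, fast_stoichiometry,
                            reduce_qe, reduce_qss, ReducedNetwork,
                            routes_for, solve_fast_conditions, species_pools)
from crnred.slaved import integrate_full

k1, km1, k2, Etot, Stot = sp.symbols("k1 km1 k2 Etot Stot")
S_, E_, ES_, P_ = sp.symbols("S E ES P")
MM_CONS = [(Etot, "E", [0, 1, 1, 0])]


def chain3():
    return ReactionNetwork(
        [Species("A1", initial_concentration=1.0), Species("A2"),
         Species("A3")],
        [Reaction("r1", {"A1": 1}, {"A2": 1}, sp.Symbol("ka")),
         Reaction("r2", {"A2": 1}, {"A3": 1}, sp.Symbol("kb"))],
        {"ka": 1.0, "kb": 2.0})


class TestFastStoichiometry:
    def test_qss_complex_row(self, mm_qss_net):
        fs = fast_stoichiometry(mm_qss_net, "QSS", ["ES"])
        assert fs.matrix.tolist() == [[1, -1]]
        assert fs.col_reactions == ["binding", "catalysis"]
        assert fs.excluded == []

    def test_qe_binding_column_excludes_product_row(self, mm_qss_net):
        fs = fast_stoichiometry(mm_qss_net, "QE", ["binding"])
        assert fs.row_species == ["S", "E", "ES"]
        assert fs.matrix.T.tolist() == [[-1, -1, 1]]
        assert fs.excluded == ["P"]

    def test_empty_fast_set_rejected(self, mm_qss_net):
        with pytest.raises(NetworkError):
            fast_stoichiometry(mm_qss_net, "QSS", [])

    def test_zero_column_exclusion_recorded(self):
        net = chain3()
        fs = fast_stoichiometry(net, "QSS", ["A2"])
        assert fs.excluded == []
        fs2 = fast_stoichiometry(net, "QSS", ["A3"])
        assert fs2.excluded == ["r1"]


class TestSpeciesPools:
    def test_enzymatic_pool_is_total_substrate(self, mm_qss_net):
        fs = fast_stoichiometry(mm_qss_net, "QE", ["binding"])
        pools = species_pools(mm_qss_net, fs)
        assert [p.label for p in pools] == ["S+ES"]
        assert pools[0].b == [1, 0, 1, 0]

    def test_pools_annihilate_fast_matrix(self, rng):
        for _ in range(5):
            M = sp.Matrix(rng.integers(-2, 3, size=(4, 2)).tolist())
            fs = FastSubsystem("QE", ["r1", "r2"], M, ["a", "b", "c", "d"],
                               ["r1", "r2"], [])
            net = ReactionNetwork(
                [Species(x) for x in "abcd"],
                [Reaction("r1", {"a": 1}, {"b": 1}, 1.0),
                 Reaction("r2", {"c": 1}, {"d": 1}, 1.0)], {})
            for p in species_pools(net, fs, include_trivial=False):
                restricted = [p.b[i] for i in range(4)]
                assert (sp.Matrix([restricted]) * M).norm() == 0

    def test_kernel_dimension_rank_nullity(self, rng):
        M = sp.Matrix(rng.integers(-2, 3, size=(5, 3)).tolist())
        from crnred.core import integer_left_nullspace
        basis = integer_left_nullspace(M)
        assert len(basis) == 5 - M.rank()


class TestElementaryModes:
    def test_chain_single_route(self):
        net = chain3()
        fs = fast_stoichiometry(net, "QSS", ["A2"])
        routes = routes_for(net, fs)
        assert len(routes) == 1
        assert routes[0].gamma == [1, 1]
        assert routes[0].net_stoichiometry == {"A1": -1, "A3": 1}
        assert routes[0].intermediates == []

    def test_enzymatic_route_conserves_enzyme(self, mm_qss_net):
        fs = fast_stoichiometry(mm_qss_net, "QSS", ["ES"])
        routes = routes_for(mm_qss_net, fs)
        assert len(routes) == 1
        r = routes[0]
        assert r.gamma == [1, 1]
        assert r.net_stoichiometry == {"S": -1, "P": 1}
        assert r.intermediates == ["E"]
        assert sorted(r.terminals) == ["P", "S"]

    def test_trivial_kernel_gives_no_modes(self):
        M = sp.Matrix([[1, 0], [0, 1]])
        fs = FastSubsystem("QSS", ["x", "y"], M, ["x", "y"],
                           ["r1", "r2"], [])
        assert elementary_modes(fs) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        rows = int(rng.integers(1, 5))
        cols = int(rng.integers(2, 7))
        M = sp.Matrix(rng.integers(-2, 3, size=(rows, cols)).tolist())
        irr = [bool(b) for b in rng.integers(0, 2, cols)]
        fs = FastSubsystem("QSS", ["x"], M, [],
                           [f"r{j}" for j in range(cols)], [])
        assert set(elementary_modes(fs, irr)) == \
            enumerate_modes_bruteforce(M, irr)

    def test_reversible_columns_canonical_sign(self):
        M = sp.Matrix([[1, -1]])
        fs = FastSubsystem("QSS", ["x"], M, ["x"], ["r1", "r2"], [])
        modes = elementary_modes(fs, [False, False])
        assert modes == [(1, 1)]


class TestSolveFastConditions:
    def test_linear_condition_monic_root(self):
        net = chain3()
        fs = fast_stoichiometry(net, "QSS", ["A2"])
        sols = solve_fast_conditions(net, fs)
        A1, A2 = sp.symbols("A1 A2")
        ka, kb = sp.symbols("ka kb")
        assert sp.simplify(sols[A2] - ka * A1 / kb) == 0

    def test_enzymatic_qss_michaelis_form(self, mm_qss_net):
        fs = fast_stoichiometry(mm_qss_net, "QSS", ["ES"])
        sols = solve_fast_conditions(mm_qss_net, fs, conservation=MM_CONS)
        expected = Etot * S_ / ((km1 + k2) / k1 + S_)
        assert sp.simplify(sols[ES_] - expected) == 0

    def test_enzymatic_qe_positive_quadratic_branch(self, mm_qss_net):
        fs = fast_stoichiometry(mm_qss_net, "QE", ["binding"])
        sols = solve_fast_conditions(mm_qss_net, fs,
                                     pool_symbols=[Stot, Etot])
        es = sols[ES_]
        # satisfies the quadratic and is the branch inside [0, min]
        resid = sp.simplify(k1 * (Stot - es) * (Etot - es) - km1 * es)
        assert resid == 0
        val = float(es.subs({k1: 1.0, km1: 1.0, Stot: 1.0, Etot: 0.01}))
        assert 0 < val < 0.01

    def test_equilibrium_limit_qe_equals_qss(self):
        """With no catalysis (k2 = 0) the QE and QSS conditions define the
        same manifold: the QSS value at S = Stot - ES_QE reproduces
        ES_QE."""
        net = build_michaelis_menten(2.0, 1.5, 1e-12, Etot=0.3, Stot=1.0)
        # k2 exactly 0 is encoded by an irreversible-free variant
        net_eq = ReactionNetwork(
            [Species("S", initial_concentration=1.0), Species("E"),
             Species("ES")],
            [Reaction("binding", {"S": 1, "E": 1}, {"ES": 1}, k1, km1)],
            {"k1": 2.0, "km1": 1.5, "Etot": 0.3, "Stot": 1.0})
        fs = fast_stoichiometry(net_eq, "QE", ["binding"])
        sols = solve_fast_conditions(net_eq, fs, pool_symbols=[Stot, Etot])
        num = {k1: 2.0, km1: 1.5, Stot: 1.0, Etot: 0.3}
        es_qe = float(sols[ES_].subs(num))
        # QSS balance at the QE point: k1 S E = km1 ES
        s_val = 1.0 - es_qe
        e_val = 0.3 - es_qe
        assert 2.0 * s_val * e_val == pytest.approx(1.5 * es_qe, rel=1e-9)


class TestRewrite:
    def test_enzymatic_qss_reduced_rate(self, mm_qss_net):
        red = reduce_qss(mm_qss_net, ["ES"], conservation=MM_CONS)
        assert [r.stoichiometry for r in red.reactions] == \
            [{"S": -1, "P": 1}]
        rate = red.reactions[0].rate
        expected = k2 * Etot * S_ / ((km1 + k2) / k1 + S_)
        assert sp.simplify(rate - expected) == 0
        assert not red.non_unique

    def test_enzymatic_qe_pooled_ode(self, mm_qss_net):
        red = reduce_qe(mm_qss_net, ["binding"], pool_symbols=[Stot, Etot])
        assert red.variables == ["S+ES"]
        ode = red.odes["S+ES"]
        # dStot/dt = -k2 [ES]_QE
        assert sp.simplify(ode + k2 * red.solutions[ES_]) == 0

    def test_reduced_tracks_full_trajectory(self):
        """Separation >= 1e3 between Etot and Stot: the reduced substrate
        dynamics matches the full model within 5 % after the layer."""
        net = build_michaelis_menten(10.0, 0.1, 1.0, Etot=1e-3, Stot=1.0)
        red = reduce_qss(net, ["ES"], conservation=MM_CONS)
        rate = red.reactions[0].rate
        f = sp.lambdify(S_, rate.subs({k1: 10.0, km1: 0.1, k2: 1.0,
                                       Etot: 1e-3}))
        horizon = 2000.0
        traj = integrate_full(net, horizon=horizon)
        sol = solve_ivp(lambda t, y: [-f(y[0])], (0, horizon), [1.0],
                        rtol=1e-10, atol=1e-13, dense_output=True)
        mask = traj.t > 10.0
        s_red = sol.sol(traj.t[mask])[0]
        s_full = traj.c[mask, 0]
        assert np.max(np.abs(s_red - s_full) / np.abs(s_full)) < 0.05

    def test_route_rate_linear_chain(self):
        net = chain3()
        red = reduce_qss(net, ["A2"])
        A1 = sp.Symbol("A1")
        ka = sp.Symbol("ka")
        assert sp.simplify(red.reactions[0].rate - ka * A1) == 0
        assert red.odes["A1"] == -red.odes["A3"]


class TestEffectiveParameters:
    def test_enzymatic_effective_set(self, mm_qss_net):
        red = reduce_qss(mm_qss_net, ["ES"], conservation=MM_CONS)
        eps = {str(p.expr): p for p in effective_parameters(red)}
        assert str(Etot * k2) in eps
        km = eps[str((k2 + km1) / k1)]
        assert not km.is_monomial
        mono = eps[str(Etot * k2)]
        assert mono.is_monomial and mono.exponents == {"Etot": 1, "k2": 1}

    def test_dominance_turns_composite_into_monomial(self):
        km = (km1 + k2) / k1
        out = dominance_simplify(km, {"km1": 1e-4, "k2": 1.0, "k1": 2.0})
        assert sp.simplify(out - k2 / k1) == 0

    def test_identity_reduction_empty_list(self):
        red = ReducedNetwork("QSS", ["A"], {"A": sp.Integer(0)})
        assert effective_parameters(red) == []
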