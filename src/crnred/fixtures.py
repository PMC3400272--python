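"""Synthetic network generators, canonical small models and separation
diagnostics.

The generators are seed-deterministic: the same arguments and seed always
produce the same network.  `generate_separated_monomolecular` draws a
random simple digraph and assigns constants eps**rank for a random
permutation of edge ranks, so the constants are totally separated by
construction whenever eps is well below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .core import RHS, Reaction, ReactionNetwork, SignedMonomial, Species

__all__ = [
    "SeparationReport", "generate_separated_monomolecular",
    "build_michaelis_menten", "michaelis_menten_reduced_rhs",
    "build_cell_cycle", "check_total_separation", "zipf_diagnostic",
    "slow_manifold_dimension",
]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_separated_monomolecular(n: int, m: int, eps: float,
                                     seed: int) -> ReactionNetwork:
    """Random monomolecular network with totally separated constants.

    ``m`` edges are drawn without replacement from the n(n-1) ordered
    pairs; edge e gets constant eps**pi(e) for a random permutation pi of
    1..m, so adjacent sorted constants differ by the factor 1/eps.
    """
    if not 0 < eps < 1:
        raise ValueError("eps must be in (0, 1)")
    if m > n * (n - 1):
        raise ValueError("too many edges for a simple digraph")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    chosen = rng.choice(len(pairs), size=m, replace=False)
    ranks = rng.permutation(m) + 1
    species = [Species(f"A{i+1}", initial_concentration=1.0)
               for i in range(n)]
    reactions = []
    params = {}
    for e, (pi, rank) in enumerate(zip(chosen, ranks)):
        i, j = pairs[pi]
        pname = f"k{e+1}"
        params[pname] = float(eps) ** int(rank)
        reactions.append(Reaction(f"r{e+1}",
                                  {f"A{i+1}": 1}, {f"A{j+1}": 1},
                                  sp.Symbol(pname)))
    return ReactionNetwork(species, reactions, params)


# ---------------------------------------------------------------------------
# canonical enzymatic mechanism  S + E <-> ES -> P + E
# ---------------------------------------------------------------------------

def build_michaelis_menten(k1: float, km1: float, k2: float,
                           Etot: float, Stot: float) -> ReactionNetwork:
    """Full 4-species enzymatic mechanism with symbolic constants
    k1 (binding), km1 (unbinding), k2 (catalysis); initial state
    [S]=Stot, [E]=Etot, [ES]=[P]=0."""
    species = [Species("S", initial_concentration=Stot),
               Species("E", initial_concentration=Etot),
               Species("ES", initial_concentration=0.0),
               Species("P", initial_concentration=0.0)]
    reactions = [
        Reaction("binding", {"S": 1, "E": 1}, {"ES": 1},
                 sp.Symbol("k1"), sp.Symbol("km1")),
        Reaction("catalysis", {"ES": 1}, {"P": 1, "E": 1},
                 sp.Symbol("k2")),
    ]
    params = {"k1": k1, "km1": km1, "k2": k2,
              "Etot": Etot, "Stot": Stot}
    return ReactionNetwork(species, reactions, params)


def michaelis_menten_reduced_rhs() -> RHS:
    """Two-variable form after eliminating E and P by the conservation
    laws E + ES = Etot and S + ES + P = Stot:

        d[S]/dt  = -k1 Etot [S] + k1 [S][ES] + km1 [ES]
        d[ES]/dt =  k1 Etot [S] - k1 [S][ES] - (km1 + k2) [ES]

    Monomials are kept unmerged so km1 [ES] and k2 [ES] can be compared
    individually during dominance pruning.
    """
    k1, km1, k2, Etot = sp.symbols("k1 km1 k2 Etot")
    mono_S = [
        SignedMonomial(-1, k1 * Etot, (1, 0), ("binding", "fwd")),
        SignedMonomial(1, k1, (1, 1), ("binding", "fwd")),
        SignedMonomial(1, km1, (0, 1), ("binding", "rev")),
    ]
    mono_ES = [
        SignedMonomial(1, k1 * Etot, (1, 0), ("binding", "fwd")),
        SignedMonomial(-1, k1, (1, 1), ("binding", "fwd")),
        SignedMonomial(-1, km1, (0, 1), ("binding", "rev")),
        SignedMonomial(-1, k2, (0, 1), ("catalysis", "fwd")),
    ]
    return RHS(["S", "ES"], [mono_S, mono_ES])


# ---------------------------------------------------------------------------
# five-variable cell-cycle oscillator
# ---------------------------------------------------------------------------

def build_cell_cycle(k1: float, k3: float, k4: float, k4p: float,
                     k6: float, k8: float, k9: float,
                     C: float, y0: dict[str, float] | None = None
                     ) -> ReactionNetwork:
    """Five-variable cell-cycle model

        y1' = k9 y2 - k8 y1 + k6 y3
        y2' = k8 y1 - k9 y2 - k3 y2 y5
        y3' = k4p y4 + k4 y4 y3^2 / C^2 - k6 y3
        y4' = -k4p y4 - k4 y4 y3^2 / C^2 + k3 y2 y5
        y5' = k1 - k3 y2 y5

    written as a mass-action network; y1+y2+y3+y4 = C is conserved.
    The caller supplies all parameter values.
    """
    y0 = y0 or {}
    species = [Species(f"y{i}", initial_concentration=y0.get(f"y{i}", 0.0))
               for i in range(1, 6)]
    k1s, k3s, k4s, k4ps, k6s, k8s, k9s, Cs = sp.symbols(
        "k1 k3 k4 k4p k6 k8 k9 C")
    reactions = [
        Reaction("r_exchange", {"y1": 1}, {"y2": 1}, k8s, k9s),
        Reaction("r_return", {"y3": 1}, {"y1": 1}, k6s),
        Reaction("r_activation", {"y2": 1, "y5": 1}, {"y4": 1}, k3s),
        Reaction("r_conversion", {"y4": 1}, {"y3": 1}, k4ps),
        Reaction("r_autocatalysis", {"y4": 1, "y3": 2}, {"y3": 3},
                 k4s / Cs ** 2),
        Reaction("r_synthesis", {}, {"y5": 1}, k1s),
    ]
    params = {"k1": k1, "k3": k3, "k4": k4, "k4p": k4p, "k6": k6,
              "k8": k8, "k9": k9, "C": C}
    return ReactionNetwork(species, reactions, params)


def slow_manifold_dimension(constraints, variables,
                            n_samples: int = 5, seed: int = 0) -> int:
    """Generic dimension of the solution set of polynomial constraints:
    number of variables minus the Jacobian rank at random positive points
    (the maximum rank over samples, i.e. the generic rank)."""
    variables = [sp.Symbol(v) if isinstance(v, str) else v
                 for v in variables]
    J = sp.Matrix([[sp.diff(sp.sympify(c), v) for v in variables]
                   for c in constraints])
    rng = np.random.default_rng(seed)
    best = 0
    for _ in range(n_samples):
        pt = {v: sp.Float(x) for v, x in
              zip(variables, rng.uniform(0.5, 2.0, len(variables)))}
        Jn = np.array(J.subs(pt), dtype=float)
        best = max(best, np.linalg.matrix_rank(Jn))
    return len(variables) - best


# ---------------------------------------------------------------------------
# convergence benchmark for the linear multiscale reduction
# ---------------------------------------------------------------------------

def linear_reduction_benchmark(eps_list=(1e-1, 1e-2, 1e-3), n: int = 6,
                               m: int = 8, n_networks: int = 20,
                               seed0: int = 0, n_times: int = 40):
    """Full-vs-reduced benchmark over seeded random monomolecular
    networks.

    For each seed and separation eps, the network is reduced, trajectories
    of the original and reduced kinetic matrices are compared in sup norm
    over a log-spaced time grid covering all timescales, and each
    approximate eigenvalue is compared with the exact spectrum of the
    rational kinetic matrix (constants as exact powers of eps).  Seeds
    whose derived monomial constants tie (total separation violated) are
    skipped.  Returns (per-eps sup-norm errors, per-eps max eigenvalue
    relative errors, number of networks used).
    """
    from .core import NetworkError
    from .linear import (TieError, eigenvalues_exact, exact_solution_mp,
                         kinetic_matrix, kinetic_matrix_rational,
                         monomolecular_digraph, reduce_monomolecular)
    from .linear import spectral_approximation

    errs = {e: [] for e in eps_list}
    eig_rel = {e: [] for e in eps_list}
    seed, used = seed0, 0
    while used < n_networks and seed < seed0 + 10 * n_networks:
        seed += 1
        try:
            per_eps = {}
            for eps in eps_list:
                net = generate_separated_monomolecular(n, m, eps, seed)
                g = monomolecular_digraph(net)
                red = reduce_monomolecular(g)
                K = kinetic_matrix(g.nodes, g.edges, g.params)
                Kr = kinetic_matrix(red.nodes, red.edge_list(), red.params)
                kv = [v for v, _ in net.k_values()]
                ts = np.logspace(np.log10(1 / max(kv)) - 1,
                                 np.log10(1 / min(kv)) + 1, n_times)
                c0 = np.zeros(n)
                c0[0] = 1.0
                C, _ = exact_solution_mp(K, c0, ts)
                Cr, _ = exact_solution_mp(Kr, c0, ts)
                # exact spectrum with constants as exact powers of eps
                eps_rat = sp.nsimplify(eps, rational=True)
                rat = {a: eps_rat ** round(np.log(v) / np.log(eps))
                       for a, v in net.parameters.items()}
                Kx = kinetic_matrix_rational(g.nodes, g.edges, rat)
                ev = eigenvalues_exact(Kx)
                spec = spectral_approximation(red)
                rel = max(np.min(np.abs(ev - lam) / abs(lam))
                          for lam in spec.eigenvalues)
                per_eps[eps] = (float(np.abs(C - Cr).max()), float(rel))
        except (TieError, NetworkError):
            continue
        for eps in eps_list:
            errs[eps].append(per_eps[eps][0])
            eig_rel[eps].append(per_eps[eps][1])
        used += 1
    return errs, eig_rel, used


# ---------------------------------------------------------------------------
# separation diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SeparationReport:
    sorted_constants: np.ndarray        # descending
    min_adjacent_ratio: float           # smallest ratio between neighbours
    totally_separated: bool
    factor: float


def check_total_separation(constants, factor: float = 10.0
                           ) -> SeparationReport:
    """Totally separated at ``factor`` iff every adjacent ratio of the
    sorted constants is at least ``factor``."""
    k = np.sort(np.asarray(list(constants), dtype=float))[::-1]
    if np.any(k <= 0):
        raise ValueError("constants must be positive")
    if len(k) < 2:
        return SeparationReport(k, np.inf, True, factor)
    ratios = k[:-1] / k[1:]
    # tolerate float representation error in ratios that are exactly at
    # the threshold (e.g. powers of 0.1)
    return SeparationReport(k, float(ratios.min()),
                            bool(np.all(ratios >= factor * (1 - 1e-12))),
                            factor)


def zipf_diagnostic(values, n_bins: int = 20):
    """Power-law exponent of the empirical density of positive values.

    A log-uniform distribution has density p(c) proportional to 1/c, i.e.
    a power law with exponent -1; wide log-scale supports with this
    exponent indicate total separation.  The exponent is estimated by
    least squares on log(density) vs log(value) over logarithmic bins
    (empty bins skipped).  Returns (slope, standard_error) and, in the
    third position, the raw slope of the log(value)-log(rank) plot for
    reference.
    """
    v = np.asarray(list(values), dtype=float)
    if len(v) < 10:
        raise ValueError("need at least 10 values")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    if v.max() == v.min():
        raise ValueError("degenerate input: all values equal")
    bins = np.logspace(np.log10(v.min()), np.log10(v.max()), n_bins + 1)
    bins[-1] *= 1 + 1e-12
    counts, edges = np.histogram(v, bins=bins)
    dens = counts / np.diff(edges)
    mids = np.sqrt(edges[1:] * edges[:-1])
    mask = counts > 0
    x, y = np.log(mids[mask]), np.log(dens[mask])
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    dof = max(len(x) - 2, 1)
    s2 = float(res[0]) / dof if len(res) else 0.0
    se = float(np.sqrt(s2 / np.sum((x - x.mean()) ** 2)))
    # secondary: rank-plot slope
    vs = np.sort(v)[::-1]
    r = np.arange(1, len(vs) + 1)
    B = np.vstack([np.log(r), np.ones_like(r, dtype=float)]).T
    rank_slope = float(np.linalg.lstsq(B, np.log(vs), rcond=None)[0][0])
    return slope, se, rank_slope
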