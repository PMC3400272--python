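"""Rewriting a non-linear network under QSS or QE assumptions.

The fast part of the dynamics is encoded in a stoichiometric matrix S^f:

* QSS mode: rows of S^f are the fast (low-concentration) species,
  columns the reactions that act on them (zero columns excluded);
* QE mode: columns of S^f are the fast reversible reactions, rows the
  species they affect (zero rows excluded).

Species pools are integer vectors b in the left kernel, b^T S^f = 0
(conservation laws of the fast subsystem); pools that are conservation
laws of the full network are constants and are filtered out.  Reaction
pools (routes) are integer vectors g in the right kernel, S^f g = 0,
chosen support-minimal with non-negative entries on irreversible
reactions — the elementary modes of the fast subsystem.  All kernel
algebra is exact (rational arithmetic, primitive integer output).

After pooling, the QE or QSS algebraic conditions are solved for the
fast species, each route becomes one reduced reaction whose rate is
fixed by matching the net production of every terminal species to the
unreduced model, and the coefficients of the reduced rates are extracted
as effective parameters — monomials (or simple rational composites) of
the original constants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .core import (NetworkError, ReactionNetwork, conservation_laws,
                   integer_left_nullspace, integer_right_nullspace, rhs,
                   stoichiometric_matrix, _primitive_integer)

__all__ = [
    "FastSubsystem", "SpeciesPool", "Route", "ReducedNetwork",
    "ReducedReaction", "EffectiveParameter", "BranchAmbiguityError",
    "fast_stoichiometry", "species_pools", "elementary_modes",
    "enumerate_modes_bruteforce", "routes_for", "solve_fast_conditions",
    "rewrite_network", "reduce_qss", "reduce_qe", "effective_parameters",
    "dominance_simplify",
]


class BranchAmbiguityError(NetworkError):
    """Several admissible positive branches solve the fast conditions."""


# ---------------------------------------------------------------------------
# fast stoichiometry
# ---------------------------------------------------------------------------

@dataclass
class FastSubsystem:
    mode: str                                   # "QSS" | "QE"
    fast: list[str]                             # species ids or reaction ids
    matrix: sp.Matrix                           # S^f, exact integers
    row_species: list[str]
    col_reactions: list[str]
    excluded: list[str]                         # zero rows/columns dropped


def fast_stoichiometry(net: ReactionNetwork, mode: str,
                       fast_set: Sequence[str]) -> FastSubsystem:
    """Build S^f for the given mode and fast set (species ids for QSS,
    reaction ids for QE)."""
    fast = list(fast_set)
    if not fast:
        raise NetworkError("fast set must be non-empty")
    S = sp.Matrix(stoichiometric_matrix(net).tolist())
    sidx = {s: i for i, s in enumerate(net.species_ids)}
    ridx = {r.id: j for j, r in enumerate(net.reactions)}
    mode = mode.upper()
    if mode == "QSS":
        for s in fast:
            if s not in sidx:
                raise NetworkError(f"unknown species {s}")
        rows = [sidx[s] for s in fast]
        cols, excl = [], []
        for j, r in enumerate(net.reactions):
            if any(S[i, j] != 0 for i in rows):
                cols.append(j)
            else:
                excl.append(r.id)
        M = S[rows, cols] if cols else sp.zeros(len(rows), 0)
        return FastSubsystem("QSS", fast, M, list(fast),
                             [net.reactions[j].id for j in cols], excl)
    if mode == "QE":
        for r in fast:
            if r not in ridx:
                raise NetworkError(f"unknown reaction {r}")
        cols = [ridx[r] for r in fast]
        rows, excl = [], []
        for i, s in enumerate(net.species_ids):
            if any(S[i, j] != 0 for j in cols):
                rows.append(i)
            else:
                excl.append(s)
        M = S[rows, cols] if rows else sp.zeros(0, len(cols))
        return FastSubsystem("QE", fast, M,
                             [net.species_ids[i] for i in rows],
                             list(fast), excl)
    raise ValueError("mode must be 'QSS' or 'QE'")


# ---------------------------------------------------------------------------
# species pools (QE)
# ---------------------------------------------------------------------------

@dataclass
class SpeciesPool:
    b: list[int]                       # over all network species
    label: str
    is_trivial: bool = False           # singleton for an unaffected species


def _in_rowspan(vec, rows) -> bool:
    if not rows:
        return all(x == 0 for x in vec)
    M = sp.Matrix(rows)
    aug = sp.Matrix(rows + [list(vec)])
    return M.rank() == aug.rank()


def _pool_label(b, species_ids) -> str:
    terms = []
    for coef, s in zip(b, species_ids):
        if coef == 0:
            continue
        if coef == 1:
            terms.append(s)
        elif coef == -1:
            terms.append(f"-{s}")
        else:
            terms.append(f"{coef}*{s}")
    return "+".join(terms).replace("+-", "-") or "0"


def species_pools(net: ReactionNetwork, fs: FastSubsystem,
                  include_trivial: bool = True) -> list[SpeciesPool]:
    """Slow species pools: integer basis of the left kernel of S^f,
    reduced modulo the conservation laws of the full network.

    Pools of the affected species come first; unaffected species are
    appended as trivial singleton pools.  Any candidate lying in the span
    of the full-network laws plus previously accepted pools is dropped
    (it carries no new slow variable)."""
    if fs.mode != "QE":
        raise NetworkError("species pools are defined for QE mode")
    n = net.n_species
    sidx = {s: i for i, s in enumerate(net.species_ids)}
    kernel = integer_left_nullspace(fs.matrix)
    candidates: list[tuple[list[int], bool]] = []
    for b in kernel:
        full = [0] * n
        for coef, s in zip(b, fs.row_species):
            full[sidx[s]] = coef
        candidates.append((full, False))
    if include_trivial:
        for s in fs.excluded:
            full = [0] * n
            full[sidx[s]] = 1
            candidates.append((full, True))
    laws = conservation_laws(net)
    accepted: list[SpeciesPool] = []
    span = [list(b) for b in laws]
    for full, trivial in candidates:
        if _in_rowspan(full, span):
            continue
        span.append(list(full))
        accepted.append(SpeciesPool(full, _pool_label(full, net.species_ids),
                                    trivial))
    return accepted


# ---------------------------------------------------------------------------
# elementary modes (QSS routes)
# ---------------------------------------------------------------------------

@dataclass
class Route:
    gamma: list[int]                   # over the columns of S^f
    reactions: list[str]               # column labels
    net_stoichiometry: dict[str, int]  # over non-fast species
    terminals: list[str]
    intermediates: list[str]
    label: str = ""


def _canonical(vec: Sequence, irreversible: Sequence[bool]) -> tuple | None:
    """Primitive integer vector with canonical sign; None if infeasible."""
    v = _primitive_integer([sp.Rational(x) for x in vec])
    has_pos = any(v[j] > 0 and irreversible[j] for j in range(len(v)))
    has_neg = any(v[j] < 0 and irreversible[j] for j in range(len(v)))
    if has_pos and has_neg:
        return None
    if has_neg:
        v = [-x for x in v]
    elif not has_pos:
        # purely reversible support: fix sign by first nonzero entry
        for x in v:
            if x != 0:
                if x < 0:
                    v = [-y for y in v]
                break
    return tuple(v)


def enumerate_modes_bruteforce(M: sp.Matrix,
                               irreversible: Sequence[bool]
                               ) -> set[tuple[int, ...]]:
    """Independent reference: all support-minimal kernel vectors of M by
    exhaustive support enumeration (kernel restricted to each support must
    be one-dimensional and sign-feasible)."""
    M = sp.Matrix(M)
    ncols = M.cols
    found: list[set[int]] = []
    modes: set[tuple[int, ...]] = set()
    for size in range(1, ncols + 1):
        for supp in itertools.combinations(range(ncols), size):
            ss = set(supp)
            if any(f < ss for f in found):
                continue
            sub = M[:, list(supp)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            v = null[0]
            if any(v[k] == 0 for k in range(len(supp))):
                continue
            gamma = [0] * ncols
            for k, j in enumerate(supp):
                gamma[j] = v[k]
            canon = _canonical(gamma, irreversible)
            if canon is None:
                continue
            if any(f <= ss for f in found):
                continue
            found.append(ss)
            modes.add(canon)
    return modes


def _double_description(M: np.ndarray) -> list[np.ndarray]:
    """Extreme rays of {x >= 0 : M x = 0} (rational arithmetic via
    fractions embedded in object arrays is avoided; integer input keeps
    exactness with Python ints)."""
    ncols = M.shape[1]
    rays: list[tuple] = [tuple(1 if j == k else 0 for j in range(ncols))
                         for k in range(ncols)]
    for row in M:
        row = [int(x) for x in row]
        vals = [sum(r * a for r, a in zip(ray, row)) for ray in rays]
        zero = [rays[i] for i, v in enumerate(vals) if v == 0]
        pos = [(rays[i], v) for i, v in enumerate(vals) if v > 0]
        neg = [(rays[i], v) for i, v in enumerate(vals) if v < 0]
        new = list(zero)
        for (rp, vp), (rn, vn) in itertools.product(pos, neg):
            comb = tuple(vp * n - vn * p for p, n in zip(rp, rn))
            g = 0
            for x in comb:
                g = np.gcd(g, abs(int(x)))
            if g > 1:
                comb = tuple(int(x) // g for x in comb)
            new.append(comb)
        # keep only rays with support-minimal zero sets (extreme rays)
        filtered = []
        supports = [frozenset(j for j, x in enumerate(r) if x != 0)
                    for r in new]
        for i, r in enumerate(new):
            if any(k != i and supports[k] < supports[i]
                   for k in range(len(new))):
                continue
            if r in filtered:
                continue
            filtered.append(r)
        rays = filtered
    return [np.array(r, dtype=object) for r in rays]


def elementary_modes(fs: FastSubsystem,
                     irreversible: Sequence[bool] | None = None
                     ) -> list[tuple[int, ...]]:
    """Support-minimal integer kernel vectors of S^f with non-negative
    entries on irreversible reactions (double-description on the cone
    with reversible columns split into two opposite irreversible ones).
    """
    M = sp.Matrix(fs.matrix)
    ncols = M.cols
    if irreversible is None:
        irreversible = [True] * ncols
    irreversible = list(irreversible)
    # split reversible columns
    split_cols = []
    col_map = []                       # (original index, sign)
    for j in range(ncols):
        split_cols.append([int(M[i, j]) for i in range(M.rows)])
        col_map.append((j, 1))
        if not irreversible[j]:
            split_cols.append([-int(M[i, j]) for i in range(M.rows)])
            col_map.append((j, -1))
    A = np.array(split_cols, dtype=object).T if split_cols else \
        np.zeros((M.rows, 0), dtype=object)
    rays = _double_description(A) if A.shape[1] else []
    modes: set[tuple[int, ...]] = set()
    for ray in rays:
        gamma = [0] * ncols
        for val, (j, sgn) in zip(ray, col_map):
            gamma[j] += sgn * int(val)
        if all(x == 0 for x in gamma):
            continue                    # futile forward/backward cycle
        canon = _canonical(gamma, irreversible)
        if canon is not None:
            modes.add(canon)
    # final support-minimality filter across recombined modes
    out = []
    supports = {m: frozenset(j for j, x in enumerate(m) if x != 0)
                for m in modes}
    for m in sorted(modes):
        if any(supports[o] < supports[m] for o in modes if o != m):
            continue
        out.append(m)
    return out


def routes_for(net: ReactionNetwork, fs: FastSubsystem) -> list[Route]:
    """Elementary modes of the fast subsystem as Route records with net
    stoichiometry, terminal and intermediate species."""
    if fs.mode != "QSS":
        raise NetworkError("routes are defined for QSS mode")
    irr = [not r.reversible for r in net.reactions
           if r.id in fs.col_reactions]
    modes = elementary_modes(fs, irr)
    S = stoichiometric_matrix(net)
    ridx = {r.id: j for j, r in enumerate(net.reactions)}
    fast = set(fs.fast)
    out = []
    for m, gamma in enumerate(modes):
        nu = np.zeros(net.n_species, dtype=int)
        for g, rid in zip(gamma, fs.col_reactions):
            nu += g * S[:, ridx[rid]]
        stoich = {}
        terms, inters = [], []
        for i, s in enumerate(net.species_ids):
            if s in fast:
                if nu[i] != 0:
                    raise NetworkError("route does not conserve fast "
                                       f"species {s}")
                continue
            touched = any(g != 0 and S[i, ridx[rid]] != 0
                          for g, rid in zip(gamma, fs.col_reactions))
            if nu[i] != 0:
                stoich[s] = int(nu[i])
                terms.append(s)
            elif touched:
                inters.append(s)
        out.append(Route(list(gamma), list(fs.col_reactions), stoich,
                         terms, inters, label=f"route{m+1}"))
    return out


# ---------------------------------------------------------------------------
# solving the fast conditions
# ---------------------------------------------------------------------------

def _positive_branch(solutions: list[dict], unknowns, sample_subs,
                     upper: Mapping | None = None):
    """Pick the solution dict whose unknowns are all positive (and below
    optional upper bounds) at a numeric sample point."""
    good = []
    for sol in solutions:
        ok = True
        for u in unknowns:
            try:
                v = complex(sp.sympify(sol[u]).subs(sample_subs))
            except (TypeError, KeyError):
                ok = False
                break
            if abs(v.imag) > 1e-9 * max(1.0, abs(v.real)) or v.real <= 0:
                ok = False
                break
            if upper and u in upper:
                ub = float(sp.sympify(upper[u]).subs(sample_subs))
                if v.real > ub * (1 + 1e-9):
                    ok = False
                    break
        if ok:
            good.append(sol)
    if not good:
        raise NetworkError("no positive branch solves the fast conditions")
    if len(good) > 1:
        raise BranchAmbiguityError(
            f"{len(good)} admissible positive branches: {good}")
    return good[0]


def solve_fast_conditions(net: ReactionNetwork, fs: FastSubsystem,
                          method: str = "symbolic",
                          conservation=None,
                          pool_symbols: Sequence[sp.Symbol] | None = None,
                          sample: Mapping | None = None) -> dict:
    """Solve the QSS (P_i = 0) or QE (R+ = R-, pools fixed) conditions
    for the fast species; returns {species symbol: expression}.

    ``conservation`` (QSS mode): list of (total_symbol, species_to_eliminate,
    law_vector) tuples describing conserved totals used to close the fast
    equations — e.g. the total enzyme when the free enzyme tracks the
    complex.  ``pool_symbols`` (QE mode): one symbol per fast-subsystem
    pool in the order of the left-kernel basis.  ``sample`` overrides the
    numeric point used for positive-branch selection.
    """
    if method not in {"symbolic", "dominance"}:
        raise ValueError("method must be 'symbolic' or 'dominance'")
    field = rhs(net, merge=True)
    syms = {s: sp.Symbol(s) for s in net.species_ids}
    sample_subs = dict(net.param_subs())
    if sample:
        sample_subs.update({sp.Symbol(str(k)) if not isinstance(k, sp.Symbol)
                            else k: v for k, v in sample.items()})

    if fs.mode == "QSS":
        unknowns = [syms[s] for s in fs.fast]
        eqs = [field.expr(net.species_index(s)) for s in fs.fast]
        upper = {}
        for item in (conservation or []):
            total_sym, elim, law = item
            expr = total_sym - sum(int(b) * syms[s]
                                   for b, s in zip(law, net.species_ids)
                                   if s != elim and b != 0)
            coef = law[net.species_index(elim)]
            if coef != 1:
                expr = expr / int(coef)
            eqs = [e.subs(syms[elim], expr) for e in eqs]
            for u in unknowns:
                upper.setdefault(u, total_sym)
        # default numeric sample for slow species / totals: 1.0
        for e in eqs:
            for s in e.free_symbols:
                sample_subs.setdefault(s, 1.0)
        for u in unknowns:
            sample_subs.pop(u, None)
        sols = sp.solve(eqs, unknowns, dict=True)
        if not sols:
            raise NetworkError("fast conditions unsolvable symbolically")
        # sample value for unknown-bound check must not include unknowns
        sel = _positive_branch(sols, unknowns, sample_subs, upper)
        return {u: sp.simplify(sel[u]) for u in unknowns}

    # QE mode: equilibrium of each fast reaction + pool constraints
    unknowns = [syms[s] for s in fs.row_species]
    ridx = {r.id: r for r in net.reactions}
    eqs = []
    for rid in fs.col_reactions:
        r = ridx[rid]
        if not r.reversible:
            raise NetworkError(f"QE reaction {rid} must be reversible")
        fwd = r.k_forward
        for s, nn in r.reactants.items():
            fwd *= syms[s] ** nn
        rev = r.k_backward
        for s, nn in r.products.items():
            rev *= syms[s] ** nn
        eqs.append(sp.expand(fwd - rev))
    kernel = integer_left_nullspace(fs.matrix)
    if pool_symbols is None:
        pool_symbols = [sp.Symbol(f"T{k+1}") for k in range(len(kernel))]
    upper = {}
    for b, tsym in zip(kernel, pool_symbols):
        eqs.append(sum(int(x) * syms[s]
                       for x, s in zip(b, fs.row_species)) - tsym)
        for x, s in zip(b, fs.row_species):
            if x == 1 and all(y >= 0 for y in b):
                upper.setdefault(syms[s], tsym)
    for e in eqs:
        for s in e.free_symbols:
            sample_subs.setdefault(s, 1.0)
    for u in unknowns:
        sample_subs.pop(u, None)
    sols = sp.solve(eqs, unknowns, dict=True)
    if not sols:
        raise NetworkError("QE conditions unsolvable symbolically")
    sel = _positive_branch(sols, unknowns, sample_subs, upper)
    return {u: sp.simplify(sel[u]) for u in unknowns}


# ---------------------------------------------------------------------------
# reduced network construction
# ---------------------------------------------------------------------------

@dataclass
class ReducedReaction:
    id: str
    stoichiometry: dict[str, int]      # over reduced variables
    rate: sp.Expr
    provenance: dict[str, int]         # original reaction -> gamma


@dataclass
class EffectiveParameter:
    name: str
    expr: sp.Expr
    is_monomial: bool
    exponents: dict[str, int] | None = None


@dataclass
class ReducedNetwork:
    mode: str
    variables: list[str]               # slow species and/or pool labels
    odes: dict[str, sp.Expr]
    reactions: list[ReducedReaction] = field(default_factory=list)
    fast: list[str] = field(default_factory=list)
    solutions: dict = field(default_factory=dict)
    pools: list[SpeciesPool] = field(default_factory=list)
    non_unique: bool = False
    parameters: dict[str, float] = field(default_factory=dict)


def rewrite_network(net: ReactionNetwork, fs: FastSubsystem, solutions: dict,
                    pools_or_routes=None, **kw) -> ReducedNetwork:
    """Dispatch to QSS (route-based) or QE (pool-based) rewriting."""
    if fs.mode == "QSS":
        return _rewrite_qss(net, fs, solutions, pools_or_routes, **kw)
    return _rewrite_qe(net, fs, solutions, pools_or_routes, **kw)


def _rewrite_qss(net, fs, solutions, routes, conservation=None,
                 check: bool = True):
    routes = routes if routes is not None else routes_for(net, fs)
    field = rhs(net, merge=True)
    syms = {s: sp.Symbol(s) for s in net.species_ids}
    sub_fast = {u: e for u, e in solutions.items()}
    # eliminate conserved partners (e.g. free enzyme via the total) before
    # substituting the fast solutions
    sub_elim = {}
    eliminated = set()
    for item in (conservation or []):
        total_sym, elim, law = item
        expr = total_sym - sum(int(b) * syms[s]
                               for b, s in zip(law, net.species_ids)
                               if s != elim and b != 0)
        coef = law[net.species_index(elim)]
        if coef != 1:
            expr = expr / int(coef)
        sub_elim[syms[elim]] = expr
        eliminated.add(elim)
    slow = [s for s in net.species_ids
            if s not in set(fs.fast) and s not in eliminated]
    # match net production of each terminal species
    rate_syms = [sp.Symbol(f"R_{r.label}") for r in routes]
    terminals = sorted({t for r in routes for t in r.terminals
                        if t not in eliminated})
    eqs = []
    for t in terminals:
        produced = sum(r.net_stoichiometry.get(t, 0) * R
                       for r, R in zip(routes, rate_syms))
        target = sp.simplify(field.expr(net.species_index(t))
                             .subs(sub_elim).subs(sub_fast))
        eqs.append(sp.Eq(produced, target))
    sol = sp.solve(eqs, rate_syms, dict=True)
    non_unique = False
    if not sol:
        raise NetworkError(
            "terminal-species matching system is inconsistent; residuals: "
            + str([sp.simplify(e.lhs - e.rhs) for e in eqs]))
    rates = sol[0]
    free = [R for R in rate_syms if R not in rates]
    if free:
        non_unique = True
        rates = {R: sp.simplify(v.subs({f: 0 for f in free}))
                 for R, v in rates.items()}
        rates.update({f: sp.Integer(0) for f in free})
    if check:
        for t in terminals:
            resid = sp.simplify(
                sum(r.net_stoichiometry.get(t, 0) * rates[R]
                    for r, R in zip(routes, rate_syms))
                - field.expr(net.species_index(t))
                .subs(sub_elim).subs(sub_fast))
            if resid != 0:
                raise NetworkError(f"rate matching failed for {t}: {resid}")
    rr = []
    odes = {s: sp.Integer(0) for s in slow}
    for r, R in zip(routes, rate_syms):
        rate = sp.simplify(rates[R])
        rr.append(ReducedReaction(
            r.label, dict(r.net_stoichiometry), rate,
            {rid: g for rid, g in zip(r.reactions, r.gamma) if g}))
        for s, nu in r.net_stoichiometry.items():
            if s in odes:
                odes[s] = odes[s] + nu * rate
    odes = {s: sp.simplify(e) for s, e in odes.items()}
    return ReducedNetwork("QSS", slow, odes, rr, list(fs.fast),
                          solutions, [], non_unique,
                          dict(net.parameters))


def _rewrite_qe(net, fs, solutions, pools=None,
                pool_symbols: Sequence[sp.Symbol] | None = None):
    pools = pools if pools is not None else species_pools(net, fs)
    field = rhs(net, merge=True)
    syms = {s: sp.Symbol(s) for s in net.species_ids}
    sub_fast = dict(solutions)
    odes = {}
    for pool in pools:
        expr = sum(int(b) * field.expr(i)
                   for i, b in enumerate(pool.b) if b != 0)
        odes[pool.label] = sp.simplify(sp.sympify(expr).subs(sub_fast))
    return ReducedNetwork("QE", [p.label for p in pools], odes, [],
                          list(fs.fast), solutions, pools, False,
                          dict(net.parameters))


def reduce_qss(net: ReactionNetwork, fast_species: Sequence[str],
               conservation=None) -> ReducedNetwork:
    """One-call QSS pipeline: S^f, elementary modes, symbolic solution of
    P_i = 0, route rates by terminal matching."""
    fs = fast_stoichiometry(net, "QSS", fast_species)
    sols = solve_fast_conditions(net, fs, conservation=conservation)
    return _rewrite_qss(net, fs, sols, routes_for(net, fs),
                        conservation=conservation)


def reduce_qe(net: ReactionNetwork, fast_reactions: Sequence[str],
              pool_symbols: Sequence[sp.Symbol] | None = None
              ) -> ReducedNetwork:
    """One-call QE pipeline: S^f, pools, equilibrium solution, pooled
    slow ODEs."""
    fs = fast_stoichiometry(net, "QE", fast_reactions)
    sols = solve_fast_conditions(net, fs, pool_symbols=pool_symbols)
    return _rewrite_qe(net, fs, sols, pool_symbols=pool_symbols)


# ---------------------------------------------------------------------------
# effective parameters
# ---------------------------------------------------------------------------

def _is_monomial(expr: sp.Expr) -> bool:
    if expr.is_Symbol or expr.is_Number:
        return True
    if expr.is_Pow:
        return _is_monomial(expr.base) and expr.exp.is_Integer
    if expr.is_Mul:
        return all(_is_monomial(a) for a in expr.args)
    return False


def _monomial_exponents(expr: sp.Expr) -> dict[str, int]:
    out: dict[str, int] = {}

    def walk(e, mult=1):
        if e.is_Symbol:
            out[str(e)] = out.get(str(e), 0) + mult
        elif e.is_Pow:
            walk(e.base, mult * int(e.exp))
        elif e.is_Mul:
            for a in e.args:
                walk(a, mult)
    walk(expr)
    return out


def _monic_denominator(expr: sp.Expr, var_syms) -> sp.Expr:
    """Divide numerator and denominator of a rational expression by the
    leading coefficient of the denominator in the concentration
    variables, e.g. Etot k1 k2 S / (k1 S + k2 + km1) becomes
    Etot k2 S / (S + (k2 + km1)/k1)."""
    num, den = sp.fraction(sp.together(expr))
    pvars = [v for v in var_syms if v in den.free_symbols]
    if not pvars:
        return expr
    try:
        poly = sp.Poly(den, *pvars)
    except sp.PolynomialError:
        return expr
    lead = poly.coeffs()[0]
    if lead == 1 or lead.free_symbols & set(pvars):
        return expr

    def rescaled(e):
        p = sp.Poly(e, *pvars)
        return sp.Add(*[sp.together(c / lead) *
                        sp.Mul(*[v ** d for v, d in zip(pvars, mono)])
                        for mono, c in zip(p.monoms(), p.coeffs())])
    try:
        return rescaled(num) / rescaled(den)
    except sp.PolynomialError:
        return expr


def effective_parameters(red: ReducedNetwork) -> list[EffectiveParameter]:
    """Maximal parameter-only coefficients of the reduced rates.

    Inside every product the parameter-only factors are grouped into one
    candidate; parameter-only summands of denominators/numerators are
    candidates of their own.  Monomials get explicit integer exponent
    vectors; composites (e.g. (k-1 + k2)/k1) are reported as named
    rational expressions."""
    var_syms = {sp.Symbol(v) for v in red.variables} | \
        {sp.Symbol(s) for s in red.fast}
    found: list[sp.Expr] = []

    def visit(e: sp.Expr):
        e = sp.sympify(e)
        if not e.free_symbols - var_syms:
            return                      # no parameters here
        if not e.free_symbols & var_syms:
            if e.free_symbols and not any(sp.simplify(e - f) == 0
                                          for f in found):
                found.append(e)
            return
        if e.is_Add:
            for a in e.args:
                visit(a)
        elif e.is_Mul:
            par = [a for a in e.args if not a.free_symbols & var_syms
                   and a.free_symbols]
            rest = [a for a in e.args if a.free_symbols & var_syms]
            if par:
                visit(sp.Mul(*par))
            for a in rest:
                visit(a)
        elif e.is_Pow:
            visit(e.base)
        return

    exprs = [r.rate for r in red.reactions] or list(red.odes.values())
    for e in exprs:
        visit(_monic_denominator(sp.together(sp.sympify(e)), var_syms))
    out = []
    for k, e in enumerate(found):
        mono = _is_monomial(e)
        out.append(EffectiveParameter(
            f"g{k+1}", e, mono,
            _monomial_exponents(e) if mono else None))
    return out


def dominance_simplify(expr: sp.Expr, params: Mapping[str, float],
                       margin: float = 10.0) -> sp.Expr:
    """Replace parameter-only sums by their dominant term whenever it
    exceeds the others by ``margin``; turns composite effective
    parameters into monomials in strongly separated regimes."""
    expr = sp.sympify(expr)
    subs = {sp.Symbol(k): sp.Float(v) for k, v in params.items()}

    def repl(e):
        if e.is_Add and not any(a.free_symbols - set(subs) for a in e.args):
            vals = [abs(float(a.subs(subs))) for a in e.args]
            top = max(range(len(vals)), key=lambda i: vals[i])
            if all(vals[top] >= margin * v
                   for i, v in enumerate(vals) if i != top):
                return e.args[top]
        return e
    return expr.replace(lambda e: e.is_Add, repl)
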