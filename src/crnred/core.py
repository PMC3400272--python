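"""Data model for deterministic mass-action reaction networks.

A network is a list of species, a list of reactions with integer
stoichiometry and mass-action rate constants, and a table of positive
parameter values.  Rate constants are stored as sympy expressions over the
declared parameter symbols so that every downstream reduction can track
effective parameters symbolically; numeric evaluation substitutes the
parameter table.

The right-hand side of the kinetic equations,

    dc/dt = P(c) = sum_j nu_j (R+_j(c) - R-_j(c)),

with nu_j = beta_j - alpha_j the global stoichiometric vector and
R+_j = k+_j prod_i c_i^alpha_ji, R-_j = k-_j prod_i c_i^beta_ji, is exposed
as a list of signed monomials per species (:class:`RHS`).  Each monomial
remembers the reaction and direction it came from; this provenance is what
lets the QE/QSS classifier prune individual rate terms rather than merged
polynomial coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "SignedMonomial",
    "RHS",
    "NetworkError",
    "UnsupportedKineticsError",
    "stoichiometric_matrix",
    "reaction_rates",
    "rhs",
    "conservation_laws",
]


class NetworkError(ValueError):
    """Invalid network structure or inconsistent input."""


class UnsupportedKineticsError(NetworkError):
    """A kinetic law that is not mass action."""


def _as_expr(x) -> sp.Expr:
    if isinstance(x, sp.Expr):
        return x
    return sp.sympify(x)


@dataclass
class Species:
    id: str
    name: str = ""
    initial_concentration: float = 0.0
    compartment: str | None = None

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise NetworkError(
                f"species {self.id}: negative initial concentration")
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """One reaction with integer stoichiometry and mass-action constants.

    ``k_forward``/``k_backward`` may be numbers or sympy expressions over
    parameter symbols.  ``k_backward`` equal to zero means irreversible.
    """

    id: str
    reactants: dict[str, int]
    products: dict[str, int]
    k_forward: sp.Expr
    k_backward: sp.Expr = sp.Integer(0)

    def __post_init__(self):
        self.k_forward = _as_expr(self.k_forward)
        self.k_backward = _as_expr(self.k_backward)
        if not self.reactants and not self.products:
            raise NetworkError(f"reaction {self.id}: empty stoichiometry")
        for side in (self.reactants, self.products):
            for s, n in side.items():
                if int(n) != n or n < 0:
                    raise NetworkError(
                        f"reaction {self.id}: stoichiometry must be a "
                        f"non-negative integer, got {s}:{n}")

    @property
    def reversible(self) -> bool:
        return self.k_backward != 0


class ReactionNetwork:
    """Ordered species, reactions and a positive parameter table.

    Species declaration order fixes all vector/matrix indexing; exponent
    vectors are dense over that order.
    """

    def __init__(self,
                 species: Sequence[Species],
                 reactions: Sequence[Reaction],
                 parameters: Mapping[str, float] | None = None):
        self.species = list(species)
        self.reactions = list(reactions)
        self.parameters = dict(parameters or {})
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate species ids")
        self._index = {sid: i for i, sid in enumerate(ids)}
        declared = set(self.parameters)
        for r in self.reactions:
            for side in (r.reactants, r.products):
                for sid in side:
                    if sid not in self._index:
                        raise NetworkError(
                            f"reaction {r.id} references unknown species {sid}")
            for k in (r.k_forward, r.k_backward):
                for sym in k.free_symbols:
                    if str(sym) not in declared:
                        raise NetworkError(
                            f"reaction {r.id}: undeclared parameter {sym}")
        for name, v in self.parameters.items():
            if v <= 0:
                raise NetworkError(f"parameter {name} must be positive")

    # -- indexing helpers -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def species_index(self, sid: str) -> int:
        return self._index[sid]

    def param_subs(self) -> dict[sp.Symbol, float]:
        return {sp.Symbol(k): v for k, v in self.parameters.items()}

    def k_values(self) -> list[tuple[float, float]]:
        """Numeric (k_forward, k_backward) per reaction."""
        subs = self.param_subs()
        out = []
        for r in self.reactions:
            out.append((float(r.k_forward.subs(subs)),
                        float(r.k_backward.subs(subs))))
        return out

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species],
                        dtype=float)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReactionNetwork):
            return NotImplemented
        if [s.__dict__ for s in self.species] != \
           [s.__dict__ for s in other.species]:
            return False
        if len(self.reactions) != len(other.reactions):
            return False
        for a, b in zip(self.reactions, other.reactions):
            if (a.id, a.reactants, a.products) != (b.id, b.reactants,
                                                   b.products):
                return False
            if sp.simplify(a.k_forward - b.k_forward) != 0:
                return False
            if sp.simplify(a.k_backward - b.k_backward) != 0:
                return False
        return self.parameters == other.parameters

    def __repr__(self):
        return (f"ReactionNetwork({self.n_species} species, "
                f"{self.n_reactions} reactions, "
                f"{len(self.parameters)} parameters)")


# ---------------------------------------------------------------------------
# stoichiometry and rates
# ---------------------------------------------------------------------------

def reactant_product_matrices(net: ReactionNetwork):
    """Dense integer matrices alpha (species x reactions) and beta."""
    n, r = net.n_species, net.n_reactions
    alpha = np.zeros((n, r), dtype=int)
    beta = np.zeros((n, r), dtype=int)
    for j, rx in enumerate(net.reactions):
        for sid, c in rx.reactants.items():
            alpha[net.species_index(sid), j] = c
        for sid, c in rx.products.items():
            beta[net.species_index(sid), j] = c
    return alpha, beta


def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Global stoichiometric matrix S with S[i, j] = beta_ji - alpha_ji."""
    alpha, beta = reactant_product_matrices(net)
    return beta - alpha


def reaction_rates(net: ReactionNetwork, c: np.ndarray) -> np.ndarray:
    """Net mass-action rates R+_j(c) - R-_j(c) at concentrations c > 0."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    alpha, beta = reactant_product_matrices(net)
    kv = net.k_values()
    out = np.empty(net.n_reactions)
    for j, (kf, kb) in enumerate(kv):
        out[j] = kf * np.prod(c ** alpha[:, j]) - kb * np.prod(c ** beta[:, j])
    return out


# ---------------------------------------------------------------------------
# polynomial right-hand side
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignedMonomial:
    """One term sign * coeff * c^exponents of a species balance polynomial.

    ``coeff`` is a positive parameter expression (or number); ``source``
    records (reaction id, 'fwd'|'rev') when the monomial comes from a
    network reaction.
    """

    sign: int
    coeff: sp.Expr
    exponents: tuple[int, ...]
    source: tuple[str, str] | None = None

    def value(self, c: np.ndarray, subs: Mapping) -> float:
        """Signed numeric value at concentrations c."""
        a = float(_as_expr(self.coeff).subs(subs))
        return self.sign * a * float(
            np.prod(np.asarray(c, float) ** np.array(self.exponents)))

    def expr(self, syms: Sequence[sp.Symbol]) -> sp.Expr:
        e = sp.Integer(self.sign) * _as_expr(self.coeff)
        for s, a in zip(syms, self.exponents):
            if a:
                e *= s ** a
        return e


class RHS:
    """Polynomial vector field dc/dt = P(c) as per-species signed monomials."""

    def __init__(self, species_ids: Sequence[str],
                 monomials: Sequence[Sequence[SignedMonomial]]):
        self.species_ids = list(species_ids)
        self.monomials = [list(ms) for ms in monomials]
        if len(self.species_ids) != len(self.monomials):
            raise NetworkError("one monomial list per species required")
        self.symbols = [sp.Symbol(s) for s in self.species_ids]

    def __iter__(self):
        return iter(self.monomials)

    def expr(self, i: int) -> sp.Expr:
        """Symbolic P_i(c)."""
        return sp.Add(*[m.expr(self.symbols) for m in self.monomials[i]])

    def exprs(self) -> list[sp.Expr]:
        return [self.expr(i) for i in range(len(self.monomials))]

    def evaluate(self, c: np.ndarray, subs: Mapping | None = None) -> np.ndarray:
        subs = subs or {}
        return np.array([sum(m.value(c, subs) for m in ms) or 0.0
                         for ms in self.monomials])

    def univariate(self, i: int, c: np.ndarray, subs: Mapping) -> np.ndarray:
        """Coefficients (ascending degree) of P_i as a polynomial in c_i
        with the other coordinates frozen at c."""
        c = np.asarray(c, dtype=float)
        deg = max((m.exponents[i] for m in self.monomials[i]), default=0)
        coeffs = np.zeros(deg + 1)
        for m in self.monomials[i]:
            a = float(_as_expr(m.coeff).subs(subs)) * m.sign
            for j, e in enumerate(m.exponents):
                if j != i and e:
                    a *= c[j] ** e
            coeffs[m.exponents[i]] += a
        return coeffs


def rhs(net: ReactionNetwork, merge: bool = False) -> RHS:
    """Build P(c) from the network reactions.

    With ``merge=False`` (default) every reaction direction contributes its
    own monomial, keeping (reaction, direction) provenance.  With
    ``merge=True`` monomials with equal exponent vectors are summed, which
    is the compact polynomial form.
    """
    n = net.n_species
    alpha, beta = reactant_product_matrices(net)
    mono: list[list[SignedMonomial]] = [[] for _ in range(n)]
    for j, rx in enumerate(net.reactions):
        nu = beta[:, j] - alpha[:, j]
        a_exp = tuple(int(x) for x in alpha[:, j])
        b_exp = tuple(int(x) for x in beta[:, j])
        for i in range(n):
            if nu[i] == 0:
                continue
            coeff = abs(int(nu[i])) * rx.k_forward
            mono[i].append(SignedMonomial(
                int(np.sign(nu[i])), coeff, a_exp, (rx.id, "fwd")))
            if rx.reversible:
                coeff = abs(int(nu[i])) * rx.k_backward
                mono[i].append(SignedMonomial(
                    -int(np.sign(nu[i])), coeff, b_exp, (rx.id, "rev")))
    out = RHS(net.species_ids, mono)
    return merge_rhs(out) if merge else out


def merge_rhs(field: RHS) -> RHS:
    """Sum monomials sharing an exponent vector; drop exact cancellations."""
    merged = []
    for ms in field.monomials:
        acc: dict[tuple[int, ...], sp.Expr] = {}
        for m in ms:
            acc[m.exponents] = acc.get(m.exponents, sp.Integer(0)) \
                + m.sign * _as_expr(m.coeff)
        row = []
        for exps, coeff in acc.items():
            coeff = sp.simplify(coeff)
            if coeff == 0:
                continue
            # sign is decided at positive parameter values
            if coeff.is_positive or (coeff.is_number and coeff > 0):
                row.append(SignedMonomial(1, coeff, exps))
            elif coeff.is_negative or (coeff.is_number and coeff < 0):
                row.append(SignedMonomial(-1, -coeff, exps))
            else:
                # mixed-sign parameter sum: keep as positive-coefficient
                # monomial pair is impossible; keep raw with sign +1
                row.append(SignedMonomial(1, coeff, exps))
        merged.append(row)
    return RHS(field.species_ids, merged)


# ---------------------------------------------------------------------------
# conservation laws (exact integer arithmetic)
# ---------------------------------------------------------------------------

def _primitive_integer(vec: Iterable[sp.Rational]) -> list[int]:
    fr = [Fraction(sp.Rational(x).p, sp.Rational(x).q) for x in vec]
    den = 1
    for f in fr:
        den = den * f.denominator // np.gcd(den, f.denominator)
    ints = [int(f * den) for f in fr]
    g = 0
    for v in ints:
        g = np.gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    neg = sum(1 for v in ints if v < 0)
    pos = sum(1 for v in ints if v > 0)
    if neg > pos:
        ints = [-v for v in ints]
    return ints


def integer_left_nullspace(S) -> list[list[int]]:
    """Primitive integer basis of {b : b^T S = 0}, computed exactly.

    The basis is the reduced row echelon form of the left kernel, scaled to
    coprime integers with a non-negative-preferred sign convention.
    """
    M = sp.Matrix(S).T
    null = M.nullspace()
    if not null:
        return []
    B = sp.Matrix([list(v) for v in null])
    B = B.rref()[0]
    rows = [r for r in B.tolist() if any(x != 0 for x in r)]
    return [_primitive_integer(r) for r in rows]


def integer_right_nullspace(S) -> list[list[int]]:
    """Primitive integer basis of {g : S g = 0}."""
    return integer_left_nullspace(sp.Matrix(S).T)


def conservation_laws(net: ReactionNetwork) -> list[list[int]]:
    """Integer basis b of the left kernel of S (b^T S = 0, exact).

    Each law means sum_i b_i c_i is constant on every trajectory.
    """
    return integer_left_nullspace(stoichiometric_matrix(net))


def conserved_totals(net: ReactionNetwork,
                     laws: Sequence[Sequence[int]] | None = None):
    """Numeric values of each conservation law at the initial state."""
    laws = conservation_laws(net) if laws is None else laws
    c0 = net.initial_concentrations()
    return [float(np.dot(b, c0)) for b in laws]
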