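"""Multiscale reduction of monomolecular reaction networks.

A monomolecular network A_i -> A_j with constants k_ji is a rank-labeled
digraph (label 1 = largest constant = quickest reaction).  When the
constants are *totally separated* (every pair differs by orders of
magnitude) the network admits a multiscale approximation that is an
acyclic deterministic digraph (every node has out-degree <= 1), obtained
by graph rewriting:

rule a  at every node keep only the fastest outgoing edge;
rule b  cut an isolated cycle by deleting its slowest (limiting) step;
rule c  glue a cycle with outgoing slow edges into one pooled node; an
        outgoing edge A_i -> A_j with constant k is renormalized to the
        monomial k * k_lim / k_i, where k_i is A_i's intra-cycle exit
        constant and k_lim the cycle's limiting constant (the
        quasi-stationary weight of A_i inside the cycle is k_lim/k_i).

Gluing iterates with rule a until the pruned system is acyclic, then glued
cycles are restored in reverse order: the cycle is cut at its limiting
step and the surviving outgoing edge re-attached to the limiting step's
source node, where the cycle mass concentrates.

Renormalized constants are carried as exact sympy monomials over the
original constants; dominance comparisons are made on log-values.

The spectral structure of the reduced digraph is explicit: one eigenvalue
-k per remaining edge, and in the totally separated limit the left/right
eigenvectors have 0-1 (resp. 0,1,-1) coordinates, so each relaxation
timescale acts as a single effective reaction from a donor pool to a
receiver node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .core import NetworkError, ReactionNetwork

__all__ = [
    "TieError", "Edge", "LabeledDigraph", "GluedCycleRecord",
    "ReducedLinearNetwork", "SpectralSolution",
    "rank_label", "reduce_monomolecular", "kinetic_matrix",
    "exact_solution", "spectral_approximation",
    "single_step_approximations", "export_dot",
]


class TieError(NetworkError):
    """Two constants are exactly equal; total separation is violated."""


def _logval(expr: sp.Expr, params: Mapping[str, float]) -> float:
    """log of a positive monomial constant, robust to extreme magnitudes."""
    e = sp.expand_log(sp.log(sp.sympify(expr)), force=True)
    e = e.subs({sp.Symbol(k): sp.Float(v) for k, v in params.items()})
    return float(e.evalf())


def _tied(la: float, lb: float, tol: float = 1e-9) -> bool:
    """Equality of log-values up to float round-off: derived monomial
    constants that coincide exactly in infinite precision differ by a few
    ulp after summing logarithms."""
    return abs(la - lb) <= tol * (1.0 + max(abs(la), abs(lb)))


@dataclass
class Edge:
    src: str
    dst: str
    expr: sp.Expr          # exact monomial over original constants
    rank: int | None = None

    def value(self, params: Mapping[str, float]) -> float:
        return float(sp.sympify(self.expr).subs(
            {sp.Symbol(k): sp.Float(v) for k, v in params.items()}))


@dataclass
class LabeledDigraph:
    nodes: list[str]
    edges: list[Edge]
    params: dict[str, float]

    def out_edges(self, n: str) -> list[Edge]:
        return [e for e in self.edges if e.src == n]


@dataclass
class GluedCycleRecord:
    glued_id: str
    cycle_nodes: list[str]            # in cycle order
    cycle_edges: list[tuple[str, str, sp.Expr]]
    limiting: tuple[str, str, sp.Expr]
    weights: dict[str, sp.Expr]       # quasi-stationary c° per node


@dataclass
class ReducedLinearNetwork:
    nodes: list[str]
    edges: dict[str, tuple[str, sp.Expr]]   # src -> (dst, constant monomial)
    params: dict[str, float]
    provenance: list[str] = field(default_factory=list)
    records: list[GluedCycleRecord] = field(default_factory=list)

    def edge_list(self) -> list[Edge]:
        return [Edge(s, d, e) for s, (d, e) in self.edges.items()]

    def is_acyclic_deterministic(self) -> bool:
        # out-degree <= 1 by construction of the dict; check acyclicity
        for start in self.nodes:
            seen = {start}
            cur = start
            while cur in self.edges:
                cur = self.edges[cur][0]
                if cur in seen:
                    return False
                seen.add(cur)
        return True


# ---------------------------------------------------------------------------
# rank labeling
# ---------------------------------------------------------------------------

def monomolecular_digraph(net: ReactionNetwork) -> LabeledDigraph:
    """Convert a monomolecular network (all reactions A -> B with unit
    stoichiometry; reversible pairs become two edges) to a digraph."""
    edges: list[Edge] = []
    for r in net.reactions:
        if (len(r.reactants) != 1 or len(r.products) != 1
                or list(r.reactants.values()) != [1]
                or list(r.products.values()) != [1]):
            raise NetworkError(
                f"reaction {r.id} is not monomolecular A -> B")
        (src,), (dst,) = r.reactants, r.products
        edges.append(Edge(src, dst, r.k_forward))
        if r.reversible:
            edges.append(Edge(dst, src, r.k_backward))
    return LabeledDigraph(net.species_ids, edges, dict(net.parameters))


def rank_label(net: ReactionNetwork | LabeledDigraph) -> LabeledDigraph:
    """Label every edge with its rank (1 = largest constant = quickest).

    Exactly equal constants violate total separation and raise
    :class:`TieError` naming the offending pair.
    """
    g = net if isinstance(net, LabeledDigraph) else monomolecular_digraph(net)
    pairs = {(e.src, e.dst) for e in g.edges}
    if len(pairs) != len(g.edges):
        raise NetworkError("at most one edge per ordered node pair")
    vals = [_logval(e.expr, g.params) for e in g.edges]
    order = sorted(range(len(vals)), key=lambda i: -vals[i])
    for pos in range(1, len(order)):
        a, b = order[pos - 1], order[pos]
        if _tied(vals[a], vals[b]):
            raise TieError(
                f"equal constants on edges {g.edges[a].src}->"
                f"{g.edges[a].dst} and {g.edges[b].src}->{g.edges[b].dst}")
    for label, i in enumerate(order, start=1):
        g.edges[i].rank = label
    return g


# ---------------------------------------------------------------------------
# rules a / b / c
# ---------------------------------------------------------------------------

def _prune(edges: dict, params) -> dict[str, tuple[str, sp.Expr, str]]:
    """Rule a: keep only the fastest outgoing edge of every node.

    ``edges`` maps (src, dst) -> (expr, attach_dst) where attach_dst is
    the original-network node the edge ultimately targets; the payload
    travels with the edge through gluing and restoration.
    """
    best: dict[str, tuple[str, sp.Expr, str, float]] = {}
    for (s, d), (expr, adst) in edges.items():
        lv = _logval(expr, params)
        if s in best:
            if _tied(lv, best[s][3]):
                raise TieError(
                    f"tie between outgoing constants of {s}: "
                    f"{best[s][1]} and {expr}")
            if lv > best[s][3]:
                best[s] = (d, expr, adst, lv)
        else:
            best[s] = (d, expr, adst, lv)
    return {s: (d, e, a) for s, (d, e, a, _) in best.items()}


def _find_cycle(pruned: dict) -> list[str] | None:
    """One cycle of the functional graph src -> dst, or None."""
    color: dict[str, int] = {}
    for start in pruned:
        if color.get(start):
            continue
        path = []
        cur = start
        while True:
            if color.get(cur) == 2:
                break
            if cur in path:
                return path[path.index(cur):]
            path.append(cur)
            if cur not in pruned:
                break
            cur = pruned[cur][0]
        for n in path:
            color[n] = 2
    return None


def reduce_monomolecular(g: LabeledDigraph | ReactionNetwork,
                         perturb_ties: bool = False) -> ReducedLinearNetwork:
    """Reduce a totally separated monomolecular network to an acyclic
    deterministic digraph with exact monomial constants (rules a/b/c).

    Ties between constants raise :class:`TieError` unless
    ``perturb_ties`` is set, in which case constants are multiplied by
    distinct factors 1 + i*1e-9 (with a warning) to force an order.
    """
    if isinstance(g, ReactionNetwork):
        g = monomolecular_digraph(g)
    params = dict(g.params)
    provenance: list[str] = []
    # edge payload: (constant monomial, original destination node)
    edges: dict[tuple[str, str], tuple[sp.Expr, str]] = {}
    for i, e in enumerate(g.edges):
        key = (e.src, e.dst)
        if key in edges:
            raise NetworkError(f"parallel edges {key}")
        expr = sp.sympify(e.expr)
        if perturb_ties:
            # distinct multiplicative factors, comfortably above the
            # log-comparison tolerance
            expr = expr * sp.Float(1 + (i + 1) * 1e-7, 20)
        edges[key] = (expr, e.dst)
    if perturb_ties:
        import warnings
        warnings.warn("constants perturbed multiplicatively to break ties; "
                      "total separation was not verified")
    nodes = list(g.nodes)
    covers: dict[str, set[str]] = {n: {n} for n in nodes}
    records: list[GluedCycleRecord] = []

    # --- forward sweep: prune (rule a) and glue cycles (rule c) ----------
    glue_idx = 0
    while True:
        pruned = _prune(edges, params)
        cycle = _find_cycle(pruned)
        if cycle is None:
            break
        glue_idx += 1
        gid = f"cycle:{glue_idx}"
        cset = set(cycle)
        cyc_edges = [(v, pruned[v][0], pruned[v][1], pruned[v][2])
                     for v in cycle]
        cyc_logs = sorted(_logval(t[2], params) for t in cyc_edges)
        if len(cyc_logs) > 1 and _tied(cyc_logs[0], cyc_logs[1]):
            raise TieError(
                f"two intra-cycle constants of {'->'.join(cycle)} tie for "
                "the limiting step; constants are not totally separated")
        lims = min(cyc_edges, key=lambda t: _logval(t[2], params))
        k_lim = lims[2]
        weights = {v: sp.together(k_lim / e) for v, _, e, _ in cyc_edges}
        provenance.append(
            f"rule c: glue cycle {'->'.join(cycle)} into {gid}; "
            f"limiting step {lims[0]}->{lims[1]}")
        new_edges: dict[tuple[str, str], tuple[sp.Expr, str]] = {}

        def _put(key, payload):
            if key in new_edges:
                old_lv = _logval(new_edges[key][0], params)
                lv = _logval(payload[0], params)
                if _tied(lv, old_lv):
                    raise TieError(f"tie while rerouting edges onto {key}")
                if lv <= old_lv:
                    return
            new_edges[key] = payload

        for (s, d), (expr, adst) in edges.items():
            s_in, d_in = s in cset, d in cset
            if s_in and d_in:
                continue                      # internal: vanishes
            if s_in:
                _put((gid, d), (sp.together(expr * weights[s]), adst))
            elif d_in:
                _put((s, gid), (expr, adst))
            else:
                _put((s, d), (expr, adst))
        edges = new_edges
        nodes = [n for n in nodes if n not in cset] + [gid]
        covers[gid] = set().union(*(covers[v] for v in cycle))
        records.append(GluedCycleRecord(
            gid, list(cycle), cyc_edges, (lims[0], lims[1], lims[2]),
            weights))

    # acyclic deterministic digraph on the glued node level
    red: dict[str, tuple[str, sp.Expr, str]] = dict(pruned)

    # --- backward sweep: restore glued cycles, cutting by rule b ---------
    for rec in reversed(records):
        gid = rec.glued_id
        out = red.pop(gid, None)
        in_edges = [(s, expr, adst) for s, (tgt, expr, adst) in red.items()
                    if tgt == gid]
        for s, _, _ in in_edges:
            del red[s]
        # cycle edges minus the limiting step
        for (s, d, expr, adst) in rec.cycle_edges:
            if (s, d) == (rec.limiting[0], rec.limiting[1]):
                continue
            red[s] = (d, expr, adst)
        if out is not None:
            tgt, expr, adst = out
            red[rec.limiting[0]] = (tgt, expr, adst)
            provenance.append(
                f"rule b/c: restore {gid}, cut limiting step "
                f"{rec.limiting[0]}->{rec.limiting[1]}, outgoing edge "
                f"{rec.limiting[0]}->{tgt} with constant {expr}")
        else:
            provenance.append(
                f"rule b: restore {gid} as a chain (limiting step "
                f"{rec.limiting[0]}->{rec.limiting[1]} removed)")
        # re-attach incoming edges to the member covering the edge's
        # original destination
        for s, expr_in, adst in in_edges:
            target = rec.cycle_nodes[0]
            for cn in rec.cycle_nodes:
                if adst in covers.get(cn, {cn}):
                    target = cn
                    break
            red[s] = (target, expr_in, adst)

    result = ReducedLinearNetwork(
        list(g.nodes), {s: (d, e) for s, (d, e, _a) in red.items()},
        params, provenance, records)
    if not result.is_acyclic_deterministic():
        raise NetworkError("reduction failed to produce an acyclic "
                           "deterministic digraph")
    return result


# ---------------------------------------------------------------------------
# kinetic matrix, exact and approximate spectral solutions
# ---------------------------------------------------------------------------

def kinetic_matrix(nodes: Sequence[str], edges: Sequence[Edge],
                   params: Mapping[str, float]) -> np.ndarray:
    """K with K[j,i] += k and K[i,i] -= k for every edge i->j."""
    idx = {n: i for i, n in enumerate(nodes)}
    K = np.zeros((len(nodes), len(nodes)))
    for e in edges:
        k = e.value(params)
        K[idx[e.dst], idx[e.src]] += k
        K[idx[e.src], idx[e.src]] -= k
    return K


def exact_solution(obj, c0: np.ndarray, times: np.ndarray,
                   params: Mapping[str, float] | None = None):
    """Solve dc/dt = K c by eigendecomposition (matrix exponential
    fallback when K is defective).

    ``obj`` may be a LabeledDigraph, a ReducedLinearNetwork or a kinetic
    matrix.  Returns (C, info) with C of shape (len(times), n).
    """
    if isinstance(obj, LabeledDigraph):
        K = kinetic_matrix(obj.nodes, obj.edges, obj.params)
    elif isinstance(obj, ReducedLinearNetwork):
        K = kinetic_matrix(obj.nodes, obj.edge_list(), obj.params)
    else:
        K = np.asarray(obj, dtype=float)
    c0 = np.asarray(c0, dtype=float)
    times = np.asarray(times, dtype=float)
    vals, R = np.linalg.eig(K)
    info = {"method": "eig", "eigenvalues": vals}
    cond = np.linalg.cond(R)
    if not np.isfinite(cond) or cond > 1e10:
        from scipy.linalg import expm
        C = np.stack([expm(K * t) @ c0 for t in times])
        info["method"] = "expm"
        return C.real, info
    amps = np.linalg.solve(R, c0)
    expo = np.exp(np.outer(times, vals))
    C = (expo * amps) @ R.T
    return C.real, info



def _horner(coeffs, x):
    """Evaluate a polynomial given descending coefficients."""
    acc = coeffs[0]
    for c in coeffs[1:]:
        acc = acc * x + c
    return acc

def kinetic_matrix_rational(nodes: Sequence[str], edges: Sequence[Edge],
                            params: Mapping[str, sp.Rational]) -> sp.Matrix:
    """Exact rational kinetic matrix; constants evaluated symbolically."""
    idx = {n: i for i, n in enumerate(nodes)}
    K = sp.zeros(len(nodes), len(nodes))
    subs = {sp.Symbol(a): sp.Rational(v) for a, v in params.items()}
    for e in edges:
        k = sp.Rational(sp.sympify(e.expr).subs(subs))
        K[idx[e.dst], idx[e.src]] += k
        K[idx[e.src], idx[e.src]] -= k
    return K


def eigenvalues_exact(Kx: sp.Matrix, dps: int = 50) -> np.ndarray:
    """Real parts of the eigenvalues of an exact rational matrix, via the
    exact characteristic polynomial with high-precision root polishing.

    Needed because the float representation of totally separated
    constants can shift the smallest eigenvalues by several percent: the
    low-order characteristic coefficients suffer heavy cancellation.
    """
    from mpmath import mp

    n = Kx.rows
    coeffs = Kx.charpoly().all_coeffs()
    # exact deflation of zero eigenvalues (trailing zero coefficients)
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    n_zero = n + 1 - len(coeffs)
    with mp.workdps(dps):
        p_c = [mp.mpf(sp.Rational(c).p) / mp.mpf(sp.Rational(c).q)
               for c in coeffs]
        dp_c = [c * (len(p_c) - 1 - i) for i, c in enumerate(p_c[:-1])]
        # Newton-polygon starts: for a spectrum separated in magnitude the
        # characteristic coefficients are separated too, and the k-th
        # largest root is close to -c_{k+1}/c_k
        starts = []
        for i in range(len(p_c) - 1):
            if p_c[i] != 0:
                starts.append(-p_c[i + 1] / p_c[i])
        out = [0.0] * n_zero
        for lam in starts:
            for _ in range(100):
                dv = _horner(dp_c, lam)
                if dv == 0:
                    break
                step = _horner(p_c, lam) / dv
                lam = lam - step
                if abs(step) <= abs(lam) * mp.mpf(10) ** (-dps + 5):
                    break
            out.append(float(mp.re(lam)))
    return np.array(out)


def exact_solution_mp(K, c0, times, dps: int = 50):
    """High-precision eigen-solution of dc/dt = K c.

    Totally separated networks have timescales spanning dozens of
    decades; double precision cannot resolve eigenvalues below
    ~1e-16 * ||K||, so both the spectrum and long-time trajectories are
    computed with mpmath at ``dps`` decimal digits and rounded to float
    on output.  Returns (C, eigenvalues).
    """
    from fractions import Fraction

    from mpmath import mp

    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    # QR iteration (even in high precision) can fail to deliver relative
    # accuracy on eigenvalues many decades below the matrix norm, so the
    # mp.eig estimates are Newton-refined on the exact rational
    # characteristic polynomial and the eigenvectors recomputed by one
    # step of inverse iteration at the refined shifts.
    Kx = sp.Matrix([[sp.Rational(Fraction(float(K[i, j])))
                     for j in range(n)] for i in range(n)])
    coeffs = Kx.charpoly().all_coeffs()
    with mp.workdps(dps):
        p_c = [mp.mpf(sp.Rational(c).p) / mp.mpf(sp.Rational(c).q)
               for c in coeffs]
        dp_c = [c * (len(p_c) - 1 - i) for i, c in enumerate(p_c[:-1])]

        def refine(lam):
            for _ in range(60):
                pv = _horner(p_c, lam)
                dv = _horner(dp_c, lam)
                if dv == 0:
                    break
                step = pv / dv
                lam = lam - step
                if abs(step) <= abs(lam) * mp.mpf(10) ** (-dps + 5):
                    break
            return lam

        A = mp.matrix([[mp.mpf(K[i, j]) for j in range(n)]
                       for i in range(n)])
        E, ER = mp.eig(A)
        lams = []
        for k in range(n):
            lam = E[k]
            if abs(lam) > 0:
                lam = refine(lam)
            lams.append(lam)
        # inverse iteration from the QR vectors at the refined shifts
        V = mp.zeros(n, n)
        V = mp.matrix(n, n)
        for k in range(n):
            shift = lams[k] * (1 + mp.mpf(10) ** (-dps + 10)) \
                if lams[k] != 0 else mp.mpf(10) ** (-4 * dps)
            B = A - mp.eye(n) * shift
            v = mp.matrix([ER[i, k] for i in range(n)])
            try:
                v = mp.lu_solve(B, v)
            except ZeroDivisionError:
                v = mp.matrix([ER[i, k] for i in range(n)])
            nrm = mp.sqrt(sum(abs(v[i]) ** 2 for i in range(n)))
            for i in range(n):
                V[i, k] = v[i] / nrm
        rhs_v = mp.matrix([mp.mpf(x) for x in np.asarray(c0, dtype=float)])
        C = np.empty((len(times), n))
        try:
            amps = mp.lu_solve(V, rhs_v)
            for ti, t in enumerate(np.asarray(times, dtype=float)):
                acc = [mp.mpc(0)] * n
                for k in range(n):
                    w = amps[k] * mp.e ** (lams[k] * mp.mpf(t))
                    for i in range(n):
                        acc[i] += V[i, k] * w
                C[ti] = [float(mp.re(x)) for x in acc]
        except ZeroDivisionError:
            # (near-)defective: matrix-exponential fallback
            for ti, t in enumerate(np.asarray(times, dtype=float)):
                M = mp.expm(A * mp.mpf(float(t)))
                C[ti] = [float(sum(M[i, j] * rhs_v[j] for j in range(n)))
                         for i in range(n)]
        eigs = np.array([float(mp.re(x)) for x in lams])
    return C, eigs


@dataclass
class SpectralSolution:
    """0-1 approximation of the spectrum of an acyclic deterministic
    digraph: one eigenvalue -k per remaining edge; l^k marks the pool
    feeding that edge (coordinates in {0,1}); r^k has +1 on the donor and
    -1 on the receiver."""
    nodes: list[str]
    eigenvalues: np.ndarray              # sorted fastest first (most negative)
    left: np.ndarray                     # (n_modes, n) 0/1
    right: np.ndarray                    # (n_modes, n) 0/1/-1
    edges: list[Edge]


def spectral_approximation(red: ReducedLinearNetwork) -> SpectralSolution:
    nodes = red.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    params = red.params
    items = sorted(red.edges.items(),
                   key=lambda kv: -_logval(kv[1][1], params))
    n = len(nodes)
    lam, L, R, elist = [], [], [], []
    out_log = {s: _logval(e, params) for s, (_d, e) in red.edges.items()}
    for s, (d, expr) in items:
        k_log = _logval(expr, params)
        k = float(sp.sympify(expr).subs(
            {sp.Symbol(a): sp.Float(v) for a, v in params.items()}))
        lam.append(-k)
        lvec = np.zeros(n)
        for m in nodes:          # pool: nodes draining into s via faster edges
            cur, ok = m, True
            while cur != s:
                if cur not in red.edges or out_log[cur] <= k_log:
                    ok = False
                    break
                cur = red.edges[cur][0]
            if ok:
                lvec[idx[m]] = 1.0
        rvec = np.zeros(n)
        rvec[idx[s]] = 1.0
        cur = d                  # receiver: first slower-draining node below
        while cur in red.edges and out_log[cur] > k_log:
            cur = red.edges[cur][0]
        rvec[idx[cur]] = -1.0
        L.append(lvec)
        R.append(rvec)
        elist.append(Edge(s, d, expr))
    return SpectralSolution(nodes, np.array(lam), np.array(L), np.array(R),
                            elist)


def single_step_approximations(red: ReducedLinearNetwork):
    """Ordered single-step view: one (timescale, donor pool, receiver) per
    remaining edge, fastest first."""
    spec = spectral_approximation(red)
    steps = []
    for lam, lvec, rvec in zip(spec.eigenvalues, spec.left, spec.right):
        donor_pool = [spec.nodes[i] for i in np.nonzero(lvec)[0]]
        receiver = spec.nodes[int(np.nonzero(rvec == -1.0)[0][0])]
        steps.append((-1.0 / lam, donor_pool, receiver))
    return steps


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_dot(obj, path) -> None:
    """Write a labeled or reduced digraph in DOT format."""
    lines = ["digraph crn {"]
    if isinstance(obj, LabeledDigraph):
        edges = obj.edges
    else:
        edges = obj.edge_list()
    for e in edges:
        lab = str(e.expr) if e.rank is None else f"{e.expr} (#{e.rank})"
        lines.append(f'  "{e.src}" -> "{e.dst}" [label="{lab}"];')
    lines.append("}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
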