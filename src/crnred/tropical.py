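"""Tropicalization of polynomial vector fields and piecewise-smooth
(Filippov) dynamics.

The tropicalization replaces each species' balance polynomial
P_i(c) = sum_alpha a_alpha c^alpha by its dominant monomial:

    dc_i/dt = s_i exp[ max_alpha ( log|a_alpha| + <log c, alpha> ) ],

with s_i the sign of the coefficient achieving the max.  The locus where
two or more monomials tie (the tropical manifold) is the discontinuity
set; trajectories can cross it or slide along it.  On a two-sided
discontinuity surface Sigma with one-sided fields f+, f- and interior
normals n+ = -n-, a sliding mode exists where

    <n+, f+> < 0   and   <n-, f-> < 0,

i.e. both one-sided fields point toward the surface.  The sliding field
is the Filippov convex combination lam*f+ + (1-lam)*f- with lam chosen so
the combination is tangent to Sigma.

All dominance comparisons are made in natural-log coordinates u = log c
with absolute tolerance 1e-9; a positivity floor (default 1e-30) guards
the log transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import linprog

from .core import RHS, SignedMonomial

__all__ = [
    "TropicalPolynomial", "TropicalODESystem", "TropicalManifold",
    "SlidingSurface", "DegenerateManifold",
    "tropicalize", "dominant_monomial", "tropical_manifold_2d",
    "sliding_test", "simulate_hybrid", "detect_fast_constraints",
    "surface_for_pair", "HybridTrajectory",
]

LOG_TOL = 1e-9
FLOOR = 1e-30


class DegenerateManifold(ValueError):
    """All monomials share one exponent vector: no discontinuity set."""


class TropicalPolynomial:
    """Signed monomials with numeric coefficients, merged by exponent.

    ``logcoeffs[k] + exponents[k] @ u`` is the log-magnitude of monomial k
    at u = log c; ``signs[k]`` its sign.
    """

    def __init__(self, signs, logcoeffs, exponents, coeff_exprs=None):
        self.signs = np.asarray(signs, dtype=int)
        self.logcoeffs = np.asarray(logcoeffs, dtype=float)
        self.exponents = np.asarray(exponents, dtype=float)
        self.coeff_exprs = coeff_exprs

    @classmethod
    def from_monomials(cls, monomials: Sequence[SignedMonomial],
                       subs: Mapping) -> "TropicalPolynomial":
        acc: dict[tuple, float] = {}
        exprs: dict[tuple, sp.Expr] = {}
        for m in monomials:
            a = m.sign * float(sp.sympify(m.coeff).subs(subs))
            acc[m.exponents] = acc.get(m.exponents, 0.0) + a
            exprs[m.exponents] = exprs.get(m.exponents, sp.Integer(0)) \
                + m.sign * sp.sympify(m.coeff)
        signs, logs, exps, ce = [], [], [], []
        for e, a in acc.items():
            if a == 0.0:
                continue
            signs.append(1 if a > 0 else -1)
            logs.append(np.log(abs(a)))
            exps.append(e)
            ce.append(exprs[e])
        return cls(signs, logs, np.array(exps, dtype=float), ce)

    def __len__(self):
        return len(self.signs)

    def log_values(self, u: np.ndarray) -> np.ndarray:
        return self.logcoeffs + self.exponents @ np.asarray(u, dtype=float)

    def tropical_value(self, c: np.ndarray) -> float:
        """max-plus polynomial P^tau(c): the largest |monomial| at c."""
        u = np.log(np.maximum(np.asarray(c, dtype=float), FLOOR))
        return float(np.exp(self.log_values(u).max()))


def dominant_monomial(p: TropicalPolynomial, c: np.ndarray,
                      tol: float = LOG_TOL):
    """Index of the dominant (largest |.|) monomial at c > 0 and the tie
    set of indices within ``tol`` of the max in log scale."""
    u = np.log(np.maximum(np.asarray(c, dtype=float), FLOOR))
    lv = p.log_values(u)
    best = int(np.argmax(lv))
    ties = [int(k) for k in np.nonzero(lv >= lv[best] - tol)[0]
            if k != best]
    return best, ties


class TropicalODESystem:
    """One TropicalPolynomial per species; the tropicalized field picks
    each species' dominant monomial."""

    def __init__(self, species_ids: Sequence[str],
                 polys: Sequence[TropicalPolynomial]):
        self.species_ids = list(species_ids)
        self.polys = list(polys)

    @property
    def n(self):
        return len(self.polys)

    def dominant_selection(self, u: np.ndarray) -> list[int]:
        return [int(np.argmax(p.log_values(u))) if len(p) else -1
                for p in self.polys]

    def field_log(self, u: np.ndarray,
                  selection: Sequence[int] | None = None) -> np.ndarray:
        """du/dt with each species following its (or the given) monomial."""
        du = np.zeros(self.n)
        for i, p in enumerate(self.polys):
            if len(p) == 0:
                continue
            k = selection[i] if selection is not None \
                else int(np.argmax(p.log_values(u)))
            du[i] = p.signs[k] * np.exp(p.log_values(u)[k] - u[i])
        return du

    def field(self, c: np.ndarray) -> np.ndarray:
        """dc/dt of the tropicalized system at c > 0."""
        u = np.log(np.maximum(np.asarray(c, dtype=float), FLOOR))
        return self.field_log(u) * np.exp(u)


def tropicalize(rhs_field: RHS, params: Mapping[str, float]
                ) -> TropicalODESystem:
    """Tropicalize a polynomial vector field at the given parameter
    values: deterministic function of the field."""
    by_name = {k: sp.Float(v) for k, v in params.items()}
    polys = []
    for ms in rhs_field.monomials:
        # substitute parameters by symbol name so caller-side assumption
        # flags (positive=True etc.) do not matter
        resolved = []
        for m in ms:
            coeff = sp.sympify(m.coeff)
            coeff = coeff.subs({s: by_name[str(s)]
                                for s in coeff.free_symbols
                                if str(s) in by_name})
            resolved.append(SignedMonomial(m.sign, coeff, m.exponents,
                                           m.source))
        polys.append(TropicalPolynomial.from_monomials(resolved, {}))
    return TropicalODESystem(rhs_field.species_ids, polys)


# ---------------------------------------------------------------------------
# 2D tropical manifold
# ---------------------------------------------------------------------------

@dataclass
class TropicalManifold:
    """Arrangement of the tie locus of a 2-variable max-plus polynomial in
    log coordinates: vertices, finite segments, rays (point + direction),
    full lines, and the indices of monomials that dominate some open cell.
    Every segment/ray/line is annotated with its tying monomial pair."""
    variables: tuple[str, str]
    vertices: list[np.ndarray]
    segments: list[tuple[np.ndarray, np.ndarray, tuple[int, int]]]
    rays: list[tuple[np.ndarray, np.ndarray, tuple[int, int]]]
    lines: list[tuple[np.ndarray, np.ndarray, tuple[int, int]]]
    cells: list[int]

    @property
    def n_arms(self) -> int:
        return len(self.rays) + len(self.lines) * 2

    def cell_of(self, p: TropicalPolynomial, u: np.ndarray) -> int:
        return int(np.argmax(p.log_values(u)))


def _effective_2d(p: TropicalPolynomial):
    """Columns of the exponent matrix that actually vary."""
    var_cols = [j for j in range(p.exponents.shape[1])
                if not np.allclose(p.exponents[:, j], p.exponents[0, j])]
    return var_cols


def tropical_manifold_2d(p: TropicalPolynomial,
                         species_ids: Sequence[str] | None = None,
                         tol: float = LOG_TOL) -> TropicalManifold:
    """Tie locus of a max-plus polynomial in exactly two effective
    variables (other exponent columns must be constant across monomials).
    """
    if len(p) == 0:
        raise DegenerateManifold("empty polynomial")
    cols = _effective_2d(p)
    if len(cols) == 0:
        raise DegenerateManifold("all monomials share one exponent vector")
    if p.exponents.shape[1] == 2:
        cols = [0, 1]          # embed in the full plane of both variables
    elif len(cols) != 2:
        raise ValueError(f"polynomial has {len(cols)} effective variables, "
                         "need exactly 2")
    A = p.exponents[:, cols]              # (m, 2) slopes
    b = p.logcoeffs.copy()                # offsets
    m = len(p)
    names = (species_ids[cols[0]], species_ids[cols[1]]) if species_ids \
        else (f"u{cols[0]}", f"u{cols[1]}")

    vertices: list[np.ndarray] = []
    segments, rays, lines = [], [], []
    for i in range(m):
        for j in range(i + 1, m):
            d = A[i] - A[j]
            if np.allclose(d, 0):
                continue
            # line  d @ u = b[j] - b[i];  direction along the line
            p0 = d * (b[j] - b[i]) / (d @ d)
            t_dir = np.array([-d[1], d[0]])
            lo, hi = -np.inf, np.inf
            feasible = True
            for k in range(m):
                if k in (i, j):
                    continue
                # dominance of the pair over k:  (A_k - A_i) @ u <= b_i - b_k
                g = A[k] - A[i]
                const = (g @ p0) - (b[i] - b[k])
                slope = g @ t_dir
                if abs(slope) < 1e-14:
                    if const > tol:
                        feasible = False
                        break
                    continue
                t_star = -const / slope
                if slope > 0:
                    hi = min(hi, t_star)
                else:
                    lo = max(lo, t_star)
            if not feasible or lo >= hi - 1e-12:
                continue
            pair = (i, j)
            if np.isfinite(lo) and np.isfinite(hi):
                a_pt, b_pt = p0 + lo * t_dir, p0 + hi * t_dir
                segments.append((a_pt, b_pt, pair))
                vertices += [a_pt, b_pt]
            elif np.isfinite(lo):
                a_pt = p0 + lo * t_dir
                rays.append((a_pt, t_dir, pair))
                vertices.append(a_pt)
            elif np.isfinite(hi):
                a_pt = p0 + hi * t_dir
                rays.append((a_pt, -t_dir, pair))
                vertices.append(a_pt)
            else:
                lines.append((p0, t_dir, pair))
    # dedupe vertices
    uniq: list[np.ndarray] = []
    for v in vertices:
        if not any(np.allclose(v, w, atol=1e-8) for w in uniq):
            uniq.append(v)
    # cells: monomials dominating an open region (Chebyshev-center LP)
    cells = []
    for i in range(m):
        A_ub, b_ub = [], []
        for k in range(m):
            if k == i:
                continue
            g = A[k] - A[i]
            nrm = np.linalg.norm(g)
            A_ub.append(np.array([g[0], g[1], nrm]))
            b_ub.append(b[i] - b[k])
        # keep the center in a large box so the LP is bounded
        box = 1e6
        for gx, gy in [(1, 0), (-1, 0), (0, 1), (0, -1)]:
            A_ub.append(np.array([gx, gy, 0.0]))
            b_ub.append(box)
        res = linprog(c=[0, 0, -1], A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                      bounds=[(None, None), (None, None), (0, None)],
                      method="highs")
        if res.success and res.x[2] > 1e-7:
            cells.append(i)
    return TropicalManifold(names, uniq, segments, rays, lines, cells)


# ---------------------------------------------------------------------------
# sliding surfaces
# ---------------------------------------------------------------------------

@dataclass
class SlidingSurface:
    """Tie hyperplane of two monomials of one species' polynomial:
    {u : <u, alpha1 - alpha2> = log|a2| - log|a1|} in log coordinates."""
    species: int
    pair: tuple[int, int]
    normal: np.ndarray          # alpha1 - alpha2
    offset: float               # log|a2| - log|a1|
    sliding_fraction: float | None = None
    samples: list[tuple[np.ndarray, bool]] = field(default_factory=list)

    def residual(self, u: np.ndarray) -> float:
        return float(self.normal @ u - self.offset)

    def project(self, u: np.ndarray) -> np.ndarray:
        n2 = self.normal @ self.normal
        return u - self.residual(u) * self.normal / n2

    def equation(self, species_ids) -> str:
        lhs = "+".join(f"{a:g}*log({s})"
                       for a, s in zip(self.normal, species_ids) if a)
        return f"{lhs} = {self.offset:g}"


def surface_for_pair(sys: TropicalODESystem, i: int,
                     pair: tuple[int, int]) -> SlidingSurface:
    p = sys.polys[i]
    k1, k2 = pair
    return SlidingSurface(i, pair,
                          p.exponents[k1] - p.exponents[k2],
                          p.logcoeffs[k2] - p.logcoeffs[k1])


def sliding_test(sys: TropicalODESystem, surf: SlidingSurface,
                 x: np.ndarray, log_coords: bool = False,
                 h: float = 1e-4) -> bool:
    """True iff both one-sided tropicalized fields point toward the
    surface at ``x`` (a point on the surface, concentrations by default).
    """
    u = np.asarray(x, dtype=float) if log_coords \
        else np.log(np.maximum(np.asarray(x, dtype=float), FLOOR))
    u = surf.project(u)
    n = surf.normal / np.linalg.norm(surf.normal)
    up, um = u + h * n, u - h * n
    fp = sys.field_log(up)
    fm = sys.field_log(um)
    return bool((n @ fp) < 0 and (-(n) @ fm) < 0)


# ---------------------------------------------------------------------------
# hybrid simulation
# ---------------------------------------------------------------------------

@dataclass
class HybridTrajectory:
    species_ids: list[str]
    t: np.ndarray
    c: np.ndarray                      # (len(t), n)
    events: list[dict]
    sliding_intervals: list[tuple[float, float, tuple[int, int, int]]]

    def log_c(self):
        return np.log(np.maximum(self.c, FLOOR))


def _lambda_filippov(sys, i, k1, k2, u, selection):
    """Filippov coefficient making the combined field tangent to the tie
    surface of monomials k1/k2 of species i."""
    p = sys.polys[i]
    grad = p.exponents[k1] - p.exponents[k2]
    s1 = list(selection)
    s1[i] = k1
    s2 = list(selection)
    s2[i] = k2
    F1 = sys.field_log(u, s1)
    F2 = sys.field_log(u, s2)
    denom = grad @ (F2 - F1)
    if abs(denom) < 1e-300:
        return 0.5, F1, F2, grad
    return (grad @ F2) / denom, F1, F2, grad


def simulate_hybrid(sys: TropicalODESystem, c0: np.ndarray, horizon: float,
                    t_eval_per_segment: int = 50, rtol: float = 1e-8,
                    atol: float = 1e-10, max_events: int = 2000
                    ) -> HybridTrajectory:
    """Integrate the tropicalized system, switching monomials at tie
    surfaces and following Filippov sliding fields where the sliding
    condition holds.  Works in log coordinates; every transition is
    recorded in the event log."""
    u = np.log(np.maximum(np.asarray(c0, dtype=float), FLOOR))
    t = 0.0
    events: list[dict] = []
    sliding_intervals = []
    ts_all = [np.array([0.0])]
    us_all = [u[None, :].copy()]
    selection = sys.dominant_selection(u)
    sliding: tuple[int, int, int] | None = None   # (species, k1, k2)
    slide_t0 = None
    tol_t = 1e-10 * horizon

    def smooth_rhs(_t, uu):
        return sys.field_log(uu, selection)

    def slide_rhs(_t, uu):
        i, k1, k2 = sliding
        lam, F1, F2, _ = _lambda_filippov(sys, i, k1, k2, uu, selection)
        lam_c = min(max(lam, 0.0), 1.0)
        return lam_c * F1 + (1 - lam_c) * F2

    n_ev = 0
    while t < horizon - tol_t and n_ev < max_events:
        if sliding is None:
            ev_fns = []
            ev_meta = []
            for i, p in enumerate(sys.polys):
                if len(p) < 2:
                    continue
                di = selection[i]
                for k in range(len(p)):
                    if k == di:
                        continue
                    def fn(_t, uu, i=i, di=di, k=k):
                        lv = sys.polys[i].log_values(uu)
                        return lv[di] - lv[k]
                    fn.terminal = True
                    fn.direction = -1
                    ev_fns.append(fn)
                    ev_meta.append((i, di, k))
            sol = solve_ivp(smooth_rhs, (t, horizon), u, events=ev_fns,
                            rtol=rtol, atol=atol, dense_output=True,
                            method="LSODA")
            tend = sol.t[-1]
            seg_t = np.linspace(t, tend, t_eval_per_segment)
            ts_all.append(seg_t[1:])
            us_all.append(sol.sol(seg_t[1:]).T)
            u = sol.y[:, -1].copy()
            t = tend
            hit = [j for j, te in enumerate(sol.t_events) if len(te)]
            if not hit:
                break
            n_ev += 1
            i, di, k = ev_meta[hit[0]]
            if len(hit) > 1:
                events.append({"t": t, "type": "degenerate",
                               "detail": "multiple simultaneous ties"})
            surf = surface_for_pair(sys, i, (di, k))
            if sliding_test(sys, surf, u, log_coords=True):
                sliding = (i, di, k)
                slide_t0 = t
                events.append({"t": t, "type": "slide_start",
                               "species": sys.species_ids[i],
                               "pair": (di, k)})
            else:
                selection[i] = k
                events.append({"t": t, "type": "switch",
                               "species": sys.species_ids[i],
                               "from": di, "to": k})
        else:
            i, k1, k2 = sliding

            def lam_fn(_t, uu):
                lam, *_ = _lambda_filippov(sys, i, k1, k2, uu, selection)
                return lam

            def lam0(_t, uu):
                return lam_fn(_t, uu)
            lam0.terminal = True

            def lam1(_t, uu):
                return lam_fn(_t, uu) - 1.0
            lam1.terminal = True
            ev_fns = [lam0, lam1]
            ev_meta = [("exit", k2), ("exit", k1)]
            # third-monomial ties of the sliding species
            p = sys.polys[i]
            for k in range(len(p)):
                if k in (k1, k2):
                    continue
                def fn3(_t, uu, k=k):
                    lv = p.log_values(uu)
                    return max(lv[k1], lv[k2]) - lv[k]
                fn3.terminal = True
                fn3.direction = -1
                ev_fns.append(fn3)
                ev_meta.append(("triple", k))
            # ties of other species
            for jj, pj in enumerate(sys.polys):
                if jj == i or len(pj) < 2:
                    continue
                dj = selection[jj]
                for k in range(len(pj)):
                    if k == dj:
                        continue
                    def fnj(_t, uu, jj=jj, dj=dj, k=k):
                        lv = sys.polys[jj].log_values(uu)
                        return lv[dj] - lv[k]
                    fnj.terminal = True
                    fnj.direction = -1
                    ev_fns.append(fnj)
                    ev_meta.append(("other", jj, dj, k))
            sol = solve_ivp(slide_rhs, (t, horizon), u, events=ev_fns,
                            rtol=rtol, atol=atol, dense_output=True,
                            method="LSODA")
            tend = sol.t[-1]
            seg_t = np.linspace(t, tend, t_eval_per_segment)
            ts_all.append(seg_t[1:])
            us_all.append(sol.sol(seg_t[1:]).T)
            u = sol.y[:, -1].copy()
            t = tend
            hit = [j for j, te in enumerate(sol.t_events) if len(te)]
            if not hit:
                sliding_intervals.append((slide_t0, t, sliding))
                break
            n_ev += 1
            meta = ev_meta[hit[0]]
            if meta[0] == "exit":
                sliding_intervals.append((slide_t0, t, sliding))
                selection[i] = meta[1]
                events.append({"t": t, "type": "slide_end",
                               "species": sys.species_ids[i],
                               "to": meta[1]})
                sliding = None
            elif meta[0] == "triple":
                events.append({"t": t, "type": "degenerate",
                               "species": sys.species_ids[i],
                               "detail": f"triple tie with monomial "
                                         f"{meta[1]}"})
                # hierarchical Filippov: keep sliding on the pair whose
                # convex field is consistent; here continue with the new
                # dominant pair
                lv = p.log_values(u)
                top2 = np.argsort(lv)[-2:]
                sliding_intervals.append((slide_t0, t, sliding))
                sliding = (i, int(top2[1]), int(top2[0]))
                slide_t0 = t
            else:
                _tag, jj, dj, k = meta
                surf = surface_for_pair(sys, jj, (dj, k))
                if sliding_test(sys, surf, u, log_coords=True):
                    events.append({"t": t, "type": "degenerate",
                                   "detail": "second sliding surface; "
                                             "switching species"})
                    sliding_intervals.append((slide_t0, t, sliding))
                    sliding = (jj, dj, k)
                    slide_t0 = t
                else:
                    selection[jj] = k
                    events.append({"t": t, "type": "switch",
                                   "species": sys.species_ids[jj],
                                   "from": dj, "to": k})
    if sliding is not None and (not sliding_intervals
                                or sliding_intervals[-1][1] < t):
        sliding_intervals.append((slide_t0, t, sliding))
    tarr = np.concatenate(ts_all)
    uarr = np.vstack(us_all)
    return HybridTrajectory(list(sys.species_ids), tarr, np.exp(uarr),
                            events, sliding_intervals)


# ---------------------------------------------------------------------------
# detection of fast constraints (QE/QSS candidates)
# ---------------------------------------------------------------------------

def detect_fast_constraints(sys: TropicalODESystem,
                            region: tuple[np.ndarray, np.ndarray],
                            n_samples: int = 10, seed: int = 0,
                            tol: float = LOG_TOL) -> list[SlidingSurface]:
    """All 2-monomial tie hyperplanes intersecting the log-coordinate box
    ``region=(lo, hi)`` on which the sliding condition holds at sampled
    points.  Each returned surface is annotated with the fraction of
    valid samples that slide."""
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for i, p in enumerate(sys.polys):
        for k1 in range(len(p)):
            for k2 in range(k1 + 1, len(p)):
                if np.allclose(p.exponents[k1], p.exponents[k2]):
                    continue
                surf = surface_for_pair(sys, i, (k1, k2))
                valid = 0
                slid = 0
                samples = []
                for _ in range(n_samples * 5):
                    if valid >= n_samples:
                        break
                    u = rng.uniform(lo, hi)
                    u = surf.project(u)
                    if np.any(u < lo - 1e-9) or np.any(u > hi + 1e-9):
                        continue
                    lv = p.log_values(u)
                    top = lv.max()
                    if lv[k1] < top - tol:
                        continue     # pair not dominant here
                    valid += 1
                    ok = sliding_test(sys, surf, u, log_coords=True)
                    slid += ok
                    samples.append((u, ok))
                if valid and slid:
                    surf.sliding_fraction = slid / valid
                    surf.samples = samples
                    out.append(surf)
    return out
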