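"""Detection of slaved species via imposed trajectories, and their
QE/QSS classification by monomial pruning.

Given simulated trajectories c(t), the *imposed trajectory* of species i
is a real positive root c*_i(t) of its own balance polynomial with every
other coordinate frozen at the simulated value:

    P_i(c_1(t), ..., c*_i(t), ..., c_n(t)) = 0.

A species is *slaved* on an interval I when

    sup_{t in I} | log c_i(t) - log c*_i(t) | < delta

for a small delta (default ln 2: within two-fold of the imposed value).
Species that are not slaved are the slow species; their number lower
bounds the dimension of any reduced model.

Slaved species split into two kinds.  Pruning the dominated monomials of
P_i along the trajectory (time-median log-magnitude, margin one decade by
default) leaves the binding constraint: when the retained monomials pair
into forward/backward rates of reversible reactions set to zero the
species satisfies quasi-equilibrium (QE); otherwise it is a
quasi-steady-state (QSS) species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .core import (RHS, ReactionNetwork, conservation_laws, rhs,
                   stoichiometric_matrix, reaction_rates)

__all__ = [
    "Trajectory", "ImposedTrajectory", "SlavedEntry", "SlavedReport",
    "integrate_full", "imposed_trajectory", "classify_species",
    "classify_qe_vs_qss", "slaved_report", "NotSlavableError",
]

DELTA_DEFAULT = math.log(2.0)


class NotSlavableError(ValueError):
    """P_i does not depend on c_i: no imposed trajectory exists."""


@dataclass
class Trajectory:
    species_ids: list[str]
    t: np.ndarray
    c: np.ndarray                       # (len(t), n)
    rtol: float
    atol: float
    stiff: bool
    conservation_drift: float = 0.0

    def column(self, i: int) -> np.ndarray:
        return self.c[:, i]


@dataclass
class ImposedTrajectory:
    species: int
    t: np.ndarray
    values: np.ndarray                  # selected positive root, NaN if none
    n_positive_roots: np.ndarray        # per time point
    note: str = "root closest to the actual trajectory in log metric"


@dataclass
class SlavedEntry:
    species: str
    status: str                         # "slaved" | "slow"
    sub_status: str                     # "QE" | "QSS" | "unresolved" | "n/a"
    max_log_distance: float
    interval: tuple[float, float]
    delta: float
    pruned_equation: list[str] = field(default_factory=list)


@dataclass
class SlavedReport:
    entries: list[SlavedEntry]

    @property
    def n_slow(self) -> int:
        return sum(e.status == "slow" for e in self.entries)

    def __str__(self):
        rows = [f"{'species':<12}{'status':<8}{'sub':<12}"
                f"{'sup|log c - log c*|':<22}interval"]
        for e in self.entries:
            rows.append(f"{e.species:<12}{e.status:<8}{e.sub_status:<12}"
                        f"{e.max_log_distance:<22.4g}"
                        f"[{e.interval[0]:.3g}, {e.interval[1]:.3g}]")
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_full(net: ReactionNetwork, c0=None, horizon: float = 1.0,
                   n_points: int = 400, rtol: float = 1e-8,
                   atol: float = 1e-12, log_times: bool = False
                   ) -> Trajectory:
    """Stiff-capable integration of dc/dt = S R(c).

    Conservation-law drift is measured and must stay below 1e-6 relative;
    a failed integration raises with the time interval reached.
    """
    c0 = net.initial_concentrations() if c0 is None else np.asarray(
        c0, dtype=float)
    S = stoichiometric_matrix(net)

    def f(_t, c):
        return S @ reaction_rates(net, np.maximum(c, 0.0))

    if log_times:
        t_eval = np.logspace(math.log10(horizon) - 9, math.log10(horizon),
                             n_points)
        t_eval = np.concatenate([[0.0], t_eval])
    else:
        t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(f, (0.0, horizon), c0, method="LSODA", rtol=rtol,
                    atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"integration failed on [{sol.t[-1] if len(sol.t) else 0}, "
            f"{horizon}]: {sol.message}")
    C = np.maximum(sol.y.T, 0.0)
    drift = 0.0
    for b in conservation_laws(net):
        tot = C @ np.asarray(b, dtype=float)
        ref = abs(tot[0]) if tot[0] != 0 else 1.0
        drift = max(drift, float(np.abs(tot - tot[0]).max() / ref))
    if drift > 1e-6:
        raise RuntimeError(f"conservation drift {drift:.2e} exceeds 1e-6")
    return Trajectory(net.species_ids, sol.t, C, rtol, atol,
                      stiff=True, conservation_drift=drift)


# ---------------------------------------------------------------------------
# imposed trajectories
# ---------------------------------------------------------------------------

def imposed_trajectory(field: RHS, traj: Trajectory, i: int,
                       subs: Mapping | None = None) -> ImposedTrajectory:
    """Positive roots of P_i in c_i with the other species frozen at each
    time point; the root closest to c_i(t) in log metric is selected (all
    positive-root counts retained)."""
    subs = subs or {}
    if all(m.exponents[i] == 0 for m in field.monomials[i]):
        raise NotSlavableError(
            f"P_{field.species_ids[i]} does not depend on "
            f"{field.species_ids[i]}")
    vals = np.full(len(traj.t), np.nan)
    counts = np.zeros(len(traj.t), dtype=int)
    for kk, tt in enumerate(traj.t):
        c = traj.c[kk]
        coeffs = field.univariate(i, c, subs)       # ascending degree
        nz = np.nonzero(np.abs(coeffs) > 0)[0]
        if len(nz) == 0:
            continue
        if len(nz) == 1:
            # single monomial: root only at 0, not positive
            continue
        roots = np.roots(coeffs[::-1])
        pos = [r.real for r in roots
               if abs(r.imag) <= 1e-9 * max(1.0, abs(r.real))
               and r.real > 0]
        counts[kk] = len(pos)
        if not pos:
            continue
        ci = max(c[i], 1e-300)
        vals[kk] = min(pos, key=lambda r: abs(math.log(r) - math.log(ci)))
    return ImposedTrajectory(i, traj.t, vals, counts)


def _fastest_timescale(field: RHS, traj: Trajectory, subs) -> float:
    """Crude estimate 1 / max_i |dP_i/dc_i| early on the trajectory."""
    k = min(1, len(traj.t) - 1)
    c = np.maximum(traj.c[k], 0.0)
    rate_max = 0.0
    for i in range(len(c)):
        coeffs = field.univariate(i, c, subs)
        # derivative of P_i wrt c_i at c_i
        d = sum(j * coeffs[j] * max(c[i], 1e-300) ** (j - 1)
                for j in range(1, len(coeffs)))
        rate_max = max(rate_max, abs(d))
    return 1.0 / rate_max if rate_max > 0 else traj.t[-1] / 100.0


def classify_species(traj: Trajectory, imposed: ImposedTrajectory,
                     delta: float = DELTA_DEFAULT,
                     interval: tuple[float, float] | None = None
                     ) -> tuple[str, float, tuple[float, float]]:
    """Slaved/slow by the sup-log criterion on the interval (default:
    everything after the initial layer, i.e. t >= 3 x fastest timescale
    supplied by the caller, or the final 90 % of the horizon)."""
    if interval is None:
        interval = (traj.t[-1] * 0.1, traj.t[-1])
    mask = (traj.t >= interval[0]) & (traj.t <= interval[1])
    ci = np.maximum(traj.c[mask, imposed.species], 1e-300)
    cs = imposed.values[mask]
    if np.all(np.isnan(cs)):
        return "slow", math.inf, interval
    with np.errstate(invalid="ignore"):
        d = np.abs(np.log(ci) - np.log(cs))
    sup = float(np.nanmax(d)) if np.any(~np.isnan(d)) else math.inf
    if np.any(np.isnan(cs)):
        sup = math.inf                       # imposed root missing somewhere
    return ("slaved" if sup < delta else "slow"), sup, interval


# ---------------------------------------------------------------------------
# QE vs QSS classification
# ---------------------------------------------------------------------------

def classify_qe_vs_qss(net: ReactionNetwork, traj: Trajectory, i: int,
                       interval: tuple[float, float] | None = None,
                       margin: float = 10.0):
    """Prune dominated monomials of P_i along the trajectory and decide
    QE vs QSS from what remains.

    Monomials whose time-median magnitude is below the largest median by
    more than ``margin`` (a decade by default) are dominated and removed.
    If every retained monomial belongs to a reversible reaction with both
    directions retained, the pruned equation is a combination of
    reversible rates set to zero: QE.  Otherwise QSS.  Returns
    (sub_status, retained monomial descriptions, magnitude table).
    """
    field = rhs(net)                    # unmerged, with provenance
    subs = net.param_subs()
    if interval is None:
        interval = (traj.t[-1] * 0.1, traj.t[-1])
    mask = (traj.t >= interval[0]) & (traj.t <= interval[1])
    monos = field.monomials[i]
    med = []
    for m in monos:
        mags = [abs(m.value(traj.c[kk], subs))
                for kk in np.nonzero(mask)[0]]
        med.append(float(np.median(mags)))
    table = [(str(m.expr(field.symbols)), m.source, v)
             for m, v in zip(monos, med)]
    top = max(med) if med else 0.0
    retained = [m for m, v in zip(monos, med) if v >= top / margin]
    pruned_any = len(retained) < len(monos)
    rev_map = {r.id: r.reversible for r in net.reactions}
    dirs: dict[str, set[str]] = {}
    for m in retained:
        rid, d = m.source
        dirs.setdefault(rid, set()).add(d)
    all_rev_paired = retained and all(
        rev_map[rid] and ds == {"fwd", "rev"} for rid, ds in dirs.items())
    any_reversible = any(rev_map[rid] for rid in dirs)
    if all_rev_paired:
        sub = "QE"
    elif not any_reversible or pruned_any:
        sub = "QSS"
    else:
        sub = "unresolved"
    eq = [("+" if m.sign > 0 else "-") + str(m.expr(field.symbols) * m.sign)
          for m in retained]
    return sub, eq, table


def slaved_report(net: ReactionNetwork, traj: Trajectory | None = None,
                  horizon: float = 1.0, delta: float = DELTA_DEFAULT,
                  interval: tuple[float, float] | None = None,
                  margin: float = 10.0) -> SlavedReport:
    """Full per-species report: slaved/slow and QE/QSS with the pruned
    equations, over the interval after the initial layer (3 x fastest
    timescale by default)."""
    if traj is None:
        traj = integrate_full(net, horizon=horizon)
    field = rhs(net)
    subs = net.param_subs()
    if interval is None:
        t0 = min(3.0 * _fastest_timescale(field, traj, subs),
                 0.5 * traj.t[-1])
        interval = (t0, traj.t[-1])
    entries = []
    for i, sid in enumerate(net.species_ids):
        try:
            imp = imposed_trajectory(field, traj, i, subs)
        except NotSlavableError:
            entries.append(SlavedEntry(sid, "slow", "n/a", math.inf,
                                       interval, delta))
            continue
        status, sup, _ = classify_species(traj, imp, delta, interval)
        if status == "slaved":
            sub, eq, _tab = classify_qe_vs_qss(net, traj, i, interval,
                                               margin)
        else:
            sub, eq = "n/a", []
        entries.append(SlavedEntry(sid, status, sub, sup, interval, delta,
                                   eq))
    return SlavedReport(entries)
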