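# crnred

Multiscale model reduction of deterministic biochemical reaction
networks with mass-action kinetics.

Large kinetic models in cell signaling, metabolism and gene regulation
suffer from uncertain parameters and combinatorial size, but their rate
constants typically span many orders of magnitude.  When constants are
*totally separated* (every pair differs by orders of magnitude) the
dynamics is governed by dominance: on each timescale only one term of
each balance matters, and the reduced model depends on the *order* of
the constants, not their exact values.  `crnred` implements this
dominance calculus end to end, for modelers who want reproducible,
symbolic reductions of their networks:

* **Linear (monomolecular) networks** `A_i -> A_j`, `dc/dt = Kc`: graph
  rewriting with three rules — prune all but the fastest edge at each
  node (rule a), cut a cycle at its slowest (limiting) step (rule b),
  glue a cycle with slow exits into a pooled node whose outgoing
  constants are renormalized by the intra-cycle quasi-stationary
  distribution, e.g. `k5·k4/k3` (rule c).  The result is an acyclic
  digraph with out-degree ≤ 1 whose spectrum is explicit: one eigenvalue
  `−k` per surviving edge, left/right eigenvectors with coordinates in
  {0,1} / {0,1,−1}, so each timescale acts as a single effective
  reaction.  Renormalized constants are kept as exact symbolic
  monomials of the original constants.
* **Tropicalization** of polynomial fields `dc_i/dt = P_i(c)`: each
  polynomial is replaced by its dominant monomial,
  `dc_i/dt = s_i · exp max_α(log|a_α| + ⟨log c, α⟩)`.  The locus where
  two monomials tie (the tropical manifold; a tripod for a 3-monomial
  polynomial in two variables) is the discontinuity set of this
  piecewise-smooth system; the package computes 2-D tropical curves,
  tests the Filippov sliding condition `⟨n₊,f₊⟩<0 ∧ ⟨n₋,f₋⟩<0`, and
  simulates the hybrid dynamics with sliding modes and an event log.
* **Slaved-species detection**: the imposed trajectory `c*_i(t)` is a
  positive root of `P_i` with all other species frozen at their
  simulated values; species with
  `sup_t |log c_i − log c*_i| < δ` (default `δ = ln 2`) are slaved,
  the rest are the slow species that bound the reduced dimension.
  Pruning dominated monomials of `P_i` along the trajectory classifies
  each slaved species as quasi-equilibrium (QE, a reversible reaction
  balances) or quasi-steady state (QSS).
* **QSS/QE network rewriting**: the fast stoichiometric matrix `S^f`
  yields species pools (integer left kernel, `bᵀS^f = 0`, full-network
  conservation laws filtered out) and reaction routes (support-minimal
  right kernel, `S^f γ = 0` — the elementary modes of the fast
  subsystem).  Fast conditions are solved symbolically, route rates are
  fixed by matching every terminal species' production to the unreduced
  model, and every coefficient of the reduced rates is reported as an
  *effective parameter* — a monomial or simple rational composite of
  the original constants.

All kernel algebra is exact (integer/rational); floating point is used
only for rate evaluation and integration.

## Worked example

Reducing the enzymatic mechanism `S + E ⇌ ES → P + E` under the QSS
assumption on the complex (`examples/04_qssqe_rewriting.py`):

```
QSS reduction: one route {'S': -1, 'P': 1} built from {'binding': 1, 'catalysis': 1}
  rate = Etot*S*k1*k2/(S*k1 + k2 + km1)
  effective parameters:
    g1 = Etot*k2   [monomial]
    g2 = (k2 + km1)/k1   [composite]
  under k2 >> k-1 the composite k_m becomes the monomial k2/k1
```

The two reactions pool into a single irreversible route `S -> P` with
the Michaelis–Menten rate `k2·Etot·[S]/(k_m + [S])`,
`k_m = (k-1 + k2)/k1`; `g1 = k2·Etot` is the maximal velocity and `g2`
is `k_m`, the two identifiable quantities of the reduced law.  The QE
variant pools species instead (`Stot = [S] + [ES]` is the slow
variable) and returns the positive root of the equilibrium quadratic,
which collapses to the original Michaelis–Menten rate when
`Etot ≪ Stot`.

Other example scripts: `01_linear_reduction.py` (rules a/b/c and the
single-step timescale hierarchy), `02_tropicalization.py` (tripods,
sliding arms, hybrid simulation), `03_slaved_species.py` (imposed
trajectories and QE/QSS classification), `05_separation_diagnostics.py`
(total separation and the Zipf fingerprint).

A thin CLI mirrors the library for shell use:

```bash
crnred generate -n 6 -m 8 --eps 0.1 --seed 42 --out net.tsv
crnred reduce-linear --input net.tsv --separation-check --steps steps.json
crnred detect-slaved --input mm.tsv --horizon 50
crnred reduce-qssqe --input mm.tsv --mode qss --fast ES
```

Networks are read and written in a native tab-separated format and in
SBML (mass-action kinetic laws only; anything else fails loudly).

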