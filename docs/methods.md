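# Methods

## Scope and model class

`crnred` operates on deterministic, homogeneous, fixed-volume reaction
networks with mass-action kinetics,

    dc/dt = P(c) = Σ_j ν_j (R⁺_j(c) − R⁻_j(c)),
    R⁺_j = k⁺_j Π_i c_i^{α_ji},   R⁻_j = k⁻_j Π_i c_i^{β_ji},

where `ν_j = β_j − α_j`.  Every `P_i` is a multivariate polynomial; the
package stores it as a list of signed monomials.  Two representations
coexist deliberately: the *unmerged* form keeps one monomial per
reaction direction with `(reaction, direction)` provenance — required
by the QE/QSS classifier, which must compare `k₋₁[ES]` and `k₂[ES]`
individually even though they share an exponent vector — while the
*merged* form sums equal-exponent monomials and is used for
tropicalization and symbolic rewriting.

Rate constants are sympy expressions over declared parameter symbols,
so every derived quantity (renormalized linear constants, reduced
rates, effective parameters) stays symbolic; numeric values enter only
at evaluation time.  Units are arbitrary but must be consistent;
nothing in the calculus depends on them.

## Linear multiscale reduction

For monomolecular networks (`dc/dt = Kc`) with totally separated
constants the multiscale approximation is an acyclic deterministic
digraph.  The rewriting loop is: prune every node to its fastest
outgoing edge (rule a); if the pruned functional graph has a cycle,
glue it into one node and reroute *all* current edges — edges into the
cycle keep their constants, an edge leaving node `A_i` with constant
`k` becomes an edge of the glued node with constant `k·k_lim/k_i`,
where `k_i` is `A_i`'s intra-cycle exit constant and `k_lim` the
slowest cycle constant (this is the totally separated limit of the
cycle's normalized quasi-stationary distribution, `c°_i ∝ 1/k_i`);
repeat until acyclic.  Restoration proceeds in reverse gluing order:
the cycle is re-expanded with its limiting step deleted and, if the
glued node kept an outgoing edge, that edge is attached to the source
node of the limiting step — the node where the cycle mass
concentrates.  Incoming edges re-attach to the member that covers their
original destination (nested glue records keep a cover map).

Two numerical choices matter:

* **Dominance comparisons** happen on log-values of the symbolic
  monomials (`log(k5·k4/k3) = log k5 + log k4 − log k3`), with a tie
  tolerance of `1e-9` *relative to the log magnitude*.  The tolerance
  is not cosmetic: derived monomials can coincide with other constants
  exactly in real arithmetic (e.g. `k8·k7/k4 = k3` when ranks satisfy
  `r8+r7−r4 = r3` for `ε^rank` constants) yet differ by an ulp after
  float log summation.  Such coincidences violate total separation and
  raise `TieError`; callers may opt into deterministic multiplicative
  perturbation (factors `1 + i·1e-7`, chosen above the tie tolerance)
  with a warning.
* **Spectra across many decades.**  An acyclic deterministic digraph
  has eigenvalue `−k` for each surviving edge; the left eigenvector
  marks the pool of nodes draining into the edge's source through
  faster edges, the right eigenvector has `+1` on the donor and `−1` on
  the first downstream node with a slower exit.  Validating these
  approximations needs reference eigenvalues up to 24 decades below the
  matrix norm — beyond double precision, and beyond what QR iteration
  delivers even in high precision.  `eigenvalues_exact` therefore forms
  the characteristic polynomial of the exact rational kinetic matrix
  and polishes mp.eig estimates by Newton iteration on it.  The float
  representation of constants like `ε^rank` matters too: the low-order
  characteristic coefficients suffer heavy cancellation, and a 1e-16
  entry perturbation can shift the smallest eigenvalue by several
  percent, so reference spectra are computed from constants as exact
  powers of a rational ε.  High-precision trajectories
  (`exact_solution_mp`) use the same Newton-refined eigenvalues with
  inverse-iteration eigenvectors, falling back to a high-precision
  matrix exponential when the eigenbasis is (near-)defective.

## Tropicalization and hybrid dynamics

The tropicalized field replaces each `P_i` by its dominant monomial in
absolute value; off the tie locus it is an S-system (monomial) field.
All dominance tests run in natural-log coordinates `u = log c` with
absolute tolerance `1e-9`; a positivity floor of `1e-30` guards the log
transform and hitting it is recorded.  Two-variable tropical curves are
computed exactly as line arrangements: for each monomial pair the tie
line is clipped by the dominance constraints of the remaining monomials
(segment / ray / full line), and a monomial owns an open cell iff its
dominance polyhedron has a Chebyshev center with positive radius
(linear program).

Hybrid integration works in `u`-space (`du_i/dt = s_i exp(L_i(u) − u_i)`
is smooth within a cell).  Tie crossings are located by the
integrator's event detection on the log-difference of the competing
monomials.  At a crossing the sliding condition is evaluated by probing
the full tropicalized field on both sides of the surface; if both sides
point inward the trajectory continues on the Filippov field
`λf₊ + (1−λ)f₋` with `λ` solving the tangency condition, clipped to
[0,1].  Sliding ends when `λ` reaches 0 or 1 (the corresponding
one-sided field takes over), and ties of three or more monomials are
flagged `degenerate` and resolved by re-entering sliding on the current
top pair — a pragmatic stand-in for a full hierarchical Filippov hull,
adequate away from high-codimension corners.  The sliding-surface
detector samples each 2-monomial tie hyperplane inside a user box,
keeps surfaces where the pair actually dominates and the sliding test
passes, and reports the sliding fraction; these surfaces are the QE/QSS
constraint candidates.

## Slaved species

`integrate_full` uses LSODA with `rtol 1e-8` / `atol 1e-12` and rejects
runs whose conservation-law drift exceeds `1e-6` relative.  Imposed
trajectories solve the frozen univariate polynomial `P_i(c_i*) = 0` at
every grid time with `numpy.roots`; among multiple positive roots the
one closest to the actual trajectory in log metric is selected and the
root count retained.  The slaving threshold defaults to `δ = ln 2`
(within two-fold of the imposed value) — no canonical value exists, and
two-fold is the coarsest level at which "tracks its constraint" is
meaningful on concentration data.  The comparison interval excludes an
initial layer of three times the fastest timescale, estimated as
`1/max_i |∂P_i/∂c_i|` early on the trajectory.  Dominance pruning for
the QE/QSS call removes monomials whose time-median magnitude falls
more than one decade (configurable) below the largest; QE requires
every retained monomial to belong to a reversible reaction with both
directions retained, so the pruned balance is a combination of
reversible rates set to zero.  Species consumed only by irreversible
reactions are QSS regardless of magnitudes; "unresolved" is returned
when nothing is dominated and reversible pairs are incomplete.

## QSS/QE rewriting

`S^f` is built per mode (QSS: rows = fast species, zero columns
excluded; QE: columns = fast reversible reactions, zero rows excluded).
Kernels are computed in exact rational arithmetic and returned as
primitive integer vectors from the RREF of the kernel basis — a
reproducible, support-reduced normal form with a non-negative-preferred
sign convention.  Species pools are reduced modulo the full-network
conservation laws (a pool in their span carries no new slow variable);
pools of fast-affected species are preferred over trivial singleton
pools of untouched species when both represent the same coset.

Elementary modes are extreme rays of `{γ : S^f γ = 0, γ_j ≥ 0 for
irreversible j}`: reversible columns are split into opposite
irreversible pairs, rays are built row by row by double description
with support-minimality filtering, futile forward/backward cycles are
dropped on recombination, and vectors are normalized to coprime
integers with a canonical sign (irreversible entries non-negative;
otherwise first nonzero positive).  An independent exhaustive
minimal-support enumerator (`enumerate_modes_bruteforce`) exists purely
as a cross-check and is exercised against the tableau implementation on
hundreds of random matrices.

Fast conditions are solved symbolically (sympy) — QSS: `P_i = 0` with
caller-designated conserved totals eliminating partner species (e.g.
`E = Etot − ES`); QE: equilibrium of each fast reaction plus the fast
pools as coordinates.  Among the algebraic branches the one positive
(and below the relevant totals) at a numeric sample point is selected;
several admissible branches raise `BranchAmbiguityError` rather than
guessing.  Route rates are determined by equating, for every terminal
species, the summed route contributions to the substituted production
rate of the unreduced model; the linear system is solved symbolically,
overdetermined systems are checked for consistency, and underdetermined
ones take the particular solution with free route rates set to zero and
are flagged `non_unique` (no canonical uniqueness rule exists at this
level of description).  Effective parameters are the maximal
parameter-only subexpressions of the reduced rates after normalizing
rational rates to a denominator monic in the concentration variables —
this is what turns `Etot·k1·k2·S/(k1·S + k2 + k₋₁)` into
`Etot·k2·S/(S + k_m)` with `k_m = (k₋₁+k2)/k1` reported as a named
composite; `dominance_simplify` collapses composites to monomials in
strongly separated regimes.

## Synthetic data and canonical models

`generate_separated_monomolecular(n, m, ε, seed)` draws a uniform
random simple digraph with `m` edges and assigns constants `ε^π(e)` for
a seeded random permutation π — totally separated by construction with
adjacent ratio `1/ε`, and bit-reproducible for a given seed.  It
emulates exactly one feature of real networks: well-separated
timescales on a random topology.  It does not emulate conservation
structure, realistic degree distributions, or correlated constants, so
passing convergence tests show the correctness of the rewriting
calculus under its own hypothesis (total separation), not performance
on any particular biological network.  Derived monomial constants can
tie by rank coincidence; such seeds violate the hypothesis and are
skipped, which the benchmark reports.

The enzymatic mechanism builder ships the full 4-species network and
its 2-variable eliminated form; defaults in tests use
`Etot/Stot = 10⁻²` (enzyme-dilute) with `k2/k₋₁ = 10²` or `10⁻³` for
the QSS and QE regimes.  The five-variable cell-cycle builder encodes
its published ODEs as a mass-action network (the autocatalytic term
`k4 y4 y3²/C²` becomes `y4 + 2y3 → 3y3`); the source prints no
parameter values, so callers must supply them — examples use a
synthetic, clearly labeled set, and the structural results (symbolic
conservation of `y1+…+y4`, tripod structure of the `y3` balance, the
2-dimensional constrained manifold) are parameter-free or tested at
generic positive values.

The Zipf diagnostic estimates the power-law exponent of the constants'
*density* by least squares on a log-binned histogram; a log-uniform
distribution (density ∝ 1/c) gives −1.  The raw log-rank slope is
reported alongside for reference but is range-dependent (≈ −L/4 for a
log-uniform sample spanning L natural-log units) and is not the
diagnostic.

## Problem sizes

Defaults keep every computation desk-scale: random linear networks use
n = 6 nodes, m = 8 edges, 20 seeds and three separation levels (about
ten seconds with the high-precision spectral checks); elementary-mode
cross-checks use 200 random matrices up to 4×6; hybrid simulations run
on 1–2 species systems.  All generators and stochastic checks are
seed-deterministic.

## Known limitations

* Tropical manifolds are computed as full arrangements only in two
  variables; higher dimensions are handled pairwise (tie hyperplanes),
  without a polyhedral complex.
* The hybrid integrator treats one sliding constraint at a time;
  simultaneous sliding on several surfaces is logged as degenerate
  rather than resolved by the full Filippov hull.
* Symbolic fast-condition solving is practical for degree ≤ 2 per fast
  species; beyond that the dominance route (pruning before solving) is
  the intended path and only partially automated (`dominance_simplify`).
* SBML support covers mass-action kinetic laws with integer
  stoichiometry; events, assignments and volume dynamics are out of
  scope, and non-mass-action laws fail loudly by design.
* QE rewriting returns pooled ODEs with symbolic rates; it does not
  attempt to re-express the pooled system as a mass-action network.
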