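"""Rewrite the enzymatic mechanism under QSS and QE assumptions and
recover the Michaelis-Menten rate law symbolically.

QSS pools the two reactions into a single route S -> P whose rate is
k2 Etot [S]/(k_m + [S]) with k_m = (k-1 + k2)/k1; QE pools the species
into the slow total Stot = [S] + [ES] consumed at rate k2 [ES]_QE with
[ES]_QE the positive root of a quadratic.  The effective parameters of
the reduced rate are monomials (k2 Etot) or simple composites (k_m) of
the original constants.
"""

import sympy as sp

from crnred.fixtures import build_michaelis_menten
from crnred.rewrite import (dominance_simplify, effective_parameters,
                            reduce_qe, reduce_qss)

Etot, Stot = sp.symbols("Etot Stot")
net = build_michaelis_menten(1.0, 1.0, 1.0, Etot=0.01, Stot=1.0)

red = reduce_qss(net, ["ES"], conservation=[(Etot, "E", [0, 1, 1, 0])])
r = red.reactions[0]
print("QSS reduction: one route", r.stoichiometry,
      "built from", r.provenance)
print("  rate =", sp.simplify(r.rate))
print("  effective parameters:")
for p in effective_parameters(red):
    kind = "monomial" if p.is_monomial else "composite"
    print(f"    {p.name} = {p.expr}   [{kind}]")
km = (sp.Symbol("km1") + sp.Symbol("k2")) / sp.Symbol("k1")
print("  under k2 >> k-1 the composite k_m becomes the monomial",
      dominance_simplify(km, {"km1": 1e-4, "k2": 1.0, "k1": 1.0}))

redq = reduce_qe(net, ["binding"], pool_symbols=[Stot, Etot])
print("\nQE reduction: slow pool(s):", redq.variables)
for v, e in redq.odes.items():
    print(f"  d({v})/dt = {sp.simplify(e)}")
print("  [ES]_QE =", sp.simplify(redq.solutions[sp.Symbol('ES')]))
print("\nIn the dilute-enzyme limit Etot << Stot the QE rate reduces to "
      "the original Michaelis-Menten law k2 Etot Stot/(k-1/k1 + Stot).")
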