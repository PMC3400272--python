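"""Reading and writing reaction networks.

Two formats are supported:

* a native tab-separated text format with ``[species]``, ``[parameters]``
  and ``[reactions]`` sections, reaction sides written as ``2 A + B``;
* SBML Level 2/3, restricted to mass-action kinetic laws (read through
  python-libsbml).  Non-mass-action kinetic laws fail loudly with
  :class:`~crnred.core.UnsupportedKineticsError` naming the reaction.
"""

from __future__ import annotations

import re
from pathlib import Path

import sympy as sp

from .core import (NetworkError, Reaction, ReactionNetwork, Species,
                   UnsupportedKineticsError)

__all__ = ["load_network", "read_native", "write_native",
           "read_sbml", "write_sbml", "parse_side", "format_side"]


def load_network(path, format: str | None = None) -> ReactionNetwork:
    """Load a network from ``path``; format inferred from the suffix
    (``.xml``/``.sbml`` -> SBML, otherwise native) unless given."""
    path = Path(path)
    if format is None:
        format = "sbml" if path.suffix.lower() in {".xml", ".sbml"} else "native"
    if format == "sbml":
        return read_sbml(path)
    if format == "native":
        return read_native(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# native tab-separated format
# ---------------------------------------------------------------------------

_SIDE_TERM = re.compile(r"^\s*(?:(\d+)\s+)?(\S+)\s*$")


def parse_side(text: str) -> dict[str, int]:
    """Parse a reaction side like ``2 A + B`` into {species: stoich}."""
    text = text.strip()
    if not text or text in {"-", "0", "∅"}:
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        m = _SIDE_TERM.match(term)
        if not m:
            raise NetworkError(f"cannot parse reaction side term {term!r}")
        n = int(m.group(1) or 1)
        sid = m.group(2)
        out[sid] = out.get(sid, 0) + n
    return out


def format_side(side: dict[str, int]) -> str:
    if not side:
        return "-"
    return " + ".join(f"{n} {s}" if n != 1 else s for s, n in side.items())


def read_native(path) -> ReactionNetwork:
    species: list[Species] = []
    reactions: list[Reaction] = []
    parameters: dict[str, float] = {}
    section = None
    header: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        s = line.strip()
        if s.startswith("[") and s.endswith("]"):
            section = s[1:-1].lower()
            header = []
            continue
        cells = line.split("\t")
        if section == "species":
            if not header:
                header = [c.strip().lower() for c in cells]
                continue
            row = dict(zip(header, cells))
            comp = row.get("compartment", "-").strip()
            species.append(Species(
                id=row["id"].strip(),
                name=row.get("name", "").strip(),
                initial_concentration=float(row.get("initial", 0) or 0),
                compartment=None if comp in {"", "-"} else comp))
        elif section == "parameters":
            parameters[cells[0].strip()] = float(cells[1])
        elif section == "reactions":
            if not header:
                header = [c.strip().lower() for c in cells]
                continue
            reactions.append(dict(zip(header, cells)))
        else:
            raise NetworkError(f"line outside a known section: {line!r}")
    syms = {p: sp.Symbol(p) for p in parameters}
    built = []
    for row in reactions:
        built.append(Reaction(
            id=row["id"].strip(),
            reactants=parse_side(row["reactants"]),
            products=parse_side(row["products"]),
            k_forward=sp.sympify(row["k_forward"], locals=syms),
            k_backward=sp.sympify(row.get("k_backward", "0") or "0",
                                  locals=syms)))
    return ReactionNetwork(species, built, parameters)


def write_native(net: ReactionNetwork, path) -> None:
    lines = ["# crnred network (tab-separated)", "[species]",
             "id\tname\tinitial\tcompartment"]
    for s in net.species:
        lines.append("\t".join([s.id, s.name,
                                repr(s.initial_concentration),
                                s.compartment or "-"]))
    lines.append("[parameters]")
    for k, v in net.parameters.items():
        lines.append(f"{k}\t{v!r}")
    lines += ["[reactions]", "id\treactants\tproducts\tk_forward\tk_backward"]
    for r in net.reactions:
        lines.append("\t".join([r.id, format_side(r.reactants),
                                format_side(r.products),
                                str(r.k_forward), str(r.k_backward)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SBML (mass-action subset)
# ---------------------------------------------------------------------------

def _mass_action_constants(expr: sp.Expr, reactants: dict[str, int],
                           products: dict[str, int], rid: str,
                           species_syms: set[sp.Symbol]):
    """Split a kinetic-law expression into (k_forward, k_backward).

    The law must expand to  kf * prod c^alpha  [- kb * prod c^beta]  with
    parameter-only coefficients; anything else raises.
    """
    fwd = sp.Integer(1)
    for s, n in reactants.items():
        fwd *= sp.Symbol(s) ** n
    rev = sp.Integer(1)
    for s, n in products.items():
        rev *= sp.Symbol(s) ** n
    poly = sp.expand(expr)
    terms = poly.args if poly.is_Add else (poly,)
    kf = sp.Integer(0)
    kb = sp.Integer(0)
    for t in terms:
        coeff_f = sp.simplify(t / fwd)
        if not coeff_f.free_symbols & species_syms:
            kf += coeff_f
            continue
        coeff_b = sp.simplify(t / rev)
        if not coeff_b.free_symbols & species_syms:
            kb += -coeff_b
            continue
        raise UnsupportedKineticsError(
            f"reaction {rid}: kinetic law term {t} is not mass action")
    if kb == 0:
        return sp.simplify(kf), sp.Integer(0)
    return sp.simplify(kf), sp.simplify(kb)


def read_sbml(path) -> ReactionNetwork:
    import libsbml
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise NetworkError(
            f"SBML parse error: {doc.getError(0).getMessage()}")
    model = doc.getModel()
    if model is None:
        raise NetworkError("SBML file contains no model")

    comp_size = {c.getId(): (c.getSize() if c.isSetSize() else 1.0)
                 for c in model.getListOfCompartments()}
    species = []
    for s in model.getListOfSpecies():
        init = s.getInitialConcentration() if s.isSetInitialConcentration() \
            else s.getInitialAmount() if s.isSetInitialAmount() else 0.0
        if init != init:  # NaN
            init = 0.0
        species.append(Species(s.getId(), s.getName() or s.getId(),
                               max(init, 0.0), s.getCompartment() or None))
    species_syms = {sp.Symbol(s.id) for s in species}

    parameters: dict[str, float] = {}
    for p in model.getListOfParameters():
        if p.getValue() > 0:
            parameters[p.getId()] = p.getValue()

    reactions = []
    for rx in model.getListOfReactions():
        rid = rx.getId()
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        for ref in rx.getListOfReactants():
            st = ref.getStoichiometry()
            if st != int(st):
                raise UnsupportedKineticsError(
                    f"reaction {rid}: non-integer stoichiometry")
            reactants[ref.getSpecies()] = reactants.get(ref.getSpecies(), 0) \
                + int(st)
        for ref in rx.getListOfProducts():
            st = ref.getStoichiometry()
            if st != int(st):
                raise UnsupportedKineticsError(
                    f"reaction {rid}: non-integer stoichiometry")
            products[ref.getSpecies()] = products.get(ref.getSpecies(), 0) \
                + int(st)
        kl = rx.getKineticLaw()
        if kl is None:
            raise UnsupportedKineticsError(f"reaction {rid}: no kinetic law")
        local = {}
        for p in kl.getListOfParameters():
            pid = f"{rid}_{p.getId()}"
            local[p.getId()] = pid
            if p.getValue() > 0:
                parameters[pid] = p.getValue()
        formula = libsbml.formulaToString(kl.getMath())
        # explicit symbol table: species ids like S or E must not resolve
        # to sympy singletons
        local_syms = {s.id: sp.Symbol(s.id) for s in species}
        local_syms.update({p: sp.Symbol(p) for p in parameters})
        local_syms.update({old: sp.Symbol(new) for old, new in local.items()})
        local_syms.update({c: sp.Float(v) for c, v in comp_size.items()})
        try:
            expr = sp.sympify(formula, locals=local_syms, rational=False)
        except (sp.SympifyError, TypeError, SyntaxError) as exc:
            raise UnsupportedKineticsError(
                f"reaction {rid}: cannot parse kinetic law: {exc}") from exc
        kf, kb = _mass_action_constants(expr, reactants, products, rid,
                                        species_syms)
        reactions.append(Reaction(rid, reactants, products, kf, kb))

    used = set()
    for r in reactions:
        used |= {str(s) for s in r.k_forward.free_symbols}
        used |= {str(s) for s in r.k_backward.free_symbols}
    missing = used - set(parameters)
    if missing:
        raise NetworkError(f"undeclared/non-positive SBML parameters: "
                           f"{sorted(missing)}")
    parameters = {k: v for k, v in parameters.items() if k in used}
    return ReactionNetwork(species, reactions, parameters)


def write_sbml(net: ReactionNetwork, path,
               rate_expressions: dict[str, sp.Expr] | None = None) -> None:
    """Write a network (or a reduced network with explicit rate
    expressions keyed by reaction id) as SBML Level 3."""
    import libsbml
    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    for s in net.species:
        sb = model.createSpecies()
        sb.setId(s.id)
        sb.setName(s.name)
        sb.setCompartment("cell")
        sb.setInitialConcentration(s.initial_concentration)
        sb.setHasOnlySubstanceUnits(False)
        sb.setBoundaryCondition(False)
        sb.setConstant(False)
    for k, v in net.parameters.items():
        pb = model.createParameter()
        pb.setId(k)
        pb.setValue(v)
        pb.setConstant(True)
    for r in net.reactions:
        rb = model.createReaction()
        rb.setId(r.id)
        rb.setReversible(bool(r.reversible))
        for sid, n in r.reactants.items():
            ref = rb.createReactant()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        for sid, n in r.products.items():
            ref = rb.createProduct()
            ref.setSpecies(sid)
            ref.setStoichiometry(float(n))
            ref.setConstant(True)
        if rate_expressions and r.id in rate_expressions:
            law = str(rate_expressions[r.id])
        else:
            fwd = "*".join([str(r.k_forward)] +
                           [f"{s}^{n}" if n > 1 else s
                            for s, n in r.reactants.items()])
            law = fwd
            if r.reversible:
                rev = "*".join([str(r.k_backward)] +
                               [f"{s}^{n}" if n > 1 else s
                                for s, n in r.products.items()])
                law = f"{fwd} - {rev}"
        kl = rb.createKineticLaw()
        ast = libsbml.parseFormula(law.replace("**", "^"))
        if ast is None:
            raise NetworkError(f"cannot encode rate for {r.id}: {law}")
        kl.setMath(ast)
    libsbml.writeSBMLToFile(doc, str(path))
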