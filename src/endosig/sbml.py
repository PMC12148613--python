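"""SBML Level 3 Version 2 export / import of the expanded ODE model.

The exporter writes the flat reaction network (one SBML reaction per
compiled reaction column, reversible rules as two irreversible reactions)
with explicit MathML kinetic laws, species initial concentrations,
compartments and global parameters.  The importer reads the same flat-ODE
subset back -- species, parameters and kinetic-law math -- and compiles a
generic ODE right-hand side from it, which makes export -> import ->
simulate a genuine round trip through the file format rather than a
memory copy.  ``validate_sbml`` performs structural validation of the
document (id uniqueness, reference resolution, MathML well-formedness,
required attributes).

Inhibitor scalings are a simulation-time construct and are not exported.
"""

from __future__ import annotations

import numpy as np
from lxml import etree

from .compile import CompiledModel
from .network import ModelError

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


# ---------------------------------------------------------------------------
# expression AST:  ("ci", name) | ("cn", value) | (op, *args)
# ---------------------------------------------------------------------------

def _rule_expression(rule, direction, species_clamp=None):
    """Kinetic-law AST for one compiled reaction column."""
    ci = lambda n: ("ci", n)
    if direction < 0:
        terms = [ci(rule.reverse_key)] + [ci(s) for s in rule.products]
        return ("*",) + tuple(terms)
    law = rule.rate_law
    k = ci(rule.rate_constant_key)
    if law == "mass_action":
        expr = ("*", k) + tuple(ci(s) for s in rule.reactants)
        if len(rule.reactants) == 0:
            expr = k
    elif law == "michaelis_menten":
        S = ci(rule.reactants[0])
        mm = ("/", S, ("+", ci(rule.km_key), S))
        if rule.modifier is not None:
            expr = ("*", k, ci(rule.modifier), mm)
        else:
            expr = ("*", k, mm)
    else:  # saturating_hill
        M = ci(rule.modifier)
        sat = ("/", M, ("+", ci(rule.km_key), M))
        if rule.reactants:
            expr = ("*", k, ci(rule.reactants[0]), sat)
        else:
            expr = ("*", k, sat)
    for g in rule.gates:
        G = ci(g.species)
        if g.sign > 0:
            gate = ("/", G, ("+", ci(g.k_key), G))
        else:
            gate = ("/", ci(g.k_key), ("+", ci(g.k_key), G))
        expr = ("*", expr, gate)
    return expr


_OPS = {"*": "times", "/": "divide", "+": "plus", "-": "minus", "^": "power"}
_OPS_INV = {v: k for k, v in _OPS.items()}


def _ast_to_mathml(expr, parent):
    if expr[0] == "ci":
        el = etree.SubElement(parent, f"{{{MATHML_NS}}}ci")
        el.text = f" {expr[1]} "
        return
    if expr[0] == "cn":
        el = etree.SubElement(parent, f"{{{MATHML_NS}}}cn")
        el.text = f" {expr[1]!r} "
        return
    apply_el = etree.SubElement(parent, f"{{{MATHML_NS}}}apply")
    etree.SubElement(apply_el, f"{{{MATHML_NS}}}{_OPS[expr[0]]}")
    for arg in expr[1:]:
        _ast_to_mathml(arg, apply_el)


def _mathml_to_ast(el):
    tag = etree.QName(el).localname
    if tag == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise ModelError("math element must hold one expression")
        return _mathml_to_ast(children[0])
    if tag == "ci":
        return ("ci", el.text.strip())
    if tag == "cn":
        return ("cn", float(el.text.strip()))
    if tag == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        if op not in _OPS_INV:
            raise ModelError(f"unsupported MathML operator {op!r}")
        return (_OPS_INV[op],) + tuple(_mathml_to_ast(c) for c in children[1:])
    raise ModelError(f"unsupported MathML element {tag!r}")


def _eval_ast(expr, env):
    op = expr[0]
    if op == "ci":
        return env[expr[1]]
    if op == "cn":
        return expr[1]
    args = [_eval_ast(a, env) for a in expr[1:]]
    if op == "*":
        out = 1.0
        for a in args:
            out *= a
        return out
    if op == "+":
        return sum(args)
    if op == "/":
        return args[0] / args[1]
    if op == "-":
        return args[0] - args[1] if len(args) == 2 else -args[0]
    if op == "^":
        return args[0] ** args[1]
    raise ModelError(f"unknown op {op!r}")


def _ast_identifiers(expr, out):
    if expr[0] == "ci":
        out.add(expr[1])
    elif expr[0] != "cn":
        for a in expr[1:]:
            _ast_identifiers(a, out)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_sbml(compiled: CompiledModel, path=None) -> bytes:
    """Serialise the compiled model as an SBML L3V2 document.

    Returns the XML bytes; writes them to ``path`` when given.
    """
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap,
                         level="3", version="2")
    model_el = etree.SubElement(root, f"{{{SBML_NS}}}model",
                                id="endosig_network",
                                timeUnits="dimensionless")
    # compartments
    comps = sorted({s.compartment for s in compiled.model.species})
    lc = etree.SubElement(model_el, f"{{{SBML_NS}}}listOfCompartments")
    for c in comps:
        etree.SubElement(lc, f"{{{SBML_NS}}}compartment", id=c,
                         spatialDimensions="3", size="1", constant="true")
    # species
    y0 = compiled.initial_state()
    ls = etree.SubElement(model_el, f"{{{SBML_NS}}}listOfSpecies")
    for i, s in enumerate(compiled.model.species):
        etree.SubElement(
            ls, f"{{{SBML_NS}}}species", id=s.name, compartment=s.compartment,
            initialConcentration=repr(float(y0[i])),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false")
    # parameters
    lp = etree.SubElement(model_el, f"{{{SBML_NS}}}listOfParameters")
    for k in compiled.params.keys():
        etree.SubElement(lp, f"{{{SBML_NS}}}parameter", id=k,
                         value=repr(float(compiled.params[k])),
                         constant="true")
    # reactions
    lr = etree.SubElement(model_el, f"{{{SBML_NS}}}listOfReactions")
    for j, (rule, direction) in enumerate(compiled.reactions):
        rid = rule.name if direction > 0 else f"{rule.name}__rev"
        r_el = etree.SubElement(lr, f"{{{SBML_NS}}}reaction", id=rid,
                                reversible="false")
        st = rule.stoichiometry()
        if direction < 0:
            st = {s: -c for s, c in st.items()}
        reactants = {s: -c for s, c in st.items() if c < 0}
        products = {s: c for s, c in st.items() if c > 0}
        if reactants:
            el = etree.SubElement(r_el, f"{{{SBML_NS}}}listOfReactants")
            for s, c in sorted(reactants.items()):
                etree.SubElement(el, f"{{{SBML_NS}}}speciesReference",
                                 species=s, stoichiometry=repr(float(c)),
                                 constant="true")
        if products:
            el = etree.SubElement(r_el, f"{{{SBML_NS}}}listOfProducts")
            for s, c in sorted(products.items()):
                etree.SubElement(el, f"{{{SBML_NS}}}speciesReference",
                                 species=s, stoichiometry=repr(float(c)),
                                 constant="true")
        expr = _rule_expression(rule, direction)
        ids = set()
        _ast_identifiers(expr, ids)
        mods = sorted(i for i in ids
                      if i in compiled._sindex and i not in st)
        if mods:
            el = etree.SubElement(r_el, f"{{{SBML_NS}}}listOfModifiers")
            for s in mods:
                etree.SubElement(el, f"{{{SBML_NS}}}modifierSpeciesReference",
                                 species=s)
        kl = etree.SubElement(r_el, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        _ast_to_mathml(expr, math)
    doc = etree.tostring(root, pretty_print=True,
                         xml_declaration=True, encoding="UTF-8")
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(doc)
    return doc


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

class ImportedModel:
    """Flat ODE model reconstructed from an SBML document."""

    def __init__(self, species_names, y0, parameters, reactions):
        self.species_names = list(species_names)
        self.y0 = np.asarray(y0, float)
        self.parameters = dict(parameters)
        #: list of (stoich dict, kinetic AST)
        self.reactions = reactions
        self._sidx = {n: i for i, n in enumerate(self.species_names)}

    def rhs(self):
        sidx = self._sidx
        pars = self.parameters

        def f(t, y):
            env = dict(pars)
            for n, i in sidx.items():
                env[n] = y[i] if y[i] > 0.0 else 0.0
            dy = np.zeros(len(y))
            for st, expr in self.reactions:
                v = _eval_ast(expr, env)
                for s, c in st.items():
                    dy[sidx[s]] += c * v
            return dy

        return f

    def simulate(self, t_span, y0=None, t_eval=None, rtol=1e-8, atol=1e-10):
        from scipy.integrate import solve_ivp
        sol = solve_ivp(self.rhs(), t_span,
                        self.y0 if y0 is None else np.asarray(y0, float),
                        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise ModelError(f"imported-model integration failed: {sol.message}")
        return sol.t, sol.y.T


def import_sbml(source) -> ImportedModel:
    """Parse an SBML L3 flat-ODE document (bytes or path)."""
    if isinstance(source, (bytes, bytearray)):
        root = etree.fromstring(bytes(source))
    else:
        root = etree.parse(str(source)).getroot()
    model_el = root.find(f"{{{SBML_NS}}}model")
    if model_el is None:
        raise ModelError("no <model> element")
    species, y0 = [], []
    for el in model_el.findall(f".//{{{SBML_NS}}}species"):
        species.append(el.get("id"))
        y0.append(float(el.get("initialConcentration", "0")))
    params = {el.get("id"): float(el.get("value", "0"))
              for el in model_el.findall(f".//{{{SBML_NS}}}parameter")}
    reactions = []
    for r_el in model_el.findall(f".//{{{SBML_NS}}}reaction"):
        st = {}
        for el in r_el.findall(f"{{{SBML_NS}}}listOfReactants/"
                               f"{{{SBML_NS}}}speciesReference"):
            st[el.get("species")] = st.get(el.get("species"), 0.0) - float(
                el.get("stoichiometry", "1"))
        for el in r_el.findall(f"{{{SBML_NS}}}listOfProducts/"
                               f"{{{SBML_NS}}}speciesReference"):
            st[el.get("species")] = st.get(el.get("species"), 0.0) + float(
                el.get("stoichiometry", "1"))
        math = r_el.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        if math is None:
            raise ModelError(f"reaction {r_el.get('id')}: no kinetic law")
        reactions.append((st, _mathml_to_ast(math)))
    return ImportedModel(species, y0, params, reactions)


def validate_sbml(source) -> list:
    """Structural validation; returns a list of error strings (empty when
    the document is valid)."""
    errors = []
    try:
        if isinstance(source, (bytes, bytearray)):
            root = etree.fromstring(bytes(source))
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as e:
        return [f"XML parse error: {e}"]
    if etree.QName(root).namespace != SBML_NS:
        errors.append("root element not in the SBML L3V2 namespace")
    if root.get("level") != "3":
        errors.append("document is not SBML Level 3")
    model_el = root.find(f"{{{SBML_NS}}}model")
    if model_el is None:
        return errors + ["missing <model>"]
    comp_ids = [el.get("id") for el in
                model_el.findall(f".//{{{SBML_NS}}}compartment")]
    sp_ids = [el.get("id") for el in
              model_el.findall(f".//{{{SBML_NS}}}species")]
    par_ids = [el.get("id") for el in
               model_el.findall(f".//{{{SBML_NS}}}parameter")]
    for name, ids in (("compartment", comp_ids), ("species", sp_ids),
                      ("parameter", par_ids)):
        if len(ids) != len(set(ids)):
            errors.append(f"duplicate {name} ids")
        if any(i is None for i in ids):
            errors.append(f"{name} without id")
    known = set(sp_ids) | set(par_ids)
    for el in model_el.findall(f".//{{{SBML_NS}}}species"):
        if el.get("compartment") not in comp_ids:
            errors.append(f"species {el.get('id')}: unknown compartment")
        for attr in ("hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if el.get(attr) is None:
                errors.append(f"species {el.get('id')}: missing {attr}")
    for r_el in model_el.findall(f".//{{{SBML_NS}}}reaction"):
        rid = r_el.get("id")
        if rid is None:
            errors.append("reaction without id")
            continue
        for el in r_el.findall(f".//{{{SBML_NS}}}speciesReference"):
            if el.get("species") not in sp_ids:
                errors.append(f"reaction {rid}: unknown species reference "
                              f"{el.get('species')!r}")
            try:
                float(el.get("stoichiometry", "1"))
            except ValueError:
                errors.append(f"reaction {rid}: non-numeric stoichiometry")
        math = r_el.find(f"{{{SBML_NS}}}kineticLaw/{{{MATHML_NS}}}math")
        if math is None:
            errors.append(f"reaction {rid}: missing kinetic law math")
            continue
        try:
            ast = _mathml_to_ast(math)
            ids = set()
            _ast_identifiers(ast, ids)
            for i in ids - known:
                errors.append(f"reaction {rid}: undefined identifier {i!r}")
        except ModelError as e:
            errors.append(f"reaction {rid}: {e}")
    return errors
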