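"""SBML Level 3 Version 1 export of sampled models.

Every metabolite becomes a species (fixed metabolites as constant boundary
species), every enzyme intermediate a species with its sampled reference
abundance, and every elementary step a reversible reaction with a mass-action
kinetic law  kf·Π(reactants) − kr·Π(products)  carried in local parameters.
Concentrations are in scaled (reference-normalized) units; the sampled
reference concentration of each metabolite (mol/L) is recorded in a package
annotation so the scaling is recoverable.  The elementary step whose net rate
equals a network reaction's rate is annotated as that reaction's flux step.

Import is supported only for documents this package wrote (enough for
round-trip checks and re-evaluation of reference rates); the writer is
canonical, so export→import→export is byte-idempotent.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model_io import FLOAT_FMT, NetworkModel
from .param_sampling import KineticParameterization

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://kinensemble.dev/sbml-annotations"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _sanitize(name: str, taken: dict[str, str]) -> str:
    if name in taken:
        return taken[name]
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "x_" + sid
    base, n = sid, 1
    while sid in taken.values():
        n += 1
        sid = f"{base}_{n}"
    taken[name] = sid
    return sid


@dataclass
class SBMLSpecies:
    id: str
    initial: float
    boundary: bool
    constant: bool
    conc_ref: float | None = None   # mol/L scaling annotation


@dataclass
class SBMLReaction:
    id: str
    reactants: list[tuple[str, float]]
    products: list[tuple[str, float]]
    params: dict[str, float]        # local parameters, e.g. kf/kr or k/r_ref
    reversible: bool = True
    flux_step_of: str | None = None  # network reaction whose net rate this step carries
    part_of: str | None = None       # owning network reaction (all elementary steps)


@dataclass
class SBMLDoc:
    model_id: str
    species: list[SBMLSpecies] = field(default_factory=list)
    reactions: list[SBMLReaction] = field(default_factory=list)


class SBMLError(ValueError):
    pass


# ---------------------------------------------------------------------------
# document construction
# ---------------------------------------------------------------------------

def build_document(model: NetworkModel, params: KineticParameterization,
                   model_id: str = "kinensemble_model") -> SBMLDoc:
    doc = SBMLDoc(model_id=model_id)
    ids: dict[str, str] = {}

    for i, met in enumerate(model.metabolites):
        doc.species.append(SBMLSpecies(
            id=_sanitize(met.id, ids), initial=1.0,
            boundary=not met.balanced, constant=not met.balanced,
            conc_ref=float(params.thermo.conc_ref[i])))

    for eid, unit in params.enzyme_units.items():
        for s, e0 in zip(unit.pattern.states, unit.e_ref):
            doc.species.append(SBMLSpecies(
                id=_sanitize(f"enz {eid} {s}", ids), initial=float(e0),
                boundary=False, constant=False))

    for eid, unit in params.enzyme_units.items():
        pat = unit.pattern
        flux_steps = {idx: rid for rid, idx in pat.flux_step.items()}
        step_owner: dict[int, str] = {}
        for rid, cyc in pat.cycles.items():
            for idx in cyc:
                step_owner[idx] = rid
        for i, st in enumerate(pat.steps):
            owner = st.reaction or step_owner.get(i)
            reactants = [(ids[f"enz {eid} {st.source}"], 1.0)]
            reactants += [(ids[m], 1.0) for m in st.substrates]
            products = [(ids[f"enz {eid} {st.target}"], 1.0)]
            products += [(ids[m], 1.0) for m in st.products]
            doc.reactions.append(SBMLReaction(
                id=_sanitize(f"step {eid} {i}", ids),
                reactants=reactants, products=products,
                params={"kf": float(unit.k_plus[i]), "kr": float(unit.k_minus[i])},
                flux_step_of=flux_steps.get(i), part_of=owner))

    for rid, fn in params.mass_action.items():
        doc.reactions.append(SBMLReaction(
            id=_sanitize(rid, ids),
            reactants=[(ids[m], c) for m, c in fn.substrates],
            products=[(ids[m], c) for m, c in fn.products],
            params={"k": fn.k, "r_ref": fn.r_ref},
            reversible=not fn.one_sided, flux_step_of=rid, part_of=rid))
    return doc


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _math_mass_action(rxn: SBMLReaction) -> ET.Element:
    """MathML for kf·Π(reactants) − kr·Π(products) (or the one-sided forms)."""
    def ci(name):
        el = ET.Element(f"{{{MATHML_NS}}}ci")
        el.text = f" {name} "
        return el

    def cn(x):
        el = ET.Element(f"{{{MATHML_NS}}}cn")
        el.text = f" {_fmt(x)} "
        return el

    def product(kname, species):
        terms = [ci(kname)] + [
            _power(ci(s), c, cn) for s, c in species
        ]
        if len(terms) == 1:
            return terms[0]
        ap = ET.Element(f"{{{MATHML_NS}}}apply")
        ap.append(ET.Element(f"{{{MATHML_NS}}}times"))
        for t in terms:
            ap.append(t)
        return ap

    def _power(base, c, cn):
        if abs(c - 1.0) < 1e-12:
            return base
        ap = ET.Element(f"{{{MATHML_NS}}}apply")
        ap.append(ET.Element(f"{{{MATHML_NS}}}power"))
        ap.append(base)
        ap.append(cn(c))
        return ap

    math = ET.Element(f"{{{MATHML_NS}}}math")
    if "kf" in rxn.params:
        fwd = product("kf", rxn.reactants)
        rev = product("kr", rxn.products)
    else:
        fwd = product("k", rxn.reactants)
        if not rxn.reversible:
            math.append(fwd)
            return math
        rev = product("k", rxn.products)
        # reversible mass action: k*(prod(subs) - r_ref*prod(prods))
        rr = ET.Element(f"{{{MATHML_NS}}}apply")
        rr.append(ET.Element(f"{{{MATHML_NS}}}times"))
        rr.append(ci("r_ref"))
        rr.append(rev)
        rev = rr
    minus = ET.Element(f"{{{MATHML_NS}}}apply")
    minus.append(ET.Element(f"{{{MATHML_NS}}}minus"))
    minus.append(fwd)
    minus.append(rev)
    math.append(minus)
    return math


def write_document(doc: SBMLDoc, path: str | Path) -> Path:
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    ET.register_namespace("kin", ANNOT_NS)
    root = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    mdl = ET.SubElement(root, f"{{{SBML_NS}}}model", {"id": doc.model_id})

    comps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{SBML_NS}}}compartment",
                  {"id": "cell", "size": "1", "constant": "true",
                   "spatialDimensions": "3"})

    sps = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for sp in doc.species:
        attrs = {
            "id": sp.id, "compartment": "cell",
            "initialConcentration": _fmt(sp.initial),
            "boundaryCondition": "true" if sp.boundary else "false",
            "constant": "true" if sp.constant else "false",
            "hasOnlySubstanceUnits": "false",
        }
        el = ET.SubElement(sps, f"{{{SBML_NS}}}species", attrs)
        if sp.conc_ref is not None:
            ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
            ET.SubElement(ann, f"{{{ANNOT_NS}}}referenceConcentration",
                          {"value": _fmt(sp.conc_ref), "units": "mole_per_litre"})

    rxns = ET.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for r in doc.reactions:
        el = ET.SubElement(rxns, f"{{{SBML_NS}}}reaction",
                           {"id": r.id, "reversible": "true" if r.reversible else "false",
                            "fast": "false"})
        if r.flux_step_of or r.part_of:
            ann = ET.SubElement(el, f"{{{SBML_NS}}}annotation")
            attrs = {}
            if r.part_of:
                attrs["reaction"] = r.part_of
            if r.flux_step_of:
                attrs["fluxStepOf"] = r.flux_step_of
            ET.SubElement(ann, f"{{{ANNOT_NS}}}networkReaction", attrs)
        if r.reactants:
            lor = ET.SubElement(el, f"{{{SBML_NS}}}listOfReactants")
            for s, c in r.reactants:
                ET.SubElement(lor, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": _fmt(c), "constant": "true"})
        if r.products:
            lop = ET.SubElement(el, f"{{{SBML_NS}}}listOfProducts")
            for s, c in r.products:
                ET.SubElement(lop, f"{{{SBML_NS}}}speciesReference",
                              {"species": s, "stoichiometry": _fmt(c), "constant": "true"})
        kl = ET.SubElement(el, f"{{{SBML_NS}}}kineticLaw")
        kl.append(_math_mass_action(r))
        lp = ET.SubElement(kl, f"{{{SBML_NS}}}listOfLocalParameters")
        for name in sorted(r.params):
            ET.SubElement(lp, f"{{{SBML_NS}}}localParameter",
                          {"id": name, "value": _fmt(r.params[name])})

    ET.indent(root, space="  ")
    path = Path(path)
    tree = ET.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="UTF-8")
    return path


def export_sbml(model: NetworkModel, params: KineticParameterization,
                path: str | Path, model_id: str = "kinensemble_model") -> Path:
    """Export one sampled model as SBML L3V1 (see module docstring)."""
    doc = build_document(model, params, model_id)
    issues = check_consistency(doc)
    if issues:
        raise SBMLError("generated document failed consistency checks: " + "; ".join(issues))
    return write_document(doc, path)


# ---------------------------------------------------------------------------
# reading / evaluation / consistency
# ---------------------------------------------------------------------------

def import_sbml(path: str | Path) -> SBMLDoc:
    """Read a document previously written by this package."""
    tree = ET.parse(path)
    root = tree.getroot()
    if root.tag != f"{{{SBML_NS}}}sbml":
        raise SBMLError(f"{path}: not an SBML L3 document")
    mdl = root.find(f"{{{SBML_NS}}}model")
    doc = SBMLDoc(model_id=mdl.get("id"))
    for sp in mdl.iter(f"{{{SBML_NS}}}species"):
        conc_ref = None
        ann = sp.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}referenceConcentration")
        if ann is not None:
            conc_ref = float(ann.get("value"))
        doc.species.append(SBMLSpecies(
            id=sp.get("id"), initial=float(sp.get("initialConcentration")),
            boundary=sp.get("boundaryCondition") == "true",
            constant=sp.get("constant") == "true", conc_ref=conc_ref))
    for r in mdl.iter(f"{{{SBML_NS}}}reaction"):
        reactants = [(sr.get("species"), float(sr.get("stoichiometry")))
                     for sr in r.findall(f"{{{SBML_NS}}}listOfReactants/{{{SBML_NS}}}speciesReference")]
        products = [(sr.get("species"), float(sr.get("stoichiometry")))
                    for sr in r.findall(f"{{{SBML_NS}}}listOfProducts/{{{SBML_NS}}}speciesReference")]
        params = {lp.get("id"): float(lp.get("value"))
                  for lp in r.findall(f"{{{SBML_NS}}}kineticLaw/{{{SBML_NS}}}listOfLocalParameters/"
                                      f"{{{SBML_NS}}}localParameter")}
        ann = r.find(f"{{{SBML_NS}}}annotation/{{{ANNOT_NS}}}networkReaction")
        doc.reactions.append(SBMLReaction(
            id=r.get("id"), reactants=reactants, products=products, params=params,
            reversible=r.get("reversible") == "true",
            flux_step_of=ann.get("fluxStepOf") if ann is not None else None,
            part_of=ann.get("reaction") if ann is not None else None))
    return doc


def evaluate_reference_rates(doc: SBMLDoc) -> dict[str, float]:
    """Net rates of the network reactions at the document's initial state.

    Initial concentrations are the reference point (scaled metabolites 1,
    enzyme states at e_ref), so this reproduces the anchored fluxes.
    """
    conc = {sp.id: sp.initial for sp in doc.species}
    out: dict[str, float] = {}
    for r in doc.reactions:
        if r.flux_step_of is None:
            continue
        fwd = float(np.prod([conc[s] ** c for s, c in r.reactants])) if r.reactants else 1.0
        rev = float(np.prod([conc[s] ** c for s, c in r.products])) if r.products else 1.0
        if "kf" in r.params:
            rate = r.params["kf"] * fwd - r.params["kr"] * rev
        elif not r.reversible:
            rate = r.params["k"] * fwd
        else:
            rate = r.params["k"] * (fwd - r.params["r_ref"] * rev)
        out[r.flux_step_of] = rate
    return out


def check_consistency(doc: SBMLDoc) -> list[str]:
    """Structural consistency checks (unique ids, resolvable references,
    finite values, parameterized kinetic laws)."""
    issues = []
    sids = [sp.id for sp in doc.species]
    if len(set(sids)) != len(sids):
        issues.append("duplicate species ids")
    rids = [r.id for r in doc.reactions]
    if len(set(rids)) != len(rids):
        issues.append("duplicate reaction ids")
    if set(rids) & set(sids):
        issues.append("reaction ids collide with species ids")
    known = set(sids)
    for r in doc.reactions:
        for s, c in r.reactants + r.products:
            if s not in known:
                issues.append(f"reaction {r.id}: unknown species {s}")
            if not (c > 0):
                issues.append(f"reaction {r.id}: non-positive stoichiometry for {s}")
        if not r.params:
            issues.append(f"reaction {r.id}: kinetic law has no parameters")
        for name, val in r.params.items():
            if not np.isfinite(val):
                issues.append(f"reaction {r.id}: parameter {name} is not finite")
    for sp in doc.species:
        if not np.isfinite(sp.initial) or sp.initial < 0:
            issues.append(f"species {sp.id}: invalid initial concentration")
    return issues
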