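"""SBML read/write.

Models are written as SBML Level 3 Version 1 with the FBC v2 package (flux
bounds, gene-product associations, biomass objective).  On reading, both FBC
constructs and the legacy conventions still common in older Level 2 files
are accepted: ``GENE_ASSOCIATION`` notes, kinetic-law ``LOWER_BOUND`` /
``UPPER_BOUND`` parameters, and boundary-condition species.

Stoichiometric coefficients travel as SBML doubles; they are re-read through
their shortest decimal representation, so any coefficient with a finite
decimal expansion (1/2, 0.1, 3, ...) round-trips exactly into the internal
rational representation.
"""

from __future__ import annotations

import logging
import re
from fractions import Fraction
from pathlib import Path

import libsbml

from .gpr import GprTree, parse_gpr
from .model import (DEFAULT_FLUX_BOUND, Compartment, Gene, Metabolite, Model,
                    Reaction, Reversibility)

log = logging.getLogger(__name__)

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")


class SBMLFormatError(ValueError):
    pass


def _sid(raw: str) -> str:
    s = _SID_BAD.sub("_", raw)
    if not s or s[0].isdigit():
        s = "x" + s
    return s


def _notes(obj) -> dict[str, str]:
    """Parse ``key: value`` lines out of an SBML notes element."""
    out: dict[str, str] = {}
    if not obj.isSetNotes():
        return out
    text = obj.getNotesString()
    for m in re.finditer(r"<p>\s*([^<:]+?)\s*:\s*(.*?)\s*</p>", text, re.S):
        out[m.group(1).strip()] = m.group(2).strip()
    return out


def _set_notes(obj, pairs: dict[str, str]) -> None:
    if not pairs:
        return
    body = "".join(f"<p>{k}: {v}</p>" for k, v in pairs.items())
    obj.setNotes(
        f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>')


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int] | None:
    if not text:
        return None
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            return None
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    return out if pos == len(text) and out else None


def format_formula(formula: dict[str, int]) -> str:
    return "".join(
        f"{el}{n if n != 1 else ''}" for el, n in sorted(formula.items()))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def read_sbml(path: str | Path) -> Model:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise SBMLFormatError(
                    f"{path}: {err.getCategoryAsString()} error at line "
                    f"{err.getLine()}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLFormatError(f"{path}: file contains no model element")

    tag = sbml_model.getId() or Path(path).stem
    model = Model(tag=tag)
    fbc = sbml_model.getPlugin("fbc")

    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        notes = _notes(comp)
        model.add_compartment(Compartment(
            id=comp.getId(),
            name=comp.getName() or "",
            is_extracellular=notes.get("extracellular", "") == "true",
        ))

    boundary_species: set[str] = set()
    species_key: dict[str, tuple[str, str]] = {}
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        notes = _notes(sp)
        mid = sp.getName() or sp.getId()
        comp = sp.getCompartment()
        if sp.getBoundaryCondition():
            boundary_species.add(sp.getId())
            continue
        formula = None
        sp_fbc = sp.getPlugin("fbc")
        if sp_fbc is not None and sp_fbc.isSetChemicalFormula():
            formula = parse_formula(sp_fbc.getChemicalFormula())
        if formula is None and "formula" in notes:
            formula = parse_formula(notes["formula"])
        sources = set(filter(None, notes.get("sources", "").split(";")))
        species_key[sp.getId()] = (mid, comp)
        model.add_metabolite(Metabolite(
            id=mid, compartment=comp, formula=formula,
            sources=sources or {tag}))

    gene_label: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            label = gp.getLabel() or gp.getId()
            gene_label[gp.getId()] = label
            model.genes.setdefault(label, Gene(label, sources={tag}))

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }

    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        notes = _notes(rxn)
        rid = rxn.getName() or rxn.getId()
        stoich: dict[tuple[str, str], Fraction] = {}

        def _add(ref, sign: int) -> None:
            sp_id = ref.getSpecies()
            if sp_id in boundary_species:
                return
            if sp_id not in species_key:
                raise SBMLFormatError(
                    f"{path}: reaction {rid} references unknown species "
                    f"{sp_id}")
            key = species_key[sp_id]
            coeff = Fraction(repr(ref.getStoichiometry()))
            stoich[key] = stoich.get(key, Fraction(0)) + sign * coeff

        for j in range(rxn.getNumReactants()):
            _add(rxn.getReactant(j), -1)
        for j in range(rxn.getNumProducts()):
            _add(rxn.getProduct(j), +1)
        stoich = {k: c for k, c in stoich.items() if c != 0}
        if not stoich:
            log.warning("%s: reaction %s has empty stoichiometry; skipped",
                        path, rid)
            continue

        lb = ub = None
        r_fbc = rxn.getPlugin("fbc")
        if r_fbc is not None and r_fbc.isSetLowerFluxBound():
            lb = params.get(r_fbc.getLowerFluxBound())
            ub = params.get(r_fbc.getUpperFluxBound())
        if lb is None and rxn.isSetKineticLaw():
            kl = rxn.getKineticLaw()
            lp = kl.getParameter("LOWER_BOUND")
            up = kl.getParameter("UPPER_BOUND")
            lb = lp.getValue() if lp is not None else None
            ub = up.getValue() if up is not None else None

        if "reversibility" in notes:
            reversibility = Reversibility(notes["reversibility"])
        elif lb is not None and ub is not None:
            if lb < 0 < ub:
                reversibility = Reversibility.REVERSIBLE
            elif ub <= 0:
                reversibility = Reversibility.BACKWARD
            else:
                reversibility = Reversibility.FORWARD
        else:
            reversibility = (Reversibility.REVERSIBLE if rxn.getReversible()
                             else Reversibility.FORWARD)
        if lb is None or ub is None:
            log.info("%s: reaction %s has no flux bounds; defaults applied",
                     path, rid)

        gpr = GprTree.empty()
        if r_fbc is not None and r_fbc.isSetGeneProductAssociation():
            gpr = _read_fbc_gpr(
                r_fbc.getGeneProductAssociation().getAssociation(), gene_label)
        elif "GENE_ASSOCIATION" in notes:
            gpr = parse_gpr(notes["GENE_ASSOCIATION"])

        sources = set(filter(None, notes.get("sources", "").split(";")))
        model.add_reaction(Reaction(
            id=rid, stoich=stoich, reversibility=reversibility,
            lb=lb, ub=ub, gpr=gpr, sources=sources or {tag}))

    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(0)
        for i in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(i)
            target = sbml_model.getReaction(fo.getReaction())
            if target is not None:
                model.biomass_reaction_id = target.getName() or target.getId()

    model.validate()
    return model


def _read_fbc_gpr(assoc, gene_label: dict[str, str]) -> GprTree:
    if assoc is None:
        return GprTree.empty()
    if assoc.isGeneProductRef():
        ref = assoc.getGeneProduct()
        return GprTree.leaf(gene_label.get(ref, ref))
    parts = [_read_fbc_gpr(assoc.getAssociation(i), gene_label)
             for i in range(assoc.getNumAssociations())]
    if assoc.isFbcAnd():
        return GprTree.all_of(parts)
    return GprTree.any_of(parts)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_sbml(model: Model, path: str | Path) -> None:
    doc_ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(doc_ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid(model.tag))
    sbml_model.setName(model.tag)
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(False)

    for cid in sorted(model.compartments):
        comp = model.compartments[cid]
        c = sbml_model.createCompartment()
        c.setId(_sid(cid))
        c.setName(comp.name or cid)
        c.setConstant(True)
        if comp.is_extracellular:
            _set_notes(c, {"extracellular": "true"})

    species_id: dict[tuple[str, str], str] = {}
    for key in sorted(model.metabolites):
        met = model.metabolites[key]
        sp = sbml_model.createSpecies()
        sid = f"M_{_sid(met.id)}__{_sid(met.compartment)}"
        species_id[key] = sid
        sp.setId(sid)
        sp.setName(met.id)
        sp.setCompartment(_sid(met.compartment))
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.formula is not None:
            sp.getPlugin("fbc").setChemicalFormula(format_formula(met.formula))
        if met.sources:
            _set_notes(sp, {"sources": ";".join(sorted(met.sources))})

    gene_id: dict[str, str] = {}
    for g in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gid = "G_" + _sid(g)
        gene_id[g] = gid
        gp.setId(gid)
        gp.setLabel(g)

    bound_param: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_param:
            pid = f"fb_{len(bound_param)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        r = sbml_model.createReaction()
        r.setId("R_" + _sid(rid))
        r.setName(rid)
        r.setReversible(rxn.reversibility is Reversibility.REVERSIBLE)
        r.setFast(False)
        for key in sorted(rxn.stoich):
            coeff = rxn.stoich[key]
            if coeff < 0:
                ref = r.createReactant()
                ref.setStoichiometry(float(-coeff))
            else:
                ref = r.createProduct()
                ref.setStoichiometry(float(coeff))
            ref.setSpecies(species_id[key])
            ref.setConstant(True)
        r_fbc = r.getPlugin("fbc")
        r_fbc.setLowerFluxBound(_param_for(float(rxn.lb)))
        r_fbc.setUpperFluxBound(_param_for(float(rxn.ub)))
        if not rxn.gpr.is_empty():
            gpa = r_fbc.createGeneProductAssociation()
            gpa.setAssociation(_fbc_gpr_string(rxn.gpr, gene_id), True)
        notes = {"reversibility": rxn.reversibility.value}
        if rxn.sources:
            notes["sources"] = ";".join(sorted(rxn.sources))
        _set_notes(r, notes)

    if model.biomass_reaction_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fbc.setActiveObjectiveId("obj")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + _sid(model.biomass_reaction_id))
        fo.setCoefficient(1.0)

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise IOError(f"could not write SBML to {path}")


def write_sbml_string(model: Model) -> str:
    import tempfile, os
    with tempfile.NamedTemporaryFile("r", suffix=".xml", delete=False) as fh:
        tmp = fh.name
    try:
        write_sbml(model, tmp)
        with open(tmp) as fh:
            return fh.read()
    finally:
        os.unlink(tmp)


def _fbc_gpr_string(tree: GprTree, gene_id: dict[str, str]) -> str:
    if tree.op == "gene":
        return gene_id[tree.gene]
    sep = " and " if tree.op == "and" else " or "
    parts = []
    for c in tree.children:
        s = _fbc_gpr_string(c, gene_id)
        parts.append(s if c.op == "gene" else "(" + s + ")")
    return sep.join(sorted(parts))
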