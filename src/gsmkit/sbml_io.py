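"""SBML level 3 import/export (versions 1 and 2, fbc v2 package).

Bounds are emitted as shared ``fbc`` flux-bound parameters, GPR rules as
``fbc:geneProductAssociation`` trees, and gene locus tags as gene-product
labels (SBML SIds cannot carry arbitrary characters, so ids are sanitised
with the conventional ``R_``/``M_``/``G_`` prefixes and the original
identifiers are kept in names/labels).
"""

from __future__ import annotations

import logging
import re
from typing import Optional

import libsbml

from .gpr import And, GeneRef, GPRNode, Or
from .model import Gene, IntegrityError, MetabolicModel, Metabolite, Reaction

logger = logging.getLogger(__name__)

_SID_BAD = re.compile(r"[^A-Za-z0-9_]")
_SID_ESCAPE = re.compile(r"__(\d+)__")


class SBMLParseError(ValueError):
    """Malformed SBML input."""


def _sid(prefix: str, raw: str) -> str:
    # cobra-style reversible escaping: "-" -> "__45__" etc.
    clean = _SID_BAD.sub(lambda m: f"__{ord(m.group(0))}__", raw)
    if not clean or (not prefix and clean[0].isdigit()):
        clean = "_" + clean
    return prefix + clean


def _strip(prefix: str, sid: str) -> str:
    if sid.startswith(prefix):
        sid = sid[len(prefix):]
    return _SID_ESCAPE.sub(lambda m: chr(int(m.group(1))), sid)


def write_sbml(model: MetabolicModel, path: str, level_version: str = "3.1") -> None:
    """Serialise a model to SBML; ``level_version`` is ``"3.1"`` or ``"3.2"``."""
    if level_version not in {"3.1", "3.2"}:
        raise ValueError(f"unsupported SBML level/version {level_version!r}")
    problems = model.validate()
    if problems:
        raise IntegrityError(
            "refusing to write model with integrity violations:\n  " + "\n  ".join(problems)
        )
    version = int(level_version.split(".")[1])
    ns = libsbml.SBMLNamespaces(3, version, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(_sid("", model.id) or "model")
    sbml_model.setName(model.id)
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    for comp_id in sorted(model.compartments):
        comp = sbml_model.createCompartment()
        comp.setId(_sid("", comp_id))
        comp.setName(comp_id)
        comp.setConstant(True)

    for met in sorted(model.metabolites.values(), key=lambda m: m.id):
        sp = sbml_model.createSpecies()
        sp.setId(_sid("M_", met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sid("", met.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp_fbc = sp.getPlugin("fbc")
        if met.formula is not None:
            sp_fbc.setChemicalFormula(met.formula)
        if met.charge is not None:
            sp_fbc.setCharge(int(met.charge))

    for gene in sorted(model.genes.values(), key=lambda g: g.locus_tag):
        gp = fbc.createGeneProduct()
        gp.setId(_sid("G_", gene.locus_tag))
        gp.setLabel(gene.locus_tag)
        if gene.product:
            gp.setName(gene.product)

    bound_params = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = _sid("", f"bnd_{len(bound_params)}")
            par = sbml_model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        sr = sbml_model.createReaction()
        sr.setId(_sid("R_", rxn.id))
        sr.setName(rxn.name or rxn.id)
        sr.setReversible(rxn.reversible)
        if version == 1:
            sr.setFast(False)
        for met_id, coeff in sorted(rxn.stoichiometry.items()):
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(_sid("M_", met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        r_fbc = sr.getPlugin("fbc")
        r_fbc.setLowerFluxBound(bound_param(rxn.lower_bound))
        r_fbc.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr is not None:
            gpa = r_fbc.createGeneProductAssociation()
            _fill_association(rxn.gpr, gpa)
        if rxn.pathway:
            sr.setSBOTerm(176)  # biochemical reaction; pathway kept in notes
            sr.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                        f"<p>pathway: {rxn.pathway}</p></body>")

    if model.objective is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        flux_obj = obj.createFluxObjective()
        flux_obj.setReaction(_sid("R_", model.objective))
        flux_obj.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")


def _fill_association(node: GPRNode, container) -> None:
    """Recursively mirror a GPR tree into an fbc association container."""
    if isinstance(node, GeneRef):
        ref = container.createGeneProductRef()
        ref.setGeneProduct(_sid("G_", node.gene))
        return
    assoc = container.createAnd() if isinstance(node, And) else container.createOr()
    for child in node.children:
        _fill_association(child, assoc)


def _association_to_gpr(assoc) -> GPRNode:
    if isinstance(assoc, libsbml.GeneProductRef):
        return GeneRef(_strip("G_", assoc.getGeneProduct()))
    children = tuple(
        _association_to_gpr(assoc.getAssociation(i)) for i in range(assoc.getNumAssociations())
    )
    return And(children) if isinstance(assoc, libsbml.FbcAnd) else Or(children)


def read_sbml(path: str) -> MetabolicModel:
    """Parse an SBML L3V1/L3V2 document (with optional fbc constructs)."""
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(
            f"{path}: SBML parse error at line {err.getLine()}: {err.getMessage()}"
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"{path}: document contains no model")
    if doc.getLevel() != 3:
        raise SBMLParseError(f"{path}: only SBML level 3 is supported, got level {doc.getLevel()}")

    model = MetabolicModel(id=sbml_model.getName() or sbml_model.getId() or "model")
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        model.compartments.add(comp.getName() or comp.getId())

    comp_names = {
        sbml_model.getCompartment(i).getId():
            sbml_model.getCompartment(i).getName() or sbml_model.getCompartment(i).getId()
        for i in range(sbml_model.getNumCompartments())
    }

    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        sp_fbc = sp.getPlugin("fbc")
        formula = None
        charge = None
        if sp_fbc is not None:
            if sp_fbc.isSetChemicalFormula():
                formula = sp_fbc.getChemicalFormula()
            if sp_fbc.isSetCharge():
                charge = sp_fbc.getCharge()
        model.add_metabolite(
            Metabolite(
                id=_strip("M_", sp.getId()),
                name=sp.getName() or "",
                compartment=comp_names.get(sp.getCompartment(), sp.getCompartment()),
                formula=formula,
                charge=charge,
            )
        )

    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            tag = gp.getLabel() or _strip("G_", gp.getId())
            model.add_gene(Gene(locus_tag=tag, product=gp.getName() or None))

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    gp_labels = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gp_labels[_strip("G_", gp.getId())] = gp.getLabel() or _strip("G_", gp.getId())

    dangling: set = set()
    for i in range(sbml_model.getNumReactions()):
        sr = sbml_model.getReaction(i)
        stoich = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            met = _strip("M_", ref.getSpecies())
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        missing = [m for m in stoich if m not in model.metabolites]
        if missing:
            raise IntegrityError(
                f"reaction {sr.getId()}: dangling species references {sorted(missing)}"
            )
        r_fbc = sr.getPlugin("fbc")
        lb, ub = (-1000.0, 1000.0) if sr.getReversible() else (0.0, 1000.0)
        gpr = None
        if r_fbc is not None:
            if r_fbc.isSetLowerFluxBound():
                lb = params.get(r_fbc.getLowerFluxBound(), lb)
            if r_fbc.isSetUpperFluxBound():
                ub = params.get(r_fbc.getUpperFluxBound(), ub)
            gpa = r_fbc.getGeneProductAssociation()
            if gpa is not None and gpa.getAssociation() is not None:
                gpr = _association_to_gpr(gpa.getAssociation())
                gpr = _relabel(gpr, gp_labels)
                dangling |= gpr.genes() - set(model.genes)
        pathway = None
        if sr.isSetNotes():
            m = re.search(r"pathway:\s*([^<]+)", sr.getNotesString())
            if m:
                pathway = m.group(1).strip()
        rxn = Reaction(
            id=_strip("R_", sr.getId()),
            name=sr.getName() or "",
            stoichiometry=stoich,
            reversible=sr.getReversible(),
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            pathway=pathway,
        )
        if dangling:
            continue  # error raised below with the full list
        model.add_reaction(rxn)

    if dangling:
        raise IntegrityError(
            f"{path}: GPR rules cite undeclared genes: {sorted(dangling)}"
        )

    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getObjective(0)
        if obj.getNumFluxObjectives() > 0:
            model.objective = _strip("R_", obj.getFluxObjective(0).getReaction())

    return model


def _relabel(node: GPRNode, labels: dict) -> GPRNode:
    if isinstance(node, GeneRef):
        return GeneRef(labels.get(node.gene, node.gene))
    cls = And if isinstance(node, And) else Or
    return cls(tuple(_relabel(c, labels) for c in node.children))


__all__ = ["read_sbml", "write_sbml", "SBMLParseError"]
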