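"""SBML readers and an FBC-v2 writer (via libsbml).

Two dialects are read:

* **sbml-fbc** — SBML Level 3 with the Flux Balance Constraints (FBC v2)
  package: flux bounds as constant parameters, GPRs as
  ``GeneProductAssociation`` trees, objective from the active FBC
  objective.

* **sbml-cobra** — the legacy COBRA dialect (SBML Level 2): bounds as
  ``LOWER_BOUND`` / ``UPPER_BOUND`` kinetic-law parameters and GPRs in
  ``GENE_ASSOCIATION`` notes.

Writing always emits FBC v2.  The biomass registry (composition id ->
reaction id) is carried in the model notes so that multi-biomass models
round-trip.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional

import libsbml

from .gpr import EMPTY_GPR, GPRExpression, parse_gpr
from .model import (
    DEFAULT_LOWER_BOUND,
    DEFAULT_UPPER_BOUND,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = ["read_sbml", "write_sbml", "SBMLFormatError"]


class SBMLFormatError(ValueError):
    """Raised when an SBML document cannot be parsed, with line context."""


_REGISTRY_RE = re.compile(r"biomass_registry:\s*([^<\n]+)")
_GA_RE = re.compile(r"GENE[ _]ASSOCIATION:\s*([^<\n]+)", re.IGNORECASE)


def _check_document(doc: libsbml.SBMLDocument, path: str) -> None:
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLFormatError(
            f"{path}: SBML parse error at line {err.getLine()}: "
            f"{err.getMessage().strip()}"
        )


def _association_to_gpr(
    assoc: libsbml.FbcAssociation, label_of: Dict[str, str]
) -> GPRExpression:
    if isinstance(assoc, libsbml.GeneProductRef):
        gp_id = assoc.getGeneProduct()
        return GPRExpression(kind="gene", gene=label_of.get(gp_id, gp_id))
    if isinstance(assoc, (libsbml.FbcAnd, libsbml.FbcOr)):
        kind = "and" if isinstance(assoc, libsbml.FbcAnd) else "or"
        children = [
            _association_to_gpr(assoc.getAssociation(i), label_of)
            for i in range(assoc.getNumAssociations())
        ]
        if len(children) == 1:
            return children[0]
        return GPRExpression(kind=kind, children=tuple(children))
    raise SBMLFormatError(f"unsupported FBC association element {assoc!r}")


def _notes_text(element) -> str:
    return element.getNotesString() if element.isSetNotes() else ""


def _registry_from_notes(model: libsbml.Model) -> Dict[str, str]:
    m = _REGISTRY_RE.search(_notes_text(model))
    registry: Dict[str, str] = {}
    if m:
        for entry in m.group(1).split(";"):
            entry = entry.strip()
            if entry and "=" in entry:
                comp_id, rxn_id = entry.split("=", 1)
                registry[comp_id.strip()] = rxn_id.strip()
    return registry


def read_sbml(path: str | Path, dialect: str = "auto") -> MetabolicModel:
    """Read an SBML model; ``dialect`` in {auto, sbml-fbc, sbml-cobra}."""
    path = str(path)
    doc = libsbml.readSBMLFromFile(path)
    _check_document(doc, path)
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLFormatError(f"{path}: document contains no <model> element")
    mplug = sbml_model.getPlugin("fbc")
    if dialect == "auto":
        dialect = "sbml-fbc" if mplug is not None else "sbml-cobra"
    if dialect == "sbml-fbc" and mplug is None:
        raise SBMLFormatError(f"{path}: no FBC package information present")

    compartments = [
        sbml_model.getCompartment(i).getId()
        for i in range(sbml_model.getNumCompartments())
    ] or ["c"]

    metabolites: List[Metabolite] = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue  # boundary species are implicit sinks, not pool members
        kegg = chebi = None
        notes = _notes_text(sp)
        mk = re.search(r"KEGG[ _]?ID:\s*([^<\s]+)", notes, re.IGNORECASE)
        mc = re.search(r"CHEBI[ _]?ID:\s*([^<\s]+)", notes, re.IGNORECASE)
        kegg = mk.group(1) if mk else None
        chebi = mc.group(1) if mc else None
        metabolites.append(Metabolite(
            id=sp.getId(),
            name=sp.getName() or sp.getId(),
            compartment=sp.getCompartment() or compartments[0],
            kegg_id=kegg,
            chebi_id=chebi,
        ))
    met_ids = {m.id for m in metabolites}

    label_of: Dict[str, str] = {}
    objective_id: Optional[str] = None
    if mplug is not None:
        for i in range(mplug.getNumGeneProducts()):
            gp = mplug.getGeneProduct(i)
            label_of[gp.getId()] = gp.getLabel() or gp.getId()
        active = mplug.getActiveObjective()
        if active is not None and active.getNumFluxObjectives() > 0:
            objective_id = active.getFluxObjective(0).getReaction()

    reactions: List[Reaction] = []
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: Dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = (
                    stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
                )
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            if ref.getSpecies() in met_ids:
                stoich[ref.getSpecies()] = (
                    stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
                )
        if not stoich:
            continue  # pure-boundary reaction collapsed to nothing

        reversible = rx.getReversible()
        lb = DEFAULT_LOWER_BOUND if reversible else 0.0
        ub = DEFAULT_UPPER_BOUND
        gpr = EMPTY_GPR
        rplug = rx.getPlugin("fbc")
        if dialect == "sbml-fbc" and rplug is not None:
            for which, setter in (("getLowerFluxBound", "lb"),
                                  ("getUpperFluxBound", "ub")):
                pid = getattr(rplug, which)()
                if pid:
                    param = sbml_model.getParameter(pid)
                    if param is None:
                        raise SBMLFormatError(
                            f"{path}: reaction {rx.getId()!r} references "
                            f"missing bound parameter {pid!r}"
                        )
                    if setter == "lb":
                        lb = param.getValue()
                    else:
                        ub = param.getValue()
            if rplug.isSetGeneProductAssociation():
                gpa = rplug.getGeneProductAssociation()
                gpr = _association_to_gpr(gpa.getAssociation(), label_of)
        else:
            kl = rx.getKineticLaw()
            if kl is not None:
                for j in range(kl.getNumParameters()):
                    p = kl.getParameter(j)
                    if p.getId() == "LOWER_BOUND":
                        lb = p.getValue()
                    elif p.getId() == "UPPER_BOUND":
                        ub = p.getValue()
                    elif p.getId() == "OBJECTIVE_COEFFICIENT" and p.getValue():
                        objective_id = rx.getId()
            ga = _GA_RE.search(_notes_text(rx))
            if ga:
                gpr = parse_gpr(ga.group(1).strip())

        reactions.append(Reaction(
            id=rx.getId(),
            name=rx.getName() or rx.getId(),
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gpr=gpr,
            is_exchange=len(stoich) == 1,
        ))

    model = MetabolicModel(
        model_id=sbml_model.getId() or Path(path).stem,
        compartments=compartments,
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
    )
    for comp_id, rxn_id in _registry_from_notes(sbml_model).items():
        if rxn_id in model.reactions:
            model.register_biomass(comp_id, rxn_id)
    return model


def _sanitize(sid: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", sid)
    if not re.match(r"[A-Za-z_]", out):
        out = "_" + out
    return out


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 + FBC v2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(_sanitize(model.id))
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)

    for comp_id in model.compartments:
        comp = sm.createCompartment()
        comp.setId(_sanitize(comp_id))
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId(_sanitize(met.id))
        sp.setName(met.name or met.id)
        sp.setCompartment(_sanitize(met.compartment))
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        notes = []
        if met.kegg_id:
            notes.append(f"KEGG_ID: {met.kegg_id}")
        if met.chebi_id:
            notes.append(f"CHEBI_ID: {met.chebi_id}")
        if notes:
            body = "".join(f"<p>{t}</p>" for t in notes)
            sp.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )

    bound_params: Dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"bnd_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    genes_seen: set[str] = set()

    def ensure_gene(gene: str) -> str:
        gid = "G_" + _sanitize(gene)
        if gene not in genes_seen:
            gp = mplug.createGeneProduct()
            gp.setId(gid)
            gp.setLabel(gene)
            genes_seen.add(gene)
        return gid

    def gpr_infix(expr: GPRExpression) -> str:
        if expr.kind == "gene":
            return ensure_gene(expr.gene)
        sep = f" {expr.kind} "
        parts = []
        for child in expr.children:
            text = gpr_infix(child)
            if child.kind in ("and", "or"):
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    for rxn in model.reactions.values():
        rx = sm.createReaction()
        rx.setId(_sanitize(rxn.id))
        rx.setName(rxn.name or rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(_sanitize(met_id))
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if not rxn.gpr.is_empty:
            gpa = rplug.createGeneProductAssociation()
            # match pre-created gene products by SId; never auto-create
            gpa.setAssociation(gpr_infix(rxn.gpr), True, False)

    if model.objective_id:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(_sanitize(model.objective_id))
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    if model.biomass_registry:
        entries = "; ".join(
            f"{cid}={rid}" for cid, rid in sorted(model.biomass_registry.items())
        )
        sm.setNotes(
            '<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>biomass_registry: {entries}</p></body>"
        )

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML to {path}")
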