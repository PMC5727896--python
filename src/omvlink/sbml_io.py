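"""SBML Level 3 + FBC v2 reading and writing via python-libsbml.

Identifier convention follows the community standard: metabolite and
reaction ids gain ``M_``/``R_`` prefixes on write and lose them on read,
so ids that start with a digit (e.g. ``13zdst``) survive the round trip.
Package-specific attributes (KEGG id, super-pathway, organism tag,
origin tag) travel as key-value pairs in SBML notes, the same mechanism
cobrapy uses, so the files stay readable by other COBRA tools.
"""

from __future__ import annotations

import math
from typing import Optional

import libsbml

from .model_core import (
    INF_CAP,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)


class SBMLError(ValueError):
    """Malformed or unsupported SBML input."""


_NOTE_KEYS = ("kegg_id", "super_pathway", "organism", "origin_tag", "annotation")


def _notes_xml(pairs: dict[str, str]) -> str:
    body = "".join(
        f"<p>{k}: {v}</p>" for k, v in pairs.items() if v not in (None, "")
    )
    return (
        '<notes><body xmlns="http://www.w3.org/1999/xhtml">'
        f"{body}</body></notes>"
    )


def _parse_notes(sbase) -> dict[str, str]:
    out: dict[str, str] = {}
    if not sbase.isSetNotes():
        return out
    notes = sbase.getNotesString()
    for chunk in notes.split("<p>")[1:]:
        text = chunk.split("</p>")[0].strip()
        if ":" in text:
            k, v = text.split(":", 1)
            out[k.strip()] = v.strip()
    return out


def _clip(mid: str, prefix: str) -> str:
    return mid[len(prefix):] if mid.startswith(prefix) else mid


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Serialize a model as SBML L3V1 with FBC v2 bounds and objective."""
    doc = libsbml.SBMLDocument(libsbml.SBMLNamespaces(3, 1, "fbc", 2))
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id or "model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)

    for comp_id in sorted(model.compartments):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for met in model.metabolites.values():
        sp = sm.createSpecies()
        sp.setId("M_" + met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)
        notes = {
            "base_id": met.base_id,
            "kegg_id": met.kegg_id,
            "super_pathway": met.super_pathway,
            "organism": met.organism,
        }
        sp.setNotes(_notes_xml({k: v for k, v in notes.items() if v}))

    # shared flux-bound parameters keyed by value
    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sm.createParameter()
            par.setId(pid)
            par.setValue(value)
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions.values():
        sr = sm.createReaction()
        sr.setId("R_" + rxn.id)
        sr.setFast(False)
        sr.setReversible(rxn.lower_bound < 0)
        for mid, coeff in rxn.stoichiometry.items():
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies("M_" + mid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        notes = {"origin_tag": rxn.origin_tag, "organism": rxn.organism}
        if rxn.annotation:
            notes["annotation"] = ";".join(rxn.annotation)
        sr.setNotes(_notes_xml({k: v for k, v in notes.items() if v}))

    if model.objective_reaction_id is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + model.objective_reaction_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: str, require_objective: bool = True) -> MetabolicModel:
    """Parse an SBML L3+FBC file into a :class:`MetabolicModel`.

    Raises :class:`SBMLError` naming the offending element on malformed
    input, on missing flux bounds, and (unless ``require_objective`` is
    False) when the file declares no active objective.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLError(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise SBMLError(f"{path}: no <model> element")

    comps = [sm.getCompartment(i).getId() for i in range(sm.getNumCompartments())]
    model = MetabolicModel(sm.getId() or "model", comps or ["c"])

    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        mid = _clip(sp.getId(), "M_")
        notes = _parse_notes(sp)
        comp = sp.getCompartment()
        base = notes.get("base_id") or _strip_compartment(mid, comp)
        formula = None
        fplug = sp.getPlugin("fbc")
        if fplug is not None and fplug.isSetChemicalFormula():
            formula = fplug.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                id=mid,
                base_id=base,
                compartment=comp,
                name=sp.getName() or mid,
                kegg_id=notes.get("kegg_id"),
                super_pathway=notes.get("super_pathway"),
                formula=formula,
                organism=notes.get("organism"),
            )
        )

    params = {
        sm.getParameter(i).getId(): sm.getParameter(i).getValue()
        for i in range(sm.getNumParameters())
    }

    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        rid = _clip(sr.getId(), "R_")
        rplug = sr.getPlugin("fbc")
        if (
            rplug is None
            or not rplug.isSetLowerFluxBound()
            or not rplug.isSetUpperFluxBound()
        ):
            raise SBMLError(f"{path}: reaction {sr.getId()} lacks FBC flux bounds")
        lb = params.get(rplug.getLowerFluxBound())
        ub = params.get(rplug.getUpperFluxBound())
        if lb is None or ub is None or math.isnan(lb) or math.isnan(ub):
            raise SBMLError(f"{path}: reaction {sr.getId()} has unresolved bounds")
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = _clip(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = _clip(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        notes = _parse_notes(sr)
        ann = notes.get("annotation")
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                origin_tag=notes.get("origin_tag", "original"),
                annotation=ann.split(";") if ann else [],
                organism=notes.get("organism"),
            )
        )

    objective: Optional[str] = None
    mplug = sm.getPlugin("fbc")
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            objective = _clip(active.getFluxObjective(0).getReaction(), "R_")
    if objective is None:
        if require_objective:
            raise SBMLError(f"{path}: no objective declared in FBC package")
    else:
        model.set_objective(objective)

    model.validate()
    return model


def _strip_compartment(mid: str, comp: str) -> str:
    suffix = "_" + comp
    return mid[: -len(suffix)] if mid.endswith(suffix) else mid
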