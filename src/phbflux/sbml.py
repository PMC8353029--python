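"""SBML import/export for stoichiometric models.

Writes SBML Level 3 Version 1 with the flux-balance-constraints (FBC v2)
package; reads both Level 3 (FBC bounds) and Level 2 documents (bounds
recovered from the kinetic-law ``LOWER_BOUND`` / ``UPPER_BOUND``
parameter convention).  Identifiers are preserved verbatim.
"""

from __future__ import annotations

import logging
import math

import libsbml

from .model import Metabolite, ModelError, Reaction, StoichiometricModel

logger = logging.getLogger(__name__)

_DEFAULT_LB = -1000.0
_DEFAULT_UB = 1000.0


class SBMLError(ModelError):
    """Raised when an SBML document cannot be parsed into a model."""


def _check(value, message: str):
    if value is None:
        raise SBMLError(f"libsbml call failed: {message}")
    if isinstance(value, int) and value != libsbml.LIBSBML_OPERATION_SUCCESS:
        raise SBMLError(f"libsbml error {value}: {message}")
    return value


def write_sbml(model: StoichiometricModel, path: str) -> None:
    """Serialise ``model`` to SBML L3V1 + FBC v2 at ``path``.

    Raises
    ------
    ModelError
        If the model has no reactions.
    OSError
        If the path cannot be written.
    """
    if not model.reactions:
        raise ModelError("cannot write a model with no reactions")
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    compartments = sorted({m.compartment for m in model.metabolites}) or ["c"]
    for comp in compartments:
        c = sbml_model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for met in model.metabolites:
        s = sbml_model.createSpecies()
        s.setId(met.id)
        s.setName(met.name or met.id)
        s.setCompartment(met.compartment)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        s.setConstant(False)
        splug = s.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))

    # Flux-bound parameters (deduplicated by value)
    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setConstant(True)
            p.setValue(value if math.isfinite(value) else
                       (libsbml.util_PosInf() if value > 0 else libsbml.util_NegInf()))
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name or rxn.id)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            if coef < 0:
                sr = r.createReactant()
            elif coef > 0:
                sr = r.createProduct()
            else:
                continue
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))
        if rxn.gene_associated:
            r.setSBOTerm("SBO:0000176")  # biochemical reaction
        elif rxn.is_exchange:
            r.setSBOTerm("SBO:0000627")  # exchange
        else:
            r.setSBOTerm("SBO:0000631")  # pseudo-reaction
        if rxn.subsystem:
            r.setNotes(f"<body xmlns='http://www.w3.org/1999/xhtml'>"
                       f"<p>SUBSYSTEM: {rxn.subsystem}</p></body>")

    if model.objective:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        mplug.setActiveObjectiveId("obj")
        for rxn_id, coef in model.objective.items():
            fo = obj.createFluxObjective()
            fo.setReaction(rxn_id)
            fo.setCoefficient(coef)

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise OSError(f"could not write SBML to {path}")


def _bound_from_value(value: float) -> float:
    if value == libsbml.util_PosInf():
        return math.inf
    if value == libsbml.util_NegInf():
        return -math.inf
    return value


def _l3_bounds(sbml_model, r) -> tuple[float | None, float | None]:
    rplug = r.getPlugin("fbc")
    lb = ub = None
    if rplug is not None:
        lb_id = rplug.getLowerFluxBound()
        ub_id = rplug.getUpperFluxBound()
        if lb_id:
            p = sbml_model.getParameter(lb_id)
            if p is None:
                raise SBMLError(
                    f"reaction {r.getId()!r}: undeclared flux bound {lb_id!r}")
            lb = _bound_from_value(p.getValue())
        if ub_id:
            p = sbml_model.getParameter(ub_id)
            if p is None:
                raise SBMLError(
                    f"reaction {r.getId()!r}: undeclared flux bound {ub_id!r}")
            ub = _bound_from_value(p.getValue())
    return lb, ub


def _l2_bounds(r) -> tuple[float | None, float | None]:
    # COBRA-style Level 2 convention: kinetic-law parameters
    lb = ub = None
    kl = r.getKineticLaw()
    if kl is not None:
        for i in range(kl.getNumParameters()):
            p = kl.getParameter(i)
            if p.getId() == "LOWER_BOUND":
                lb = _bound_from_value(p.getValue())
            elif p.getId() == "UPPER_BOUND":
                ub = _bound_from_value(p.getValue())
    return lb, ub


def read_sbml(path: str) -> StoichiometricModel:
    """Parse an SBML file (Level 2 or Level 3 + FBC) into a model.

    Missing flux bounds default to (-1000, 1000) for reversible
    reactions and (0, 1000) otherwise, with a logged warning.

    Raises
    ------
    SBMLError
        On malformed documents, naming the offending element.
    FileNotFoundError
        If the file does not exist.
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLError(f"malformed SBML: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLError("malformed SBML: document contains no <model> element")

    metabolites = []
    species_ids = set()
    for i in range(sbml_model.getNumSpecies()):
        s = sbml_model.getSpecies(i)
        formula = None
        charge = None
        splug = s.getPlugin("fbc")
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        elif s.isSetCharge():  # Level 2 charge attribute
            charge = s.getCharge()
        metabolites.append(
            Metabolite(
                id=s.getId(),
                name=s.getName() or s.getId(),
                compartment=s.getCompartment() or "c",
                formula=formula or None,
                charge=charge,
            )
        )
        species_ids.add(s.getId())

    level = sbml_model.getLevel()
    reactions = []
    for i in range(sbml_model.getNumReactions()):
        r = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(r.getNumReactants()):
            sr = r.getReactant(j)
            if sr.getSpecies() not in species_ids:
                raise SBMLError(
                    f"reaction {r.getId()!r} references undeclared "
                    f"species {sr.getSpecies()!r}")
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(r.getNumProducts()):
            sr = r.getProduct(j)
            if sr.getSpecies() not in species_ids:
                raise SBMLError(
                    f"reaction {r.getId()!r} references undeclared "
                    f"species {sr.getSpecies()!r}")
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        if level >= 3:
            lb, ub = _l3_bounds(sbml_model, r)
        else:
            lb, ub = _l2_bounds(r)
        if lb is None or ub is None:
            reversible = r.getReversible()
            if lb is None:
                lb = _DEFAULT_LB if reversible else 0.0
            if ub is None:
                ub = _DEFAULT_UB
            logger.warning(
                "reaction %s: missing flux bounds, defaulting to (%g, %g)",
                r.getId(), lb, ub)
        sbo = r.getSBOTermID() if r.isSetSBOTerm() else ""
        gene_associated = sbo not in ("SBO:0000627", "SBO:0000628",
                                      "SBO:0000631", "SBO:0000632")
        if sbo == "":
            rplug = r.getPlugin("fbc")
            has_gpr = rplug is not None and rplug.getGeneProductAssociation() is not None
            gene_associated = has_gpr or len(stoich) > 1
        subsystem = None
        if r.isSetNotes():
            notes = r.getNotesString()
            if "SUBSYSTEM:" in notes:
                subsystem = notes.split("SUBSYSTEM:")[1].split("<")[0].strip()
        reactions.append(
            Reaction(
                id=r.getId(),
                name=r.getName() or r.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gene_associated=gene_associated,
                subsystem=subsystem,
            )
        )

    objective: dict[str, float] = {}
    mplug = sbml_model.getPlugin("fbc")
    if mplug is not None:
        obj = mplug.getActiveObjective()
        if obj is not None:
            for j in range(obj.getNumFluxObjectives()):
                fo = obj.getFluxObjective(j)
                objective[fo.getReaction()] = fo.getCoefficient()

    try:
        return StoichiometricModel(
            metabolites=metabolites,
            reactions=reactions,
            objective=objective,
            id=sbml_model.getId() or "model",
        )
    except ModelError as exc:
        raise SBMLError(str(exc)) from exc
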