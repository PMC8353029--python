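"""Stoichiometric model data structures and the built-in core model.

The core model is a desk-scale network of central carbon metabolism of
*Paracoccus denitrificans* growing on succinate: succinate uptake, the
oxidative TCA cycle, the anaplerotic exit through malic enzyme and
pyruvate dehydrogenase, the three-step PHB branch (beta-ketothiolase,
acetoacetyl-CoA reductase, PHB synthase), lumped respiration, a
maintenance ATP drain and a biomass pseudo-reaction.  It is small enough
to reason about by hand yet rich enough to reproduce the flux structure
of the two physiological phases (growth-arrested PHB accumulation and
exponential growth).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: Effective molar mass of the PHB monomer inside the polymer chain
#: (3-hydroxybutyrate minus the water lost on polymerisation), g/mol.
PHB_MONOMER_MOLAR_MASS = 96.0

#: Non-growth ATP demand of succinate-grown P. denitrificans,
#: mmol ATP g-DW^-1 h^-1 (intercept of the Pirt relation).
DEFAULT_MAINTENANCE_ATP = 7.5

_ELEMENTS = ("C", "H", "O", "N", "P", "S")
_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ModelError(ValueError):
    """Raised for structurally invalid models or parameters."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string such as ``C4H4O4`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"malformed formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ModelError(f"malformed formula {formula!r}")
    if any(v < 0 for v in counts.values()):
        raise ModelError(f"negative element count in {formula!r}")
    return counts


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    Parameters
    ----------
    id:
        Short unique identifier, e.g. ``succ_c``.
    name:
        Human-readable name.
    compartment:
        ``"c"`` (cytosol) or ``"e"`` (extracellular).
    formula:
        Elemental composition as a string (``C4H4O4``), optional.
    charge:
        Formal charge, optional.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def element_counts(self) -> dict[str, int] | None:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  Bounds are in mmol g-DW^-1 h^-1 except for
    the biomass pseudo-reaction, whose flux is the specific growth rate
    in h^-1.  ``gene_associated`` is True for enzyme-catalysed steps and
    False for exchanges, sinks, maintenance and the biomass reaction.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_associated: bool = True
    subsystem: str | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r} has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction touching exactly one metabolite."""
        return len(self.stoichiometry) == 1

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class StoichiometricModel:
    """A constraint-based metabolic model.

    ``objective`` maps reaction ids to linear objective coefficients
    (by convention maximised; the FBA layer accepts either sense).
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    id: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        if len(set(met_ids)) != len(met_ids):
            raise ModelError("duplicate metabolite ids")
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelError("duplicate reaction ids")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        for rxn in self.reactions:
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelError(
                        f"reaction {rxn.id!r} references undeclared "
                        f"metabolite {met_id!r}"
                    )
        for rxn_id in self.objective:
            if rxn_id not in self._rxn_index:
                raise ModelError(f"objective references unknown reaction {rxn_id!r}")

    def copy(self) -> "StoichiometricModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def stoichiometric_matrix(self):
        """Dense S matrix (metabolites x reactions), numpy array."""
        import numpy as np

        met_pos = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[met_pos[met_id], j] = coef
        return S

    # -- tabular dump ----------------------------------------------------
    def to_tables(self) -> tuple[str, str]:
        """Dump as two TSV tables (metabolites, reactions)."""
        met_lines = ["id\tname\tcompartment\tformula\tcharge"]
        for m in self.metabolites:
            met_lines.append(
                f"{m.id}\t{m.name}\t{m.compartment}\t{m.formula or ''}\t"
                f"{'' if m.charge is None else m.charge}"
            )
        rxn_lines = ["id\tname\tstoichiometry\tlower_bound\tupper_bound\tgene_associated"]
        for r in self.reactions:
            parts = []
            for met_id in sorted(r.stoichiometry):
                parts.append(f"{r.stoichiometry[met_id]:g} {met_id}")
            rxn_lines.append(
                f"{r.id}\t{r.name}\t{' + '.join(parts)}\t{r.lower_bound:g}\t"
                f"{r.upper_bound:g}\t{int(r.gene_associated)}"
            )
        return "\n".join(met_lines) + "\n", "\n".join(rxn_lines) + "\n"


# ---------------------------------------------------------------------------
# Core model construction
# ---------------------------------------------------------------------------

#: Default biomass precursor demands, mmol per g-DW, plus growth-associated
#: ATP.  These are generic heterotroph values used to calibrate the core
#: model's biomass pseudo-reaction; they are NOT measured for
#: P. denitrificans and are exposed as a parameter for that reason.
DEFAULT_BIOMASS_DEMANDS: dict[str, float] = {
    "accoa_c": 2.5,
    "oaa_c": 1.8,
    "akg_c": 1.1,
    "pyr_c": 2.8,
    "nadph_c": 16.0,
    "atp_c": 40.0,
}


@dataclass
class CoreModelParams:
    """Tunable parameters of the built-in core model.

    Parameters
    ----------
    po_ratio:
        ATP synthesised per NADH oxidised by the lumped respiratory
        chain (dimensionless, default 1.5).
    me_cofactor:
        Cofactor reduced by malic enzyme, ``"NADPH"`` (default) or
        ``"NADH"``.
    include_transhydrogenase:
        Whether to include a reversible NADH/NADPH transhydrogenase
        (default True), so either malic-enzyme cofactor choice leaves
        the PHB route feasible.
    maintenance_atp:
        Lower bound of the non-growth ATP drain,
        mmol g-DW^-1 h^-1 (default 7.5).
    biomass_demands:
        Precursor demands of the biomass pseudo-reaction, mmol per g-DW.
    """

    po_ratio: float = 1.5
    me_cofactor: str = "NADPH"
    include_transhydrogenase: bool = True
    maintenance_atp: float = DEFAULT_MAINTENANCE_ATP
    biomass_demands: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIOMASS_DEMANDS)
    )

    def validate(self) -> None:
        if not self.po_ratio > 0:
            raise ModelError(f"po_ratio must be > 0, got {self.po_ratio}")
        if self.maintenance_atp < 0:
            raise ModelError(
                f"maintenance_atp must be >= 0, got {self.maintenance_atp}"
            )
        if self.me_cofactor not in ("NADH", "NADPH"):
            raise ModelError(
                f"me_cofactor must be 'NADH' or 'NADPH', got {self.me_cofactor!r}"
            )
        if any(v < 0 for v in self.biomass_demands.values()):
            raise ModelError("biomass demands must be non-negative")


def _core_metabolites() -> list[Metabolite]:
    c = "c"
    defs = [
        ("succ_e", "Succinate (extracellular)", "e", "C4H4O4", -2),
        ("succ_c", "Succinate", c, "C4H4O4", -2),
        ("fum_c", "Fumarate", c, "C4H2O4", -2),
        ("mal_c", "L-Malate", c, "C4H4O5", -2),
        ("oaa_c", "Oxaloacetate", c, "C4H2O5", -2),
        ("pyr_c", "Pyruvate", c, "C3H3O3", -1),
        ("cit_c", "Citrate", c, "C6H5O7", -3),
        ("icit_c", "Isocitrate", c, "C6H5O7", -3),
        ("akg_c", "2-Oxoglutarate", c, "C5H4O5", -2),
        ("succoa_c", "Succinyl-CoA", c, "C25H35N7O19P3S", -5),
        ("accoa_c", "Acetyl-CoA", c, "C23H34N7O17P3S", -4),
        ("aacoa_c", "Acetoacetyl-CoA", c, "C25H36N7O18P3S", -4),
        ("hbcoa_c", "(R)-3-Hydroxybutyryl-CoA", c, "C25H38N7O18P3S", -4),
        ("coa_c", "Coenzyme A", c, "C21H32N7O16P3S", -4),
        ("phb_c", "PHB monomer unit", c, "C4H6O2", 0),
        ("nad_c", "NAD+", c, "C21H26N7O14P2", -1),
        ("nadh_c", "NADH", c, "C21H27N7O14P2", -2),
        ("nadp_c", "NADP+", c, "C21H25N7O17P3", -3),
        ("nadph_c", "NADPH", c, "C21H26N7O17P3", -4),
        ("atp_c", "ATP", c, "C10H12N5O13P3", -4),
        ("adp_c", "ADP", c, "C10H12N5O10P2", -3),
        ("pi_c", "Phosphate", c, "HO4P", -2),
        ("o2_c", "Oxygen", c, "O2", 0),
        ("co2_c", "Carbon dioxide", c, "CO2", 0),
        ("h2o_c", "Water", c, "H2O", 0),
        ("biomass_c", "Biomass", c, None, None),
    ]
    return [
        Metabolite(mid, name, comp, formula, charge)
        for mid, name, comp, formula, charge in defs
    ]


def build_core_model(params: CoreModelParams | None = None) -> StoichiometricModel:
    """Build the built-in core model of succinate-grown *P. denitrificans*.

    The network covers succinate uptake, the oxidative TCA cycle, the
    malic-enzyme/pyruvate-dehydrogenase route from C4 acids to
    acetyl-CoA, the phaA/phaB/phaC PHB branch with a monomer sink,
    lumped respiration (NADH + 1/2 O2 + P/O ADP -> P/O ATP), an ATP
    maintenance drain bounded below by ``params.maintenance_atp`` and a
    biomass pseudo-reaction draining the configured precursors.

    Raises
    ------
    ModelError
        If ``params`` violates its invariants.
    """
    params = params or CoreModelParams()
    params.validate()
    po = params.po_ratio
    inf = math.inf

    rxns: list[Reaction] = []

    def add(rxn_id, name, stoich, lb=0.0, ub=1000.0, gene=True, subsystem=None):
        rxns.append(
            Reaction(
                rxn_id,
                stoich,
                name=name,
                lower_bound=lb,
                upper_bound=ub,
                gene_associated=gene,
                subsystem=subsystem,
            )
        )

    # Boundary
    add("EX_succ", "Succinate exchange", {"succ_e": -1}, lb=-1000, gene=False,
        subsystem="exchange")
    add("EX_o2", "O2 exchange", {"o2_c": -1}, lb=-1000, gene=False,
        subsystem="exchange")
    add("EX_co2", "CO2 exchange", {"co2_c": -1}, lb=-1000, gene=False,
        subsystem="exchange")
    add("EX_h2o", "H2O exchange", {"h2o_c": -1}, lb=-1000, gene=False,
        subsystem="exchange")
    add("DM_phb", "PHB monomer sink", {"phb_c": -1}, gene=False,
        subsystem="sink")
    add("DM_biomass", "Biomass drain", {"biomass_c": -1}, gene=False,
        subsystem="sink")

    # Transport
    add("SUCCt", "Succinate transport", {"succ_e": -1, "succ_c": 1},
        subsystem="transport")

    # TCA cycle and anaplerotic exit.  Succinate dehydrogenase reduces the
    # quinone pool, lumped here into the NAD pool (see docs/methods.md).
    add("SDH", "Succinate dehydrogenase",
        {"succ_c": -1, "nad_c": -1, "fum_c": 1, "nadh_c": 1}, subsystem="TCA")
    add("FUM", "Fumarase", {"fum_c": -1, "h2o_c": -1, "mal_c": 1},
        lb=-1000, subsystem="TCA")
    add("MDH", "Malate dehydrogenase",
        {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1},
        lb=-1000, subsystem="TCA")
    if params.me_cofactor == "NADPH":
        me_ox, me_red = "nadp_c", "nadph_c"
    else:
        me_ox, me_red = "nad_c", "nadh_c"
    add("ME", "Malic enzyme",
        {"mal_c": -1, me_ox: -1, "pyr_c": 1, "co2_c": 1, me_red: 1},
        subsystem="anaplerosis")
    add("PDH", "Pyruvate dehydrogenase",
        {"pyr_c": -1, "coa_c": -1, "nad_c": -1,
         "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, subsystem="anaplerosis")
    add("CS", "Citrate synthase",
        {"accoa_c": -1, "oaa_c": -1, "h2o_c": -1, "cit_c": 1, "coa_c": 1},
        subsystem="TCA")
    add("ACONT", "Aconitase", {"cit_c": -1, "icit_c": 1}, lb=-1000,
        subsystem="TCA")
    add("ICDH", "Isocitrate dehydrogenase (NADP)",
        {"icit_c": -1, "nadp_c": -1, "akg_c": 1, "co2_c": 1, "nadph_c": 1},
        subsystem="TCA")
    add("AKGDH", "2-Oxoglutarate dehydrogenase",
        {"akg_c": -1, "coa_c": -1, "nad_c": -1,
         "succoa_c": 1, "co2_c": 1, "nadh_c": 1}, subsystem="TCA")
    add("SUCOAS", "Succinyl-CoA synthetase",
        {"succoa_c": -1, "adp_c": -1, "pi_c": -1,
         "succ_c": 1, "coa_c": 1, "atp_c": 1}, lb=-1000, subsystem="TCA")

    # PHB branch
    add("PHAA", "Beta-ketothiolase (phaA)",
        {"accoa_c": -2, "aacoa_c": 1, "coa_c": 1}, subsystem="PHB")
    add("PHAB", "Acetoacetyl-CoA reductase (phaB)",
        {"aacoa_c": -1, "nadph_c": -1, "hbcoa_c": 1, "nadp_c": 1},
        subsystem="PHB")
    add("PHAC", "PHB synthase (phaC)",
        {"hbcoa_c": -1, "phb_c": 1, "coa_c": 1}, subsystem="PHB")

    # Energy metabolism
    add("RESP", "Respiration (lumped, NADH)",
        {"nadh_c": -1, "o2_c": -0.5, "adp_c": -po, "pi_c": -po,
         "nad_c": 1, "atp_c": po, "h2o_c": po + 1},
        subsystem="oxidative phosphorylation")
    if params.include_transhydrogenase:
        add("THD", "Transhydrogenase",
            {"nadh_c": -1, "nadp_c": -1, "nad_c": 1, "nadph_c": 1},
            lb=-1000, subsystem="oxidative phosphorylation")
    add("ATPM", "ATP maintenance",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
        lb=params.maintenance_atp, ub=inf, gene=False, subsystem="maintenance")

    # Biomass pseudo-reaction: drains precursors, regenerates the
    # cofactor pools, produces 1 g-DW of biomass per unit flux (h^-1).
    d = params.biomass_demands
    stoich: dict[str, float] = {"biomass_c": 1.0}
    for met_id, demand in d.items():
        if demand == 0:
            continue
        stoich[met_id] = stoich.get(met_id, 0.0) - demand
    if d.get("accoa_c"):
        stoich["coa_c"] = stoich.get("coa_c", 0.0) + d["accoa_c"]
    if d.get("nadph_c"):
        stoich["nadp_c"] = stoich.get("nadp_c", 0.0) + d["nadph_c"]
    if d.get("atp_c"):
        stoich["adp_c"] = stoich.get("adp_c", 0.0) + d["atp_c"]
        stoich["pi_c"] = stoich.get("pi_c", 0.0) + d["atp_c"]
        stoich["h2o_c"] = stoich.get("h2o_c", 0.0) - d["atp_c"]
    add("BIOMASS", "Biomass pseudo-reaction", stoich, gene=False,
        subsystem="biomass")

    model = StoichiometricModel(
        metabolites=_core_metabolites(),
        reactions=rxns,
        objective={"BIOMASS": 1.0},
        id="phbflux_core",
    )
    return model


# ---------------------------------------------------------------------------
# Mass balance checking
# ---------------------------------------------------------------------------

_SKIP_SUBSYSTEMS = {"exchange", "sink", "maintenance", "biomass"}


def check_mass_balance(
    model: StoichiometricModel,
    elements: tuple[str, ...] = ("C", "O", "N", "P", "S"),
    tol: float = 1e-9,
) -> list[tuple[str, str, float]]:
    """Check elemental balance of internal enzyme-catalysed reactions.

    Exchanges, sinks, the biomass pseudo-reaction and the maintenance
    drain are skipped, as are reactions touching any metabolite without
    a formula (with a warning).  Hydrogen is not among the default
    elements because protons are not modelled explicitly.

    Returns
    -------
    list of (reaction_id, element, imbalance)
        Net production of each unbalanced element; empty iff every
        checked reaction balances.
    """
    problems: list[tuple[str, str, float]] = []
    for rxn in model.reactions:
        if rxn.is_exchange or (rxn.subsystem in _SKIP_SUBSYSTEMS):
            continue
        counts: dict[str, float] = {}
        skip = False
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            ec = met.element_counts()
            if ec is None:
                logger.warning(
                    "skipping mass balance of %s: metabolite %s has no formula",
                    rxn.id, met_id,
                )
                skip = True
                break
            for el, n in ec.items():
                counts[el] = counts.get(el, 0.0) + coef * n
        if skip:
            continue
        for el in elements:
            imbalance = counts.get(el, 0.0)
            if abs(imbalance) > tol:
                problems.append((rxn.id, el, imbalance))
    return problems
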