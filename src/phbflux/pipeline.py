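"""Two-phase flux analysis: PHB accumulation vs exponential growth.

After transfer of starved, PHB-free cells to fresh succinate medium the
culture passes through two physiological phases:

* **accumulation** — no net growth; PHB content jumps to ~7.8% of dry
  weight within 30 min (a molar monomer rate of ~1.63 mmol g-DW^-1
  h^-1);
* **exponential** — growth at mu with the PHB content constant at ~7%,
  i.e. a tenfold lower specific PHB rate.

Each phase is simulated by pinning the growth and PHB fluxes to their
measured values, imposing the maintenance ATP lower bound, minimising
the succinate uptake rate and resolving the remaining degeneracy with
parsimonious FBA.  The report compares predicted uptake, acetyl-CoA
synthesis, TCA-cycle engagement and active-enzyme sets between phases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from .fba import (
    ACTIVE_FLUX_TOL,
    ConstraintSet,
    FBAError,
    FluxSolution,
    active_reactions,
    pfba,
    production_rate,
    solve_fba,
)
from .kinetics import (
    BatchTimeSeries,
    RateEstimates,
    accumulation_rate,
    estimate_rates,
)
from .model import DEFAULT_MAINTENANCE_ATP, StoichiometricModel, build_core_model

logger = logging.getLogger(__name__)


@dataclass
class ReactionMap:
    """Which reactions play the pipeline's four roles.

    Defaults match the built-in core model.  ``uptake_is_exchange``
    states the sign convention: on an exchange reaction, uptake is a
    negative flux and the reported uptake rate is its magnitude.
    """

    growth: str = "BIOMASS"
    phb: str = "DM_phb"
    uptake: str = "EX_succ"
    maintenance: str = "ATPM"
    acetyl_coa: str = "accoa_c"
    citrate_synthase: str = "CS"
    uptake_is_exchange: bool = True

    @classmethod
    def for_genome_scale(cls, **overrides) -> "ReactionMap":
        """Mapping template for an external genome-scale model.

        Identifier schemes differ between reconstructions, so the four
        role ids must be supplied explicitly (e.g. the biomass reaction,
        the PHB demand, the succinate exchange and the ATP maintenance
        reaction of the deposited model).
        """
        return cls(**overrides)


@dataclass
class PhaseSpec:
    """Constraints defining one physiological phase.

    growth_rate in h^-1; phb_molar_rate and maintenance_atp in
    mmol g-DW^-1 h^-1.  The accumulation phase has growth_rate = 0.
    """

    name: str
    growth_rate: float
    phb_molar_rate: float
    maintenance_atp: float = DEFAULT_MAINTENANCE_ATP

    def validate(self) -> None:
        if self.name not in ("accumulation", "exponential"):
            raise ValueError(
                f"phase name must be 'accumulation' or 'exponential', "
                f"got {self.name!r}")
        if self.name == "accumulation" and self.growth_rate != 0:
            raise ValueError("the accumulation phase has zero growth rate")
        if self.growth_rate < 0 or self.phb_molar_rate < 0 or self.maintenance_atp < 0:
            raise ValueError("rates must be non-negative")


ACCUMULATION_PHASE = PhaseSpec("accumulation", growth_rate=0.0, phb_molar_rate=1.63)
EXPONENTIAL_PHASE = PhaseSpec("exponential", growth_rate=0.232, phb_molar_rate=0.169)


@dataclass
class PhaseReport:
    """FBA outcome for one phase.

    ``predicted_uptake`` and ``acetyl_coa_rate`` in mmol g-DW^-1 h^-1
    (uptake reported as a magnitude).  ``n_active_enzymes`` counts
    gene-associated reactions carrying flux in the parsimonious
    solution; FBA optima are degenerate, so this count is
    solution-dependent even though the optimal uptake is not.
    """

    spec: PhaseSpec
    status: str
    predicted_uptake: float | None = None
    acetyl_coa_rate: float | None = None
    n_active_enzymes: int | None = None
    active_enzymes: set[str] = field(default_factory=set)
    tca_active: bool | None = None
    solution: FluxSolution | None = None
    diagnostics: dict | None = None

    def to_dict(self) -> dict:
        return {
            "phase": self.spec.name,
            "growth_rate_per_h": self.spec.growth_rate,
            "phb_molar_rate": self.spec.phb_molar_rate,
            "maintenance_atp": self.spec.maintenance_atp,
            "status": self.status,
            "predicted_uptake_mmol_per_gDW_h": self.predicted_uptake,
            "acetyl_coa_rate_mmol_per_gDW_h": self.acetyl_coa_rate,
            "n_active_enzymes": self.n_active_enzymes,
            "n_active_enzymes_caveat": (
                "count taken from the parsimonious-FBA solution; alternate "
                "optima can activate different enzyme sets"),
            "tca_active": self.tca_active,
            "diagnostics": self.diagnostics,
        }


def _phase_constraints(spec: PhaseSpec, rmap: ReactionMap) -> ConstraintSet:
    return ConstraintSet(
        fixed_fluxes={
            rmap.growth: spec.growth_rate,
            rmap.phb: spec.phb_molar_rate,
        },
        bound_overrides={rmap.maintenance: (spec.maintenance_atp, float("inf"))},
    )


def _diagnose_infeasibility(model, spec, rmap) -> dict:
    """Relax one pin at a time and report which restores feasibility."""
    releases = {
        "growth_pin": ConstraintSet(
            fixed_fluxes={rmap.phb: spec.phb_molar_rate},
            bound_overrides={rmap.maintenance: (spec.maintenance_atp, float("inf"))}),
        "phb_pin": ConstraintSet(
            fixed_fluxes={rmap.growth: spec.growth_rate},
            bound_overrides={rmap.maintenance: (spec.maintenance_atp, float("inf"))}),
        "maintenance_bound": ConstraintSet(
            fixed_fluxes={rmap.growth: spec.growth_rate,
                          rmap.phb: spec.phb_molar_rate}),
    }
    restoring = []
    for label, cons in releases.items():
        sol = solve_fba(model, {rmap.uptake: 1.0},
                        "max" if rmap.uptake_is_exchange else "min", cons)
        if sol.status == "optimal":
            restoring.append(label)
    return {"relaxation_restores_feasibility": restoring}


def run_phase(
    model: StoichiometricModel,
    spec: PhaseSpec,
    rmap: ReactionMap | None = None,
    tol: float = ACTIVE_FLUX_TOL,
) -> PhaseReport:
    """Simulate one phase: pin rates, minimise uptake, resolve with pFBA.

    The growth and PHB fluxes are fixed to the phase's measured values,
    the maintenance ATP lower bound is imposed, succinate uptake is
    minimised and the optimum is made parsimonious.  On infeasibility
    the report carries diagnostics naming which single relaxed
    constraint restores feasibility.
    """
    spec.validate()
    rmap = rmap or ReactionMap()
    for role, rxn_id in (("growth", rmap.growth), ("phb", rmap.phb),
                         ("uptake", rmap.uptake), ("maintenance", rmap.maintenance)):
        try:
            model.reaction(rxn_id)
        except KeyError:
            raise FBAError(
                f"model lacks the configured {role} reaction {rxn_id!r}") from None
    constraints = _phase_constraints(spec, rmap)
    # uptake on an exchange is a negative flux: minimising its magnitude
    # means maximising the (negative) exchange flux
    direction = "max" if rmap.uptake_is_exchange else "min"
    solution = pfba(model, {rmap.uptake: 1.0}, direction, constraints)
    if solution.status != "optimal":
        logger.warning("phase %s infeasible; running pin diagnostics", spec.name)
        return PhaseReport(
            spec=spec, status=solution.status,
            diagnostics=_diagnose_infeasibility(model, spec, rmap))
    uptake = float(solution.fluxes[rmap.uptake])
    predicted_uptake = abs(uptake) if rmap.uptake_is_exchange else uptake
    accoa_rate = float(production_rate(solution, model, rmap.acetyl_coa))
    active = active_reactions(solution, model, tol)
    if rmap.citrate_synthase in solution.fluxes:
        tca_active = bool(abs(solution.fluxes[rmap.citrate_synthase]) > tol)
    else:
        tca_active = None
    return PhaseReport(
        spec=spec,
        status="optimal",
        predicted_uptake=predicted_uptake,
        acetyl_coa_rate=accoa_rate,
        n_active_enzymes=len(active),
        active_enzymes=active,
        tca_active=tca_active,
        solution=solution,
    )


def compare_phases(r1: PhaseReport, r2: PhaseReport) -> dict:
    """Tabulate the two phases side by side.

    Reports predicted uptake, acetyl-CoA rates, active-enzyme counts and
    set differences, and the ratio of the phases' PHB rates.
    """
    for r in (r1, r2):
        if r.status != "optimal":
            raise FBAError(f"phase {r.spec.name!r} is {r.status}, not optimal")
    if r2.spec.phb_molar_rate > 0:
        phb_ratio = r1.spec.phb_molar_rate / r2.spec.phb_molar_rate
    else:
        phb_ratio = float("inf")
    only_1 = sorted(r1.active_enzymes - r2.active_enzymes)
    only_2 = sorted(r2.active_enzymes - r1.active_enzymes)
    return {
        "phases": [r1.spec.name, r2.spec.name],
        "predicted_uptake": [r1.predicted_uptake, r2.predicted_uptake],
        "acetyl_coa_rate": [r1.acetyl_coa_rate, r2.acetyl_coa_rate],
        "n_active_enzymes": [r1.n_active_enzymes, r2.n_active_enzymes],
        "enzymes_only_in_first": only_1,
        "enzymes_only_in_second": only_2,
        "phb_rate_ratio_first_to_second": phb_ratio,
        "tca_active": [r1.tca_active, r2.tca_active],
    }


def run_full_analysis(
    series: BatchTimeSeries,
    model: StoichiometricModel | None = None,
    rmap: ReactionMap | None = None,
    window: tuple[int, int] | None = None,
    phb_content: float | None = None,
    maintenance_atp: float = DEFAULT_MAINTENANCE_ATP,
) -> dict:
    """End-to-end analysis of a batch series.

    Chains rate estimation (growth rate and yield by regression, the
    accumulation rate from the first sampling interval), builds the two
    PhaseSpecs, runs both phase FBAs on ``model`` (default: the built-in
    core model) and returns one JSON-serialisable report.  Every derived
    number is logged with the formula that produced it.
    """
    if len(series) < 3:
        raise ValueError("time series too short for rate estimation")
    model = model or build_core_model()
    rates: RateEstimates = estimate_rates(series, window=window,
                                          phb_content=phb_content)
    logger.info("mu = slope(ln X vs t over window %s) = %.4f h^-1",
                rates.window, rates.mu)
    logger.info("yield = slope(X vs consumed S) = %.2f gDW/mol", rates.yield_xs)
    logger.info("q_s = 1000*mu/yield = %.3f mmol/gDW/h", rates.q_s)
    logger.info("q_PHB = mu*content = %.2f mg/gDW/h = %.4f mmol/gDW/h",
                rates.q_phb_mass, rates.q_phb_molar)
    # accumulation rate from the first sampling interval (zero growth)
    if len(series) < 2 or series.time[1] <= series.time[0]:
        raise ValueError("need a first sampling interval for the accumulation rate")
    acc = accumulation_rate(series.phb_content[0], series.phb_content[1],
                            series.time[1] - series.time[0])
    logger.info("accumulation rate = (w1-w0)/dt/96 = %.4f mmol/gDW/h", acc)
    phase1 = PhaseSpec("accumulation", 0.0, acc, maintenance_atp)
    phase2 = PhaseSpec("exponential", rates.mu, rates.q_phb_molar, maintenance_atp)
    r1 = run_phase(model, phase1, rmap)
    r2 = run_phase(model, phase2, rmap)
    report = {
        "kinetics": {**rates.to_dict(), "accumulation_rate_mmol_per_gDW_h": acc},
        "phase_accumulation": r1.to_dict(),
        "phase_exponential": r2.to_dict(),
    }
    if r1.status == "optimal" and r2.status == "optimal":
        report["comparison"] = compare_phases(r1, r2)
    return report


def report_to_json(report: dict, indent: int = 2) -> str:
    return json.dumps(report, indent=indent, default=str)
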