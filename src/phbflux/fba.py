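"""Flux balance analysis on stoichiometric models.

The linear programs (steady state S·v = 0, flux bounds, linear
objective) are solved with scipy's HiGHS backend.  ``pfba`` resolves the
degeneracy of the FBA optimum parsimoniously by minimising the total
absolute flux among all optima, which is the closest thing to a
canonical representative of the optimal face and the basis for counting
"active" enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import StoichiometricModel

#: Fluxes below this magnitude (mmol g-DW^-1 h^-1) are treated as zero
#: when deciding whether a reaction is active; LP solver noise floor.
ACTIVE_FLUX_TOL = 1e-6

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


class FBAError(ValueError):
    """Raised for inconsistent FBA problem formulations."""


@dataclass
class ConstraintSet:
    """Extra constraints layered on a model for one simulation.

    ``fixed_fluxes`` pins reactions to exact values (implemented as
    lower = upper bound overrides); ``bound_overrides`` replaces a
    reaction's (lower, upper) bounds.
    """

    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def apply(self, model: StoichiometricModel, lb: np.ndarray, ub: np.ndarray) -> None:
        pos = {r: i for i, r in enumerate(model.reaction_ids)}
        for rxn_id, (lo, hi) in self.bound_overrides.items():
            if rxn_id not in pos:
                raise KeyError(f"unknown reaction {rxn_id!r}")
            lb[pos[rxn_id]] = lo
            ub[pos[rxn_id]] = hi
        for rxn_id, value in self.fixed_fluxes.items():
            if rxn_id not in pos:
                raise KeyError(f"unknown reaction {rxn_id!r}")
            lb[pos[rxn_id]] = value
            ub[pos[rxn_id]] = value


@dataclass
class FluxSolution:
    """Outcome of one FBA solve.

    ``fluxes`` maps reaction ids to rates in mmol g-DW^-1 h^-1 (the
    biomass pseudo-reaction in h^-1); populated only when ``status`` is
    ``"optimal"``.
    """

    status: str
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def _problem_arrays(model, objective, constraints):
    rxn_ids = model.reaction_ids
    pos = {r: i for i, r in enumerate(rxn_ids)}
    for rxn_id in objective:
        if rxn_id not in pos:
            raise KeyError(f"unknown reaction {rxn_id!r}")
    n = len(rxn_ids)
    c = np.zeros(n)
    for rxn_id, coef in objective.items():
        c[pos[rxn_id]] = coef
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if constraints is not None:
        constraints.apply(model, lb, ub)
    S = model.stoichiometric_matrix()
    return S, c, lb, ub, rxn_ids


def solve_fba(
    model: StoichiometricModel,
    objective: dict[str, float] | None = None,
    direction: str = "max",
    constraints: ConstraintSet | None = None,
) -> FluxSolution:
    """Solve one flux balance LP.

    Parameters
    ----------
    model:
        The stoichiometric model.
    objective:
        Linear objective as reaction-id -> coefficient; defaults to the
        model's declared objective.
    direction:
        ``"max"`` or ``"min"``.
    constraints:
        Optional equality pins and bound overrides.

    Returns
    -------
    FluxSolution
        With ``status`` in {optimal, infeasible, unbounded}.  At an
        optimum the flux vector satisfies S·v = 0 and the bounds to
        within 1e-8.
    """
    if direction not in ("min", "max"):
        raise FBAError(f"direction must be 'min' or 'max', got {direction!r}")
    objective = objective if objective is not None else model.objective
    if not objective:
        raise FBAError("no objective given and model declares none")
    S, c, lb, ub, rxn_ids = _problem_arrays(model, objective, constraints)
    if np.any(lb > ub):
        return FluxSolution(status="infeasible", objective_value=None)
    sign = 1.0 if direction == "min" else -1.0
    res = linprog(
        sign * c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None)
    fluxes = dict(zip(rxn_ids, res.x))
    return FluxSolution(status="optimal", objective_value=float(c @ res.x),
                        fluxes=fluxes)


def pfba(
    model: StoichiometricModel,
    objective: dict[str, float] | None = None,
    direction: str = "max",
    constraints: ConstraintSet | None = None,
    opt_tol: float = 1e-9,
) -> FluxSolution:
    """Parsimonious FBA: minimal total |flux| among FBA optima.

    First solves the FBA problem, then — holding the primary objective
    at its optimum to within relative tolerance ``opt_tol`` — minimises
    the sum of absolute fluxes, with each reaction split into forward
    and reverse non-negative halves.  The returned solution attains the
    FBA optimum (never worsens it) and is far less degenerate, making it
    a reasonable basis for reporting which enzymes carry flux.
    """
    first = solve_fba(model, objective, direction, constraints)
    if first.status != "optimal":
        return first
    objective = objective if objective is not None else model.objective
    S, c, lb, ub, rxn_ids = _problem_arrays(model, objective, constraints)
    n = len(rxn_ids)
    opt = first.objective_value
    # v = p - q with p, q >= 0; minimise sum(p + q)
    S2 = np.hstack([S, -S])
    bounds = []
    for i in range(n):
        lo, hi = lb[i], ub[i]
        if lo >= 0:
            bounds.append((lo, hi))  # p
        else:
            bounds.append((0.0, max(hi, 0.0)))
    for i in range(n):
        lo, hi = lb[i], ub[i]
        if hi <= 0:
            bounds.append((-hi, -lo))  # q
        else:
            bounds.append((0.0, max(-lo, 0.0)))
    # Pin the primary objective to its optimal value (small slack so the
    # secondary LP is not infeasible through round-off).
    eps = opt_tol * max(1.0, abs(opt))
    c2 = np.concatenate([c, -c])
    sign = 1.0 if direction == "min" else -1.0
    A_ub = np.vstack([sign * c2, -sign * c2])
    b_ub = np.array([sign * opt + eps, -sign * opt + eps])
    res = linprog(
        np.ones(2 * n),
        A_eq=S2,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        return FluxSolution(status=_STATUS.get(res.status, "infeasible"),
                            objective_value=None)
    v = res.x[:n] - res.x[n:]
    fluxes = dict(zip(rxn_ids, v))
    return FluxSolution(status="optimal", objective_value=float(c @ v),
                        fluxes=fluxes)


def active_reactions(
    solution: FluxSolution,
    model: StoichiometricModel,
    tol: float = ACTIVE_FLUX_TOL,
) -> set[str]:
    """Gene-associated reactions carrying flux above ``tol`` in magnitude.

    FBA optima are degenerate, so the membership of this set depends on
    which optimal flux vector the solver returned; pair it with ``pfba``
    for a reproducible (but still solution-dependent) enzyme count.
    """
    if solution.status != "optimal":
        raise FBAError(f"solution status is {solution.status!r}, not optimal")
    return {
        rxn_id
        for rxn_id, flux in solution.fluxes.items()
        if abs(flux) > tol and model.reaction(rxn_id).gene_associated
    }


def production_rate(
    solution: FluxSolution,
    model: StoichiometricModel,
    metabolite_id: str,
) -> float:
    """Total production rate of a metabolite in a flux solution.

    Sums coefficient × flux over all (reaction, direction) pairs that
    produce the metabolite; at steady state this equals the total
    consumption rate.  Units mmol g-DW^-1 h^-1.
    """
    model.metabolite(metabolite_id)  # raises KeyError if unknown
    total = 0.0
    for rxn in model.reactions:
        coef = rxn.stoichiometry.get(metabolite_id)
        if coef is None:
            continue
        contribution = coef * solution.fluxes.get(rxn.id, 0.0)
        if contribution > 0:
            total += contribution
    return total


def flux_table(solution: FluxSolution) -> str:
    """Flux solution as a TSV table (reaction id, flux)."""
    lines = ["reaction_id\tflux"]
    for rxn_id, flux in solution.fluxes.items():
        lines.append(f"{rxn_id}\t{flux:.10g}")
    return "\n".join(lines) + "\n"
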