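"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from phbflux import (
    StoichiometricModel,
    build_core_model,
    load_packaged_timeseries,
)
from phbflux.model import Metabolite, Reaction


@pytest.fixture(scope="session")
def core_model() -> StoichiometricModel:
    return build_core_model()


@pytest.fixture(scope="session")
def batch_series():
    return load_packaged_timeseries()


# ---------------------------------------------------------------------------
# Independent reference solver (cobrapy) — used only as an oracle
# ---------------------------------------------------------------------------

def to_cobra(model: StoichiometricModel):
    """Convert to a cobrapy model for cross-checking, never for solving
    inside the package itself."""
    import cobra

    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, compartment=m.compartment)
        for m in model.metabolites
    }
    crs = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = -1e6 if r.lower_bound == -math.inf else r.lower_bound
        cr.upper_bound = 1e6 if r.upper_bound == math.inf else r.upper_bound
        crs.append(cr)
    cm.add_reactions(crs)
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {mets[k]: v for k, v in r.stoichiometry.items()}
        )
    return cm


def cobra_optimum(model: StoichiometricModel, objective: dict[str, float],
                  direction: str, constraints=None):
    """Reference FBA optimum via cobrapy/GLPK; returns (status, value)."""
    cm = to_cobra(model)
    if constraints is not None:
        for rxn_id, (lo, hi) in constraints.bound_overrides.items():
            cm.reactions.get_by_id(rxn_id).bounds = (
                -1e6 if lo == -math.inf else lo,
                1e6 if hi == math.inf else hi,
            )
        for rxn_id, value in constraints.fixed_fluxes.items():
            cm.reactions.get_by_id(rxn_id).bounds = (value, value)
    cm.objective = {cm.reactions.get_by_id(k): v for k, v in objective.items()}
    cm.objective_direction = "max" if direction == "max" else "min"
    sol = cm.optimize()
    if sol.status != "optimal":
        return sol.status, None
    return "optimal", sol.objective_value


# ---------------------------------------------------------------------------
# Random small network generator for solver cross-checks
# ---------------------------------------------------------------------------

def random_network(rng: np.random.Generator) -> tuple[StoichiometricModel, dict]:
    """A random small metabolic network with exchanges at both ends.

    Linear/branched chains of unit conversions with random bounds; the
    objective maximises the terminal export.  Feasibility is not
    guaranteed (both solvers must agree on status either way).
    """
    n_mets = int(rng.integers(3, 7))
    mets = [Metabolite(f"M{i}") for i in range(n_mets)]
    rxns = [
        Reaction("EX_in", {"M0": 1}, lower_bound=0.0,
                 upper_bound=float(rng.integers(1, 10)), gene_associated=False),
        Reaction("EX_out", {f"M{n_mets-1}": -1}, lower_bound=0.0,
                 upper_bound=1000.0, gene_associated=False),
    ]
    n_internal = int(rng.integers(n_mets - 1, 10))
    for k in range(n_internal):
        i, j = rng.choice(n_mets, size=2, replace=False)
        rev = bool(rng.random() < 0.3)
        coef_in = float(rng.integers(1, 3))
        coef_out = float(rng.integers(1, 3))
        rxns.append(
            Reaction(
                f"R{k}", {f"M{i}": -coef_in, f"M{j}": coef_out},
                lower_bound=-float(rng.integers(1, 20)) if rev else 0.0,
                upper_bound=float(rng.integers(1, 20)),
            )
        )
    # guarantee a backbone path M0 -> M1 -> ... so the network is not
    # trivially blocked in most draws
    for i in range(n_mets - 1):
        rxns.append(Reaction(f"B{i}", {f"M{i}": -1, f"M{i+1}": 1},
                             upper_bound=float(rng.integers(1, 20))))
    model = StoichiometricModel(metabolites=mets, reactions=rxns,
                                objective={"EX_out": 1.0}, id="random")
    return model, {"EX_out": 1.0}


# ---------------------------------------------------------------------------
# Brute-force vertex enumeration (oracle for pFBA parsimony)
# ---------------------------------------------------------------------------

def enumerate_vertices(A: np.ndarray, b: np.ndarray, lb: np.ndarray,
                       ub: np.ndarray, tol: float = 1e-9) -> list[np.ndarray]:
    """All vertices of {v : A v = b, lb <= v <= ub} by brute force.

    A vertex fixes at least n - rank(A) variables at a bound; enumerate
    every such choice and solve the reduced linear system.  Only viable
    for tiny problems.
    """
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    n_fix = n - rank
    vertices: list[np.ndarray] = []
    for fixed_vars in itertools.combinations(range(n), n_fix):
        free_vars = [i for i in range(n) if i not in fixed_vars]
        for bounds_choice in itertools.product(*[
            [lb[i], ub[i]] for i in fixed_vars
        ]):
            if any(not math.isfinite(v) for v in bounds_choice):
                continue
            v = np.zeros(n)
            for i, val in zip(fixed_vars, bounds_choice):
                v[i] = val
            rhs = b - A[:, list(fixed_vars)] @ np.array(bounds_choice)
            Af = A[:, free_vars]
            sol, residuals, rk, _ = np.linalg.lstsq(Af, rhs, rcond=None)
            if rk < len(free_vars):
                continue  # underdetermined: not a vertex
            v[free_vars] = sol
            if np.max(np.abs(A @ v - b)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
                vertices.append(v)
    return vertices
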