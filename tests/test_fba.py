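"""FBA solver behaviour, pFBA parsimony and flux summaries."""

import numpy as np
import pytest

from phbflux import (
    ConstraintSet,
    FBAError,
    active_reactions,
    flux_table,
    pfba,
    production_rate,
    solve_fba,
)
from phbflux.model import Metabolite, Reaction, StoichiometricModel

from conftest import cobra_optimum, enumerate_vertices, random_network


@pytest.fixture
def toy_chain():
    """EX_A (uptake capped at 1) -> A -> B -> EX_B."""
    return StoichiometricModel(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[
            Reaction("EX_A", {"A": 1}, lower_bound=0, upper_bound=1,
                     gene_associated=False),
            Reaction("AB", {"A": -1, "B": 1}),
            Reaction("EX_B", {"B": -1}, gene_associated=False),
        ],
        objective={"EX_B": 1.0},
        id="chain",
    )


@pytest.fixture
def detour_network():
    """A -> B directly, or A -> C -> B: same yield, different total flux."""
    return StoichiometricModel(
        metabolites=[Metabolite("A"), Metabolite("B"), Metabolite("C")],
        reactions=[
            Reaction("EX_A", {"A": 1}, upper_bound=1, gene_associated=False),
            Reaction("DIRECT", {"A": -1, "B": 1}),
            Reaction("VIA_C1", {"A": -1, "C": 1}),
            Reaction("VIA_C2", {"C": -1, "B": 1}),
            Reaction("EX_B", {"B": -1}, gene_associated=False),
        ],
        objective={"EX_B": 1.0},
        id="detour",
    )


class TestSolveFBA:
    def test_single_path_chain(self, toy_chain):
        sol = solve_fba(toy_chain)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(1.0)
        assert sol.fluxes["AB"] == pytest.approx(1.0)

    def test_unknown_objective_reaction_raises(self, toy_chain):
        with pytest.raises(KeyError, match="NOPE"):
            solve_fba(toy_chain, {"NOPE": 1.0})

    def test_unknown_pin_raises(self, toy_chain):
        with pytest.raises(KeyError, match="NOPE"):
            solve_fba(toy_chain, constraints=ConstraintSet(fixed_fluxes={"NOPE": 1}))

    def test_infeasible_pin_reported(self, toy_chain):
        cons = ConstraintSet(fixed_fluxes={"EX_B": 2.0})  # uptake cap is 1
        sol = solve_fba(toy_chain, constraints=cons)
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_unbounded_reported(self):
        model = StoichiometricModel(
            metabolites=[Metabolite("A")],
            reactions=[
                Reaction("EX_in", {"A": 1}, lower_bound=0, upper_bound=np.inf,
                         gene_associated=False),
                Reaction("EX_out", {"A": -1}, upper_bound=np.inf,
                         gene_associated=False),
            ],
            objective={"EX_out": 1.0},
        )
        assert solve_fba(model).status == "unbounded"

    def test_maintenance_above_energy_ceiling_infeasible(self, core_model):
        cons = ConstraintSet(
            fixed_fluxes={"BIOMASS": 0.0, "DM_phb": 0.0},
            bound_overrides={"ATPM": (1e9, np.inf), "EX_succ": (0.0, 0.0)},
        )
        sol = solve_fba(core_model, {"EX_succ": 1.0}, "max", cons)
        assert sol.status == "infeasible"

    def test_solution_within_bounds(self, core_model):
        cons = ConstraintSet(fixed_fluxes={"BIOMASS": 0.0, "DM_phb": 1.63})
        sol = solve_fba(core_model, {"EX_succ": 1.0}, "max", cons)
        for rxn in core_model.reactions:
            lo, hi = rxn.lower_bound, rxn.upper_bound
            if rxn.id in cons.fixed_fluxes:
                lo = hi = cons.fixed_fluxes[rxn.id]
            assert sol.fluxes[rxn.id] >= lo - 1e-8
            assert sol.fluxes[rxn.id] <= hi + 1e-8


class TestPFBA:
    def test_detour_avoided(self, detour_network):
        sol = pfba(detour_network)
        assert sol.objective_value == pytest.approx(1.0)
        assert sol.fluxes["DIRECT"] == pytest.approx(1.0)
        assert sol.fluxes["VIA_C1"] == pytest.approx(0.0, abs=1e-9)

    def test_objective_never_worsened(self, core_model):
        cons = ConstraintSet(fixed_fluxes={"BIOMASS": 0.0, "DM_phb": 1.63})
        plain = solve_fba(core_model, {"EX_succ": 1.0}, "max", cons)
        pars = pfba(core_model, {"EX_succ": 1.0}, "max", cons)
        assert pars.objective_value >= plain.objective_value - 1e-6

    def test_total_flux_not_above_any_optimal_vertex(self, detour_network):
        """Brute-force enumeration of the optimal face's vertices: the
        parsimonious solution's total |v| is the minimum over all of them."""
        sol = pfba(detour_network)
        model = detour_network
        S = model.stoichiometric_matrix()
        c = np.array([1.0 if r == "EX_B" else 0.0 for r in model.reaction_ids])
        A = np.vstack([S, c])
        b = np.concatenate([np.zeros(S.shape[0]), [sol.objective_value]])
        lb = np.array([r.lower_bound for r in model.reactions])
        ub = np.array([r.upper_bound for r in model.reactions])
        vertices = enumerate_vertices(A, b, lb, ub)
        assert vertices, "oracle found no optimal vertices"
        total = sum(abs(v) for v in sol.fluxes.values())
        best = min(np.abs(v).sum() for v in vertices)
        assert total <= best + 1e-6
        assert total == pytest.approx(3.0, abs=1e-6)  # EX_A + DIRECT + EX_B

    def test_infeasible_propagates(self, toy_chain):
        cons = ConstraintSet(fixed_fluxes={"EX_B": 2.0})
        assert pfba(toy_chain, constraints=cons).status == "infeasible"


class TestActiveReactions:
    def test_exchanges_never_counted(self, toy_chain):
        sol = solve_fba(toy_chain)
        assert active_reactions(sol, toy_chain) == {"AB"}

    def test_zero_solution_empty(self, toy_chain):
        cons = ConstraintSet(fixed_fluxes={"EX_A": 0.0})
        sol = solve_fba(toy_chain, constraints=cons)
        assert active_reactions(sol, toy_chain) == set()

    def test_huge_tolerance_empty(self, toy_chain):
        sol = solve_fba(toy_chain)
        assert active_reactions(sol, toy_chain, tol=10.0) == set()

    def test_non_optimal_solution_rejected(self, toy_chain):
        cons = ConstraintSet(fixed_fluxes={"EX_B": 2.0})
        sol = solve_fba(toy_chain, constraints=cons)
        with pytest.raises(FBAError):
            active_reactions(sol, toy_chain)


class TestProductionRate:
    def test_chain_terminal_metabolite(self, toy_chain):
        sol = solve_fba(toy_chain)
        assert production_rate(sol, toy_chain, "B") == pytest.approx(1.0)

    def test_unknown_metabolite_raises(self, toy_chain):
        sol = solve_fba(toy_chain)
        with pytest.raises(KeyError):
            production_rate(sol, toy_chain, "Z")

    def test_production_equals_consumption_at_steady_state(self, core_model):
        cons = ConstraintSet(fixed_fluxes={"BIOMASS": 0.1, "DM_phb": 0.2})
        sol = pfba(core_model, {"EX_succ": 1.0}, "max", cons)
        for met in core_model.metabolites:
            if met.compartment != "c" or met.id == "biomass_c":
                continue
            produced = production_rate(sol, core_model, met.id)
            consumed = -sum(
                min(rxn.stoichiometry.get(met.id, 0.0) * sol.fluxes[rxn.id], 0.0)
                for rxn in core_model.reactions
            )
            assert produced == pytest.approx(consumed, abs=1e-7), met.id


class TestOracleEquivalence:
    def test_core_model_phase_one_matches_reference(self, core_model):
        cons = ConstraintSet(fixed_fluxes={"BIOMASS": 0.0, "DM_phb": 1.63})
        ours = solve_fba(core_model, {"EX_succ": 1.0}, "max", cons)
        status, ref = cobra_optimum(core_model, {"EX_succ": 1.0}, "max", cons)
        assert ours.status == status == "optimal"
        assert ours.objective_value == pytest.approx(ref, abs=1e-6)

    def test_random_networks_match_reference(self):
        rng = np.random.default_rng(20210809)
        n_checked = 0
        for _ in range(20):
            model, objective = random_network(rng)
            ours = solve_fba(model, objective, "max")
            status, ref = cobra_optimum(model, objective, "max")
            assert ours.status == status, model.id
            if status == "optimal":
                assert ours.objective_value == pytest.approx(ref, abs=1e-6)
                n_checked += 1
        assert n_checked >= 10  # most random draws must be solvable


class TestMonotonicityAndScaling:
    def _min_uptake(self, core_model, growth=0.0, phb=1.63, maintenance=7.5):
        cons = ConstraintSet(
            fixed_fluxes={"BIOMASS": growth, "DM_phb": phb},
            bound_overrides={"ATPM": (maintenance, np.inf)},
        )
        sol = solve_fba(core_model, {"EX_succ": 1.0}, "max", cons)
        assert sol.status == "optimal"
        return -sol.objective_value

    @pytest.mark.parametrize(
        "param,values",
        [("phb", [0.0, 0.5, 1.0, 1.63, 2.5]),
         ("growth", [0.0, 0.05, 0.1, 0.2, 0.3]),
         ("maintenance", [0.0, 5.0, 7.5, 15.0, 30.0])],
    )
    def test_minimal_uptake_nondecreasing_in_each_demand(self, core_model,
                                                         param, values):
        uptakes = [self._min_uptake(core_model, **{param: v}) for v in values]
        assert all(b >= a - 1e-8 for a, b in zip(uptakes, uptakes[1:]))

    def test_doubling_all_demands_doubles_minimal_uptake(self, core_model):
        base = self._min_uptake(core_model, growth=0.1, phb=0.8, maintenance=7.5)
        double = self._min_uptake(core_model, growth=0.2, phb=1.6, maintenance=15.0)
        assert double == pytest.approx(2 * base, rel=1e-8)


def test_flux_table_format(toy_chain):
    sol = solve_fba(toy_chain)
    table = flux_table(sol)
    lines = table.strip().splitlines()
    assert lines[0] == "reaction_id\tflux"
    assert len(lines) == 4
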