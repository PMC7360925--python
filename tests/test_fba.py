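"""LP engine: FBA, pFBA, FVA, balance checking, solver-independence."""

import math

import numpy as np
import pytest

from symbiofba import (
    Metabolite,
    OrganismModel,
    Reaction,
    ReactionKind,
    ToyParams,
    assemble_community,
    check_balance,
    flux_variability,
    make_toy_symbiosis,
    solve_fba,
    solve_pfba,
)
from symbiofba.fba import FluxSolution
from symbiofba.synth import random_network

from _oracles import pfba_vertex_oracle


class TestSolveFBA:
    def test_max_histidine_delivery_hits_closed_form(self, toy):
        """With the host demand relaxed to a free sink, max deliverable
        histidine is capped only by precursor uptake minus self-uses."""
        relaxed_host = toy.host.with_reaction_bounds("DM_his", 0.0, 1000.0)
        spec = toy.spec(None)
        from symbiofba import CommunitySpec, Medium

        spec = CommunitySpec(
            host=relaxed_host,
            symbionts=spec.symbionts,
            medium=spec.medium,
            reference=spec.reference,
        )
        community = assemble_community(spec)
        sink = community.reaction_of("DM_his", "host")
        sol = solve_fba(community, objective={sink: 1.0}, sense="max").require_optimal()
        # every mmol of precursor yields one histidine; a + b are pinned uses
        expected = toy.params.uptake_cap - toy.params.b
        assert sol.objective_value == pytest.approx(expected, abs=1e-9)

    def test_demand_free_zero_bounds_gives_zero_flux(self):
        model = OrganismModel.from_parts(
            id="frozen",
            metabolites=[Metabolite("A")],
            reactions=[Reaction("EX_A", {"A": -1.0}, lb=0.0, ub=0.0, kind=ReactionKind.EXCHANGE)],
        )
        sol = solve_fba(model, objective={}, sense="max")
        assert sol.status == "optimal"
        assert all(v == 0.0 for v in sol.fluxes.values())

    def test_infeasibility_is_reported_not_silenced(self, toy):
        from symbiofba import Medium, apply_medium

        starved = apply_medium(assemble_community(toy.spec(None)), Medium({}))
        sol = solve_fba(starved, objective={}, sense="max")
        assert sol.status == "infeasible"
        assert sol.fluxes == {}
        assert math.isnan(sol.objective_value)


class TestSolvePFBA:
    def test_baseline_hisd_flux_is_host_demand(self, two_compartment, toy):
        sol = solve_pfba(two_compartment, objective={}).require_optimal()
        rid = two_compartment.reaction_of("HisD", "Buchnera")
        assert sol.fluxes[rid] == pytest.approx(toy.v_his(0.0), abs=1e-9)

    def test_trio_at_one_to_five_matches_analytic(self, toy):
        community = assemble_community(toy.spec(5.0))
        sol = solve_pfba(community, objective={}).require_optimal()
        rid = community.reaction_of("HisD", "Buchnera")
        assert sol.fluxes[rid] == pytest.approx(1.268, abs=1e-9)

    def test_no_gratuitous_secretion(self, three_compartment):
        """Parsimony forbids pointless histidine export to the environment."""
        sol = solve_pfba(three_compartment, objective={}).require_optimal()
        assert sol.fluxes[three_compartment.pool_exchanges["his"]] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_matches_vertex_enumeration_on_small_networks(self, seed):
        model = random_network(seed, n_mets=5, n_rxns=7)
        sol = solve_pfba(model, objective={}).require_optimal()
        oracle_total, _ = pfba_vertex_oracle(model)
        assert sol.objective_value == pytest.approx(oracle_total, abs=1e-6)

    def test_matches_cobra_fba_objective(self):
        """Independent solver route: cobra/GLPK agrees on the FBA optimum."""
        cobra = pytest.importorskip("cobra")
        model = random_network(11, n_mets=5, n_rxns=7)
        target = sorted(model.reactions)[0]
        ours = solve_fba(model, objective={target: 1.0}, sense="max").require_optimal()

        cm = cobra.Model("x")
        mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
        for rid, rx in model.reactions.items():
            cr = cobra.Reaction(rid)
            cm.add_reactions([cr])
            cr.add_metabolites({mets[k]: v for k, v in rx.stoich.items()})
            cr.bounds = (rx.lb, rx.ub)
        cm.objective = cm.reactions.get_by_id(target)
        assert ours.objective_value == pytest.approx(cm.slim_optimize(), abs=1e-6)

    def test_determinism_bit_for_bit(self, three_compartment):
        a = solve_pfba(three_compartment, objective={})
        b = solve_pfba(three_compartment, objective={})
        assert a.fluxes == b.fluxes
        assert a.objective_value == b.objective_value

    def test_scale_invariance(self):
        """Scaling all demands and caps by k scales every flux by k."""
        base = make_toy_symbiosis(ToyParams(h_A=0.8, a=0.5, h_H=0.05, uptake_cap=10.0))
        k = 3.0
        scaled = make_toy_symbiosis(ToyParams(h_A=0.8 * k, a=0.5 * k, h_H=0.05 * k, uptake_cap=10.0 * k))
        sol_b = solve_pfba(assemble_community(base.spec(2.0)), objective={}).require_optimal()
        sol_s = solve_pfba(assemble_community(scaled.spec(2.0)), objective={}).require_optimal()
        for rid, v in sol_b.fluxes.items():
            assert sol_s.fluxes[rid] == pytest.approx(k * v, abs=1e-8)


class TestFluxVariability:
    def test_hisd_unique_at_strict_parsimony(self, two_compartment):
        rid = two_compartment.reaction_of("HisD", "Buchnera")
        fva = flux_variability(two_compartment, [rid], gamma=0.0)
        lo, hi = fva[rid]
        assert lo == pytest.approx(1.0, abs=1e-7)
        assert hi == pytest.approx(1.0, abs=1e-7)

    def test_unneeded_free_sink_pinned_to_zero(self, two_compartment):
        """A free sink carrying no demand stays at 0 inside the pFBA envelope."""
        rid = two_compartment.reaction_of("SINK_aicar", "host")
        fva = flux_variability(two_compartment, [rid], gamma=0.0)
        lo, hi = fva[rid]
        assert (lo, hi) == (pytest.approx(0.0, abs=1e-7), pytest.approx(0.0, abs=1e-7))

    def test_gamma_widens_or_preserves_intervals(self, three_compartment):
        rids = list(three_compartment.pool_transports.values())
        tight = flux_variability(three_compartment, rids, gamma=0.0)
        loose = flux_variability(three_compartment, rids, gamma=0.1)
        for rid in rids:
            assert loose[rid][0] <= tight[rid][0] + 1e-9
            assert loose[rid][1] >= tight[rid][1] - 1e-9


class TestCheckBalance:
    def test_pfba_solutions_are_balanced(self, three_compartment):
        sol = solve_pfba(three_compartment, objective={}).require_optimal()
        assert check_balance(three_compartment, sol) == {}

    def test_corrupted_flux_reports_exact_metabolites(self, two_compartment):
        sol = solve_pfba(two_compartment, objective={}).require_optimal()
        rid = two_compartment.reaction_of("HisD", "Buchnera")
        fluxes = dict(sol.fluxes)
        fluxes[rid] += 0.5  # breaks every metabolite HisD touches
        corrupt = FluxSolution(status="optimal", objective_value=sol.objective_value, fluxes=fluxes)
        report = check_balance(two_compartment, corrupt)
        touched = set(two_compartment.model.reactions[rid].stoich)
        assert set(report) == touched

    def test_infinite_tolerance_reports_nothing(self, two_compartment):
        sol = solve_pfba(two_compartment, objective={}).require_optimal()
        rid = two_compartment.reaction_of("HisD", "Buchnera")
        fluxes = dict(sol.fluxes)
        fluxes[rid] += 0.5
        corrupt = FluxSolution(status="optimal", objective_value=0.0, fluxes=fluxes)
        assert check_balance(two_compartment, corrupt, eps=np.inf) == {}
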