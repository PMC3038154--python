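"""Single flux-balance optimizations: objective values frozen from
hand enumeration of the fixture pathways, plus the contract properties."""

import math

import pytest

from fluxseries import (
    AlgorithmParams,
    ConstraintSet,
    FluxDistribution,
    Metabolite,
    Network,
    Objective,
    Reaction,
    Status,
    ThermoConfig,
    compute_fba_t_c,
    expression_match,
    fba_maximize,
    fitness_maximization,
    flux_minimization,
    mfa_fit,
    moma_l1,
    post_check,
    room,
)
from fluxseries.fixtures import make_chain, make_loop, make_parallel


def assert_steady_state(net, dist, tol=1e-6):
    for mid in net.internal_metabolite_ids():
        acc = sum(
            rxn.stoichiometry.get(mid, 0.0) * dist.fluxes[rid]
            for rid, rxn in net.reactions.items()
        )
        assert abs(acc) <= tol, f"mass balance violated at {mid}"
    for rid, rxn in net.reactions.items():
        assert rxn.lower_bound - tol <= dist.fluxes[rid] <= rxn.upper_bound + tol


class TestFbaMaximize:
    def test_chain_forces_equal_fluxes(self, chain):
        dist = fba_maximize(chain, {"EX_C": 1.0})
        assert dist.objective_value == pytest.approx(10.0)
        assert all(v == pytest.approx(10.0) for v in dist.fluxes.values())
        assert_steady_state(chain, dist)

    def test_zero_capacity_reaction(self, chain):
        chain.reactions["EX_C"].upper_bound = 0.0
        dist = fba_maximize(chain, {"EX_C": 1.0})
        assert dist.objective_value == pytest.approx(0.0)

    def test_unbounded_cycle(self, loop):
        loop.reactions["R1"].upper_bound = math.inf
        loop.reactions["R2"].upper_bound = math.inf
        loop.reactions["R3"].upper_bound = math.inf
        dist = fba_maximize(loop, {"R1": 1.0})
        assert dist.status is Status.UNBOUNDED
        assert dist.fluxes == {}

    def test_unknown_objective_reaction(self, chain):
        with pytest.raises(KeyError):
            fba_maximize(chain, {"nope": 1.0})


class TestFluxMinimization:
    def test_chain_with_fixed_demand(self, chain):
        dist = flux_minimization(chain, ConstraintSet(flux_fixes={"EX_C": 1.0}))
        assert dist.objective_value == pytest.approx(4.0)
        assert all(v == pytest.approx(1.0) for v in dist.fluxes.values())

    def test_parallel_prefers_short_pathway(self, parallel):
        # two extreme pathways: direct (3 steps) vs via X (4 steps)
        dist = flux_minimization(parallel, ConstraintSet(flux_fixes={"EX_B": 1.0}))
        assert dist.objective_value == pytest.approx(3.0)
        assert dist.fluxes["R1"] == pytest.approx(1.0)

    def test_weights_reroute_the_optimum(self, parallel):
        parallel.reactions["R1"].weight = 5.0
        dist = flux_minimization(parallel, ConstraintSet(flux_fixes={"EX_B": 1.0}))
        assert dist.objective_value == pytest.approx(4.0)  # 4 < 7
        assert dist.fluxes["R1"] == pytest.approx(0.0)
        assert dist.fluxes["R2a"] == pytest.approx(1.0)

    def test_no_demand_returns_zero_flux(self, chain):
        dist = flux_minimization(chain)
        assert dist.objective_value == pytest.approx(0.0)

    def test_infeasible_demand_is_a_result(self, chain):
        dist = flux_minimization(chain, ConstraintSet(flux_fixes={"EX_C": 99.0}))
        assert dist.status is Status.INFEASIBLE
        assert dist.fluxes == {}

    def test_objective_monotone_in_weights(self, parallel):
        cs = ConstraintSet(flux_fixes={"EX_B": 1.0})
        base = flux_minimization(parallel, cs).objective_value
        parallel.reactions["R2a"].weight = 0.1
        cheaper = flux_minimization(parallel, cs).objective_value
        assert cheaper <= base + 1e-9


REF_R1_PATH = FluxDistribution(
    Status.OPTIMAL,
    {"EX_A": 1.0, "R1": 1.0, "R2a": 0.0, "R2b": 0.0, "EX_B": 1.0},
    3.0,
)


class TestMomaL1:
    def test_feasible_reference_has_zero_distance(self, parallel):
        dist = moma_l1(
            parallel, REF_R1_PATH, ConstraintSet(flux_fixes={"EX_B": 1.0})
        )
        assert dist.objective_value == pytest.approx(0.0)
        assert dist.fluxes == pytest.approx(REF_R1_PATH.fluxes)

    def test_knockout_reroutes_at_distance_three(self, parallel):
        # post-knockout the flux space is one-dimensional:
        # R1: 1->0, R2a: 0->1, R2b: 0->1
        dist = moma_l1(
            parallel,
            REF_R1_PATH,
            ConstraintSet(knockouts={"R1"}, flux_fixes={"EX_B": 1.0}),
        )
        assert dist.objective_value == pytest.approx(3.0)

    def test_zero_reference_equals_flux_minimization(self, parallel):
        zero_ref = FluxDistribution(
            Status.OPTIMAL, {r: 0.0 for r in parallel.reactions}, 0.0
        )
        cs = ConstraintSet(flux_fixes={"EX_B": 1.0})
        a = moma_l1(parallel, zero_ref, cs)
        b = flux_minimization(parallel, cs)
        assert a.objective_value == pytest.approx(b.objective_value)

    def test_non_optimal_reference_rejected(self, parallel):
        with pytest.raises(ValueError):
            moma_l1(parallel, FluxDistribution(Status.INFEASIBLE), None)


class TestRoom:
    def test_no_perturbation_no_changes(self, parallel):
        dist = room(
            parallel, REF_R1_PATH, ConstraintSet(flux_fixes={"EX_B": 1.0})
        )
        assert dist.objective_value == 0

    def test_knockout_changes_three_fluxes(self, parallel):
        # frozen from brute force over all 2^5 binary patterns
        dist = room(
            parallel,
            REF_R1_PATH,
            ConstraintSet(knockouts={"R1"}, flux_fixes={"EX_B": 1.0}),
            AlgorithmParams(room_delta=0.0, room_epsilon=0.001),
        )
        assert dist.objective_value == 3

    def test_wide_tolerance_absorbs_the_reroute(self, parallel):
        dist = room(
            parallel,
            REF_R1_PATH,
            ConstraintSet(knockouts={"R1"}, flux_fixes={"EX_B": 1.0}),
            AlgorithmParams(room_delta=1.0, room_epsilon=1.0),
        )
        assert dist.objective_value == 0


class TestFitness:
    def test_unconstrained_targets_reach_full_fitness(self, chain):
        dist = fitness_maximization(chain, {"EX_C": (1.0, 1.0)})
        assert dist.objective_value == pytest.approx(1.0)

    def test_inhibition_cap_propagates(self, chain):
        # alpha=0.05 on R1 with bound magnitude 10 caps the chain at 0.5
        dist = fitness_maximization(
            chain, {"EX_C": (1.0, 1.0)}, {"R1": 0.05}
        )
        assert dist.objective_value == pytest.approx(0.5)

    def test_blocked_pathway_zero_fitness(self, chain):
        dist = fitness_maximization(chain, {"EX_C": (1.0, 1.0)}, {"R1": 0.0})
        assert dist.objective_value == pytest.approx(0.0)

    def test_anti_monotone_in_alpha(self, chain):
        values = [
            fitness_maximization(
                chain, {"EX_C": (1.0, 2.0)}, {"R1": alpha}
            ).objective_value
            for alpha in (1.0, 0.5, 0.1, 0.05, 0.0)
        ]
        assert values == sorted(values, reverse=True)
        assert all(0.0 <= f <= 1.0 for f in values)

    def test_zero_reference_rate_rejected(self, chain):
        with pytest.raises(ValueError, match="zero reference"):
            fitness_maximization(chain, {"EX_C": (1.0, 0.0)})

    def test_alpha_outside_unit_interval_rejected(self, chain):
        with pytest.raises(ValueError, match="alpha"):
            fitness_maximization(chain, {"EX_C": (1.0, 1.0)}, {"R1": 1.5})


class TestExpressionMatch:
    def test_all_high_chain_fully_agrees(self, chain):
        dist, agreement = expression_match(
            chain, {r: "HIGH" for r in chain.reactions}
        )
        assert agreement == 4
        params = AlgorithmParams()
        assert all(
            abs(v) >= params.activity_eps - 1e-9 for v in dist.fluxes.values()
        )

    def test_dead_end_reaction_cannot_agree(self, chain):
        chain.add_metabolite(Metabolite("D"))
        chain.add_reaction(
            Reaction("R_dead", {"C": -1.0, "D": 1.0}, upper_bound=10.0)
        )
        states = {r: "HIGH" for r in ("EX_A", "R1", "R2", "EX_C", "R_dead")}
        _, agreement = expression_match(chain, states)
        assert agreement == 4  # R_dead is blocked, v = 0 forced

    def test_empty_states_reduce_to_flux_minimization(self, chain):
        cs = ConstraintSet(flux_fixes={"EX_C": 1.0})
        dist, agreement = expression_match(chain, {}, cs)
        assert agreement == 0
        assert dist.objective_value == pytest.approx(
            flux_minimization(chain, cs).objective_value
        )

    def test_low_states_silence_a_branch(self, parallel):
        dist, agreement = expression_match(
            parallel,
            {"R1": "LOW", "EX_B": "HIGH"},
            ConstraintSet(flux_fixes={"EX_B": 1.0}),
        )
        assert agreement == 2
        assert abs(dist.fluxes["R1"]) <= 1e-6


class TestMfaFit:
    def test_consistent_measurements_fit_exactly(self, chain):
        dist = mfa_fit(chain, {"EX_A": (1.0, 1.0), "EX_C": (1.0, 1.0)})
        assert dist.objective_value == pytest.approx(0.0)
        assert all(v == pytest.approx(1.0) for v in dist.fluxes.values())

    def test_inconsistent_measurements_residual(self, chain):
        # the chain forces EX_A = EX_C; best compromise deviates by 1 total
        dist = mfa_fit(chain, {"EX_A": (1.0, 1.0), "EX_C": (2.0, 1.0)})
        assert dist.objective_value == pytest.approx(1.0)

    def test_empty_measurements_rejected(self, chain):
        with pytest.raises(ValueError):
            mfa_fit(chain, {})


class TestThermodynamicFeasibility:
    def test_loop_admits_only_zero_flux(self, loop):
        plain = fba_maximize(loop, {"R1": 1.0})
        assert plain.objective_value == pytest.approx(10.0)
        thermo = compute_fba_t_c(
            loop, Objective("MAX_LINEAR", coefficients={"R1": 1.0})
        )
        assert thermo.status is Status.OPTIMAL
        assert thermo.objective_value <= AlgorithmParams().zero_tol + 1e-9

    def test_positive_cycle_demand_infeasible(self, loop):
        dist = compute_fba_t_c(
            loop, constraints=ConstraintSet(flux_fixes={"R1": 1.0})
        )
        assert dist.status is Status.INFEASIBLE

    @staticmethod
    def two_met_network():
        return Network(
            [Metabolite("A"), Metabolite("B")],
            [
                Reaction("EX_A", {"A": 1.0}, upper_bound=10, is_exchange=True),
                Reaction("RAB", {"A": -1.0, "B": 1.0}, upper_bound=10),
                Reaction("EX_B", {"B": -1.0}, upper_bound=10, is_exchange=True),
            ],
        )

    def test_endergonic_reaction_blocks_forward_flux(self):
        # required ln(c_A/c_B) = 30/2.577 ≈ 11.64 exceeds the window's
        # maximal ratio ln(1e-2/1e-5) ≈ 6.91
        net = self.two_met_network()
        dist = compute_fba_t_c(
            net,
            constraints=ConstraintSet(flux_fixes={"RAB": 1.0}),
            thermo=ThermoConfig(dg0={"RAB": 30.0}),
        )
        assert dist.status is Status.INFEASIBLE

    def test_neutral_reaction_allows_flux_with_witness(self):
        net = self.two_met_network()
        dist = compute_fba_t_c(
            net,
            constraints=ConstraintSet(flux_fixes={"RAB": 1.0}),
            thermo=ThermoConfig(dg0={"RAB": 0.0}),
        )
        assert dist.status is Status.OPTIMAL
        lnc = dist.log_concentrations
        assert lnc is not None and lnc["B"] < lnc["A"]

    def test_attainable_endergonic_flux(self):
        # ΔG°' = 10 needs ln(c_A/c_B) ≥ 3.88, within the 6.91 window
        net = self.two_met_network()
        dist = compute_fba_t_c(
            net,
            constraints=ConstraintSet(flux_fixes={"RAB": 1.0}),
            thermo=ThermoConfig(dg0={"RAB": 10.0}),
        )
        assert dist.status is Status.OPTIMAL


class TestPostCheck:
    def test_own_solutions_pass(self, chain):
        dist = flux_minimization(chain, ConstraintSet(flux_fixes={"EX_C": 1.0}))
        assert post_check(chain, dist).passed

    def test_tampered_mass_balance_names_metabolite(self, chain):
        dist = flux_minimization(chain, ConstraintSet(flux_fixes={"EX_C": 1.0}))
        dist.fluxes["R1"] = 5.0
        report = post_check(chain, dist)
        assert not report.passed
        failed = {item.name for item in report.failures()}
        assert "mass_balance[A]" in failed and "mass_balance[B]" in failed

    def test_loop_solution_fails_thermo_check(self, loop):
        dist = fba_maximize(loop, {"R1": 1.0})
        report = post_check(loop, dist, thermo=ThermoConfig())
        assert not report.passed
        assert any(
            item.name == "thermodynamic_feasibility"
            for item in report.failures()
        )

    def test_thermo_solution_passes_thermo_check(self):
        net = TestThermodynamicFeasibility.two_met_network()
        thermo = ThermoConfig(dg0={"RAB": 10.0})
        dist = compute_fba_t_c(
            net, constraints=ConstraintSet(flux_fixes={"RAB": 1.0}),
            thermo=thermo,
        )
        assert post_check(net, dist, thermo=thermo).passed


def test_every_optimal_result_satisfies_mass_balance_and_bounds(parallel):
    cs = ConstraintSet(flux_fixes={"EX_B": 1.0})
    for dist in (
        flux_minimization(parallel, cs),
        fba_maximize(parallel, {"EX_B": 1.0}),
        moma_l1(parallel, REF_R1_PATH, cs),
        room(parallel, REF_R1_PATH, cs),
    ):
        assert dist.status is Status.OPTIMAL
        assert_steady_state(parallel, dist)


def test_contradictory_constraint_set_is_infeasible(chain):
    dist = flux_minimization(
        chain, ConstraintSet(flux_fixes={"R1": 1.0}, knockouts={"R1"})
    )
    assert dist.status is Status.INFEASIBLE


def test_objective_descriptor_validation():
    with pytest.raises(ValueError, match="requires"):
        Objective(kind="MAX_LINEAR")
    with pytest.raises(ValueError, match="unknown"):
        Objective(kind="QP_MOMA")
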