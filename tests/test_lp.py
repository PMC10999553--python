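"""FBA/FVA/MOMA against brute-force vertex-enumeration and QP oracles."""

import numpy as np
import pytest

from rhizoflux import fba, fva, moma, production_rate
from rhizoflux import synth
from rhizoflux.model import MediaCondition, apply_media

from conftest import fba_oracle, moma_oracle


def steady_state_residual(model, solution):
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    v = np.array([solution.fluxes[r] for r in rxn_ids])
    return float(np.abs(S @ v).max())


ALL_FIXTURES = [
    lambda: synth.make_chain_model(1, 10.0),
    lambda: synth.make_chain_model(3, 2.5),
    lambda: synth.make_branched_model(10.0),
    lambda: synth.make_branched_model(10.0, branch_capacity=(5.0, 5.0)),
    lambda: synth.make_branched_model(10.0, dead_end_branch=True),
    lambda: synth.make_isozyme_model(),
    lambda: synth.make_symbiosis_toy(),
    lambda: synth.make_symbiosis_toy(redundant_fdx_source=False),
]


class TestFBA:
    def test_chain_uptake_limited(self, chain3):
        model, truth = chain3
        sol = fba(model)
        assert sol.ok
        assert sol.objective_value == pytest.approx(truth["optimum"], abs=1e-9)

    def test_closed_uptake_gives_zero(self, chain3):
        model, _ = chain3
        closed = apply_media(model, MediaCondition({}), close_others=True)
        assert fba(closed).objective_value == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("make", ALL_FIXTURES)
    def test_objective_matches_vertex_enumeration_oracle(self, make):
        model, _ = make()
        expected, _ = fba_oracle(model)
        sol = fba(model)
        assert sol.ok
        assert abs(sol.objective_value - expected) < 1e-6

    @pytest.mark.parametrize("make", ALL_FIXTURES)
    def test_steady_state_and_bounds_respected(self, make):
        model, _ = make()
        sol = fba(model)
        assert steady_state_residual(model, sol) < 1e-6
        lb, ub = model.bounds_arrays()
        v = np.array([sol.fluxes[r] for r in model.reaction_ids])
        assert np.all(v >= lb - 1e-6) and np.all(v <= ub + 1e-6)

    def test_infeasible_status(self, chain3):
        model, _ = chain3
        bad = model.copy()
        bad.reactions["R1"].lower_bound = 1.0  # force flux with uptake closed
        bad.reactions["R1"].upper_bound = 1.0
        bad.reactions["EX_A"].lower_bound = 0.0
        sol = fba(bad)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_unknown_objective_rejected(self, chain3):
        model, _ = chain3
        with pytest.raises(KeyError):
            fba(model, objective_id="nope")

    def test_tightening_a_bound_never_raises_the_optimum(self, branched):
        model, _ = branched
        base = fba(model).objective_value
        for frac in (0.75, 0.5, 0.25, 0.0):
            tightened = model.copy()
            tightened.reactions["R1"].upper_bound = 10.0 * frac
            assert fba(tightened).objective_value <= base + 1e-9


class TestFVA:
    def test_unique_optimum_pins_every_reaction(self, chain3):
        model, truth = chain3
        ranges = fva(model, fraction_of_optimum=1.0)
        for rid, (lo, hi) in ranges.items():
            expected = -truth["optimum"] if rid == "EX_A" else truth["optimum"]
            assert lo == pytest.approx(expected, abs=1e-6)
            assert hi == pytest.approx(expected, abs=1e-6)

    def test_fraction_zero_gives_pure_feasibility_range(self, chain3):
        model, _ = chain3
        ranges = fva(model, fraction_of_optimum=0.0)
        assert ranges["EX_A"] == pytest.approx((-10.0, 0.0), abs=1e-6)

    def test_equivalent_branches_span_zero_to_total(self, branched):
        model, truth = branched
        ranges = fva(model, fraction_of_optimum=1.0, reaction_ids=truth["branch_ids"])
        for rid in truth["branch_ids"]:
            lo, hi = ranges[rid]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(truth["optimum"], abs=1e-6)

    @pytest.mark.parametrize("make", ALL_FIXTURES)
    def test_fva_interval_contains_fba_flux(self, make):
        model, _ = make()
        sol = fba(model)
        ranges = fva(model, fraction_of_optimum=1.0)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_bad_fraction_rejected(self, chain3):
        model, _ = chain3
        with pytest.raises(ValueError):
            fva(model, fraction_of_optimum=1.5)


class TestMOMA:
    def test_zero_perturbation_returns_reference(self, branched):
        model, _ = branched
        ref = fba(model).fluxes
        sol = moma(model, ref)
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.0, abs=1e-5)
        for rid, v in ref.items():
            assert sol.fluxes[rid] == pytest.approx(v, abs=1e-4)

    def test_chain_bound_drop_is_analytic(self, chain3):
        # bound 10 -> 5 forces every chain flux to 5; distance 4 * 5^2 = 100
        model, _ = chain3
        ref = fba(model).fluxes
        perturbed = model.copy()
        perturbed.reactions["R1"].upper_bound = 5.0
        sol = moma(perturbed, ref)
        assert sol.ok
        for rid in ("T_A", "R1", "BIO"):
            assert sol.fluxes[rid] == pytest.approx(5.0, abs=1e-5)
        assert sol.fluxes["EX_A"] == pytest.approx(-5.0, abs=1e-5)
        assert sol.objective_value == pytest.approx(100.0, rel=1e-5)

    def test_branch_closure_matches_trust_constr_oracle(self, branched):
        model, _ = branched
        ref = fba(model).fluxes
        perturbed = model.copy()
        perturbed.reactions["R1"].lower_bound = 0.0
        perturbed.reactions["R1"].upper_bound = 0.0
        sol = moma(perturbed, ref)
        expected_dist, expected_flux = moma_oracle(perturbed, ref)
        assert sol.ok
        assert sol.objective_value == pytest.approx(expected_dist, abs=1e-4)
        for rid, v in expected_flux.items():
            assert sol.fluxes[rid] == pytest.approx(v, abs=1e-3)

    def test_infeasible_perturbation_reported(self, chain3):
        model, _ = chain3
        ref = fba(model).fluxes
        perturbed = model.copy()
        perturbed.reactions["EX_A"].lower_bound = 0.0
        perturbed.reactions["R1"].lower_bound = 1.0
        sol = moma(perturbed, ref)
        assert sol.status == "infeasible"


class TestProductionRate:
    def test_single_producer(self, chain3):
        model, _ = chain3
        sol = fba(model)
        assert production_rate(model, sol, ["A_c"]) == pytest.approx(10.0, abs=1e-6)

    def test_untouched_pool_is_zero(self, symbiosis):
        model, _ = symbiosis
        sol = fba(model)
        assert production_rate(model, sol, ["w_c"]) == pytest.approx(0.0, abs=1e-9)

    def test_producer_and_consumer_counts_gross(self, symbiosis):
        # ATP pool: produced 2.5/succ by catabolism, consumed by nitrogenase
        # and the symbiotic drain; gross production is the producing term only
        model, truth = symbiosis
        sol = fba(model)
        assert production_rate(model, sol, ["atp_c"]) == pytest.approx(
            truth["atp_gross_production_at_optimum"], abs=1e-6
        )

    def test_unknown_metabolite_rejected(self, chain3):
        model, _ = chain3
        with pytest.raises(KeyError):
            production_rate(model, fba(model), ["nope"])
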