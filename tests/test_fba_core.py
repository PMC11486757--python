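"""FBA / pFBA correctness against hand solutions, vertex enumeration and cobrapy."""

import numpy as np
import pytest

from chemoflux.exact import alternative_optima_total_flux, brute_force_fba, enumerate_vertices
from chemoflux.fba_core import (
    FbaError,
    MeasuredExchange,
    apply_measured_exchanges,
    build_stoichiometric_matrix,
    exchange_from_specific_rate,
    fba,
    pfba,
)
from chemoflux.model_io import MetabolicModel, Metabolite, Reaction
from chemoflux.species import default_registry
from chemoflux.synthetic_data import ToyModelSpec, make_toy_model


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        model = MetabolicModel(
            metabolites=[Metabolite("A"), Metabolite("B")],
            reactions=[Reaction("R", {"A": -1.0, "B": 1.0})],
            objective_id="R",
        )
        assert np.array_equal(build_stoichiometric_matrix(model), [[-1.0], [1.0]])

    def test_matches_hand_encoded_matrix(self):
        model, _ = make_toy_model(ToyModelSpec(topology="branched_tca", include_ngam=True))
        # rows GLU, AKG, OAA, ATP x cols EX_glu, GDH, TCA, CATA, ATPM, BIOMASS
        expected = np.array(
            [
                [-1, -1, 0, 0, 0, 0],
                [0, 1, -1, 0, 0, 0],
                [0, 0, 1, -1, 0, -1],
                [0, 0, 2, 1, -1, -3],
            ],
            dtype=float,
        )
        assert np.array_equal(build_stoichiometric_matrix(model), expected)

    def test_column_order_follows_declaration_order(self):
        model, _ = make_toy_model(ToyModelSpec(topology="chain"))
        S = build_stoichiometric_matrix(model)
        permuted = model.copy()
        permuted.reactions = permuted.reactions[::-1]
        assert np.array_equal(build_stoichiometric_matrix(permuted), S[:, ::-1])


class TestFba:
    def test_linear_chain_yield(self):
        model, _ = make_toy_model(ToyModelSpec(topology="chain", uptake_bound=10.0, biomass_yield=0.5))
        sol = fba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(5.0, abs=1e-9)

    def test_all_exchanges_closed_gives_zero_growth(self, dual_substrate):
        model, _ = dual_substrate
        closed = apply_measured_exchanges(
            model,
            [MeasuredExchange("EX_glc", fixed_zero=True), MeasuredExchange("EX_glu", fixed_zero=True)],
            ngam=0.0,
        )
        sol = fba(closed)
        assert sol.optimal and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_objective_matches_vertex_enumeration(self, toy_case):
        _, model, _ = toy_case
        sol = fba(model)
        exact_opt, _ = brute_force_fba(model)
        assert sol.objective_value == pytest.approx(exact_opt, abs=1e-6)

    def test_steady_state_residual_and_bounds(self, toy_case):
        _, model, _ = toy_case
        sol = fba(model)
        S = build_stoichiometric_matrix(model)
        v = np.array([sol.fluxes[r] for r in model.reaction_ids()])
        assert np.max(np.abs(S @ v)) <= 1e-6
        for r in model.reactions:
            assert r.lb - 1e-6 <= sol.fluxes[r.id] <= r.ub + 1e-6

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_linear_homogeneity_in_bounds(self, k):
        # no fixed maintenance: scaling all bounds scales the optimum
        model, _ = make_toy_model(ToyModelSpec(topology="chain_detour"))
        scaled = model.copy()
        for r in scaled.reactions:
            r.lb, r.ub = k * r.lb, k * r.ub
        assert fba(scaled).objective_value == pytest.approx(k * fba(model).objective_value, rel=1e-9)


class TestMeasuredExchanges:
    def test_fixed_zero_clamps_flux(self, dual_substrate):
        model, _ = dual_substrate
        constrained = apply_measured_exchanges(model, [MeasuredExchange("EX_ace", fixed_zero=True)])
        sol = pfba(constrained)
        assert sol.fluxes["EX_ace"] == 0.0

    def test_fixed_uptake_is_respected(self, dual_substrate):
        model, _ = dual_substrate
        constrained = apply_measured_exchanges(model, [MeasuredExchange("EX_glc", rate=-10.0)])
        sol = fba(constrained)
        assert sol.fluxes["EX_glc"] == pytest.approx(-10.0, abs=1e-6)

    def test_ngam_above_atp_capacity_is_infeasible(self, dual_substrate):
        # both uptakes at 10 regenerate at most 30 ATP
        model, _ = dual_substrate
        constrained = apply_measured_exchanges(model, [], ngam=35.0)
        assert fba(constrained).status == "infeasible"

    def test_unknown_reaction_lists_candidates(self, dual_substrate):
        model, _ = dual_substrate
        with pytest.raises(FbaError, match="EX_glc"):
            apply_measured_exchanges(model, [MeasuredExchange("EX_gkc", rate=-1.0)])

    def test_positive_uptake_convention_flips_sign(self, dual_substrate):
        model, _ = dual_substrate
        constrained = apply_measured_exchanges(
            model, [MeasuredExchange("EX_glc", rate=10.0)], sign_convention="positive_uptake"
        )
        assert constrained.get_reaction("EX_glc").lb == -10.0

    def test_adapter_converts_mass_rates_to_mmol(self):
        card = default_registry()["glucose"]
        ex = exchange_from_specific_rate("EX_glc", 0.18016, 0.018016, card, uptake=True)
        assert ex.rate == pytest.approx(-1.0)
        assert ex.sd == pytest.approx(0.1)


class TestPfba:
    def test_known_optimum_and_fluxes(self, toy_case):
        name, model, known = toy_case
        sol = pfba(model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(known.objective_value, rel=1e-5)
        for rid, v in known.fluxes.items():
            assert sol.fluxes[rid] == pytest.approx(v, abs=1e-4), (name, rid)

    def test_detour_carries_no_flux(self):
        model, _ = make_toy_model(ToyModelSpec(topology="chain_detour"))
        sol = pfba(model)
        assert sol.fluxes["R_DETOUR1"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["R_DETOUR2"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["R_DIRECT"] == pytest.approx(10.0, abs=1e-6)

    def test_optimality_sandwich(self, toy_case):
        _, model, _ = toy_case
        opt = fba(model)
        par = pfba(model)
        eps = 2e-6 * max(1.0, abs(opt.objective_value))
        assert par.objective_value >= opt.objective_value - eps
        assert par.objective_value <= opt.objective_value + eps
        assert par.total_abs_flux <= opt.total_abs_flux + 1e-6

    def test_total_flux_beats_randomized_alternatives(self, toy_case):
        _, model, _ = toy_case
        opt = fba(model)
        par = pfba(model)
        alternatives = alternative_optima_total_flux(
            model, opt.objective_value, n_perturbations=100, seed=7
        )
        assert alternatives, "no alternative optima found"
        assert all(par.total_abs_flux <= alt + 1e-5 for alt in alternatives)

    def test_infeasibility_is_propagated(self, dual_substrate):
        model, _ = dual_substrate
        constrained = apply_measured_exchanges(model, [], ngam=35.0)
        assert pfba(constrained).status == "infeasible"


class TestVertexEnumeration:
    def test_vertices_are_feasible(self, toy_case):
        _, model, _ = toy_case
        S = build_stoichiometric_matrix(model)
        lb = np.array([r.lb for r in model.reactions])
        ub = np.array([r.ub for r in model.reactions])
        verts = enumerate_vertices(model)
        assert verts
        for v in verts:
            assert np.max(np.abs(S @ v)) <= 1e-7
            assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)

    def test_refuses_large_networks(self):
        model = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[Reaction(f"R{i}", {"A": 1.0 if i % 2 else -1.0}, lb=0, ub=1) for i in range(13)],
            objective_id="R0",
        )
        with pytest.raises(ValueError, match="enumeration"):
            enumerate_vertices(model)


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {m.id: cobra.Metabolite(m.id, compartment=m.compartment or "c") for m in model.metabolites}
    for r in model.reactions:
        rx = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
        cm.add_reactions([rx])
        rx.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
    cm.objective = model.objective_id
    return cm


class TestCobraCrossCheck:
    """Independent implementation agreement on the toy networks."""

    def test_fba_objective_agrees(self, toy_case):
        _, model, _ = toy_case
        ours = fba(model)
        theirs = _to_cobra(model).optimize()
        assert ours.objective_value == pytest.approx(theirs.objective_value, abs=1e-6)

    def test_pfba_fluxes_agree(self, toy_case):
        from cobra.flux_analysis import pfba as cobra_pfba

        _, model, _ = toy_case
        ours = pfba(model)
        theirs = cobra_pfba(_to_cobra(model))
        for rid in model.reaction_ids():
            assert ours.fluxes[rid] == pytest.approx(float(theirs.fluxes[rid]), abs=1e-5), rid
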