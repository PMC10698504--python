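"""FBA/pFBA solver contracts, knockout propagation and the
unconditional-essentiality filter."""

import numpy as np
import pytest

import oracles
from conftest import make_model
from gemeval.fba_core import (
    WILDTYPE,
    apply_knockout,
    find_unconditional_essentials,
    knockout_grid,
    solve_fba,
    solve_pfba,
)
from gemeval.model_io import parse_gpr
from gemeval.synthetic_data import ToyGemConfig, build_toy_gem, toy_scenario


def _stoich_residual(model, fluxes):
    res = {m.id: 0.0 for m in model.metabolites}
    for r in model.reactions:
        v = fluxes[r.id]
        for mid, coef in r.stoichiometry.items():
            res[mid] += coef * v
    return max(abs(x) for x in res.values())


class TestFBA:
    def test_hand_solved_chain_optimum(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        assert _stoich_residual(chain_model, sol.fluxes) <= 1e-6

    def test_closed_exchanges_mean_no_growth(self, chain_model):
        closed = chain_model.update_bounds({"EX_A": (0.0, 1000.0)})
        assert solve_fba(closed).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unproducible_biomass_precursor_gives_zero(self):
        model = make_model(
            {"A_c": "c", "ghostprecursor_c": "c"},
            {"SRC": ({"A_c": 1.0}, 0.0, 10.0, ""),
             "SINK": ({"A_c": -1.0}, 0.0, 1000.0, ""),
             "BIO": ({"A_c": -1.0, "ghostprecursor_c": -1.0}, 0.0, 1000.0, "")},
        )
        assert solve_fba(model).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_optimum_reproducible_across_restarts(self, toy_study):
        import dataclasses
        env = toy_study.model  # solve the same LP from fresh compilations
        vals = [solve_fba(dataclasses.replace(env)).objective_value
                for _ in range(3)]
        assert max(vals) - min(vals) <= 1e-6

    def test_matches_vertex_enumeration_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(40):  # the full 200-network sweep runs in acceptance
            model, S, lb, ub, obj = oracles.random_network(rng)
            got = solve_fba(model).objective_value
            want = oracles.lp_max_by_enumeration(S, lb, ub, obj)
            assert got == pytest.approx(want, abs=1e-6)

    def test_cobra_agrees_on_toy_wildtype(self, toy_study, tmp_path):
        cobra = pytest.importorskip("cobra")
        from gemeval.model_io import write_model
        from gemeval.scenarios import apply_medium, MediumSpec

        env = apply_medium(toy_study.model, MediumSpec(carbon_source="carb01"))
        path = tmp_path / "env.json"
        write_model(env, path)
        cm = cobra.io.load_json_model(str(path))
        assert solve_fba(env).objective_value == \
            pytest.approx(cm.slim_optimize(), abs=1e-6)


class TestPFBA:
    def test_single_route_equals_fba(self, chain_model):
        fba, pfba = solve_fba(chain_model), solve_pfba(chain_model)
        assert pfba.objective_value == pytest.approx(fba.objective_value, abs=1e-6)
        for rid in fba.fluxes:
            assert pfba.fluxes[rid] == pytest.approx(fba.fluxes[rid], abs=1e-6)

    def test_two_routes_take_the_short_one(self, two_route_model):
        sol = solve_pfba(two_route_model)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["DIRECT"] == pytest.approx(10.0, abs=1e-6)
        assert abs(sol.fluxes["DETOUR1"]) <= 1e-6
        # total flux must not exceed any enumerated alternative optimum
        S = np.zeros((4, 6))
        rids = [r.id for r in two_route_model.reactions]
        mids = [m.id for m in two_route_model.metabolites]
        for j, r in enumerate(two_route_model.reactions):
            for mid, c in r.stoichiometry.items():
                S[mids.index(mid), j] = c
        lb = np.array([r.lower_bound for r in two_route_model.reactions])
        ub = np.array([min(r.upper_bound, 50.0) for r in two_route_model.reactions])
        alts = oracles.alternative_optima_vertices(S, lb, ub,
                                                   rids.index("BIO"), 10.0)
        assert alts, "oracle found no alternative optima"
        total = sum(abs(v) for v in sol.fluxes.values())
        assert total <= min(np.abs(a).sum() for a in alts) + 1e-6

    def test_detached_reversible_cycle_carries_no_flux(self, chain_model):
        from dataclasses import replace
        from gemeval.model_io import Metabolite, Reaction

        mets = chain_model.metabolites + (Metabolite("X_c", compartment="c"),
                                          Metabolite("Y_c", compartment="c"))
        rxns = chain_model.reactions + (
            Reaction("CYC1", {"X_c": -1.0, "Y_c": 1.0}, -50.0, 50.0),
            Reaction("CYC2", {"Y_c": -1.0, "X_c": 1.0}, -50.0, 50.0),
        )
        model = replace(chain_model, metabolites=mets, reactions=rxns)
        sol = solve_pfba(model)
        assert abs(sol.fluxes["CYC1"]) <= 1e-6
        assert abs(sol.fluxes["CYC2"]) <= 1e-6

    def test_total_flux_not_above_plain_fba(self, toy_study):
        from gemeval.scenarios import apply_medium, MediumSpec

        env = apply_medium(toy_study.model, MediumSpec(carbon_source="carb02"))
        fba, pfba = solve_fba(env), solve_pfba(env)
        assert pfba.objective_value == pytest.approx(fba.objective_value, abs=1e-6)
        assert sum(map(abs, pfba.fluxes.values())) <= \
            sum(map(abs, fba.fluxes.values())) + 1e-6


class TestKnockout:
    @pytest.mark.parametrize("gpr,ko,disabled", [
        ("gA or gB", {"gA"}, False),
        ("gA and gB", {"gA"}, True),
        ("(gA and gB) or (gA and gC)", {"gA"}, True),
        ("(gA and gB) or (gA and gC)", {"gB"}, False),
        ("", {"gA"}, False),
    ])
    def test_boolean_propagation(self, gpr, ko, disabled):
        model = make_model(
            {"A_c": "c"},
            {"R": ({"A_c": 1.0}, 0.0, 10.0, gpr),
             "BIO": ({"A_c": -1.0}, 0.0, 1000.0, "")},
        )
        genes = frozenset({"gA", "gB", "gC"} | model.genes)
        import dataclasses
        model = dataclasses.replace(model, genes=genes)
        ko_model = apply_knockout(model, ko)
        r = ko_model.reaction("R")
        assert ((r.lower_bound, r.upper_bound) == (0.0, 0.0)) is disabled

    def test_unknown_gene_raises(self, chain_model):
        with pytest.raises(KeyError):
            apply_knockout(chain_model, {"ghost"})

    def test_locality_and_no_mutation(self, toy_study):
        model = toy_study.model
        ko = apply_knockout(model, {"g_c01_1"})
        changed = [r.id for r, k in zip(model.reactions, ko.reactions)
                   if (r.lower_bound, r.upper_bound)
                   != (k.lower_bound, k.upper_bound)]
        assert changed == ["CARB01_S1"]
        assert model.reaction("CARB01_S1").upper_bound > 0  # input untouched

    def test_disabling_reactions_never_raises_optimum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            model, *_ = oracles.random_network(rng)
            base = solve_fba(model).objective_value
            kill = rng.choice([r.id for r in model.reactions],
                              size=rng.integers(1, 3), replace=False)
            reduced = model.update_bounds({rid: (0.0, 0.0) for rid in kill})
            assert solve_fba(reduced).objective_value <= base + 1e-6


class TestGrid:
    def test_grid_shape_and_wildtype_rows(self, toy_study):
        genes = ["g_c01_1", "g_c02_1", "g_iso1_main", "g_v1_1"]
        carbons = ["carb01", "carb02"]
        table, _ = knockout_grid(toy_study.model, genes, carbons,
                                 toy_study.scenario)
        assert len(table) == len(genes) * len(carbons) + len(carbons)
        assert (table["gene"] == WILDTYPE).sum() == len(carbons)
        assert table[table["gene"] == WILDTYPE]["fitness"].isna().all()

    def test_noop_knockout_matches_wildtype(self, toy_study):
        table, _ = knockout_grid(toy_study.model, ["g_iso1_main"],
                                 ["carb01", "carb03"], toy_study.scenario)
        wt = table[table["gene"] == WILDTYPE].set_index("carbon")["biomass_flux"]
        ko = table[table["gene"] == "g_iso1_main"].set_index("carbon")["biomass_flux"]
        for c in ("carb01", "carb03"):
            assert ko[c] == pytest.approx(wt[c], abs=1e-6)

    def test_transporter_knockout_is_carbon_specific(self, toy_study):
        table, _ = knockout_grid(toy_study.model, ["g_c01_1"],
                                 ["carb01", "carb02"], toy_study.scenario)
        sub = table[table["gene"] == "g_c01_1"].set_index("carbon")
        assert not sub.loc["carb01", "grows"]
        assert sub.loc["carb02", "grows"]

    def test_rerun_is_deterministic(self, toy_study):
        args = (toy_study.model, ["g_c01_1", "g_v1_1"], ["carb01"],
                toy_study.scenario)
        t1, _ = knockout_grid(*args)
        t2, _ = knockout_grid(*args)
        assert t1.equals(t2)


class TestUnconditionalEssentials:
    def test_toy_vitamin_genes_are_rescued_by_open_exchanges(self, toy_study):
        # every vitamin has an (ordinarily closed) extracellular supply
        # route, so opening all exchanges rescues their biosynthesis genes
        ess = find_unconditional_essentials(toy_study.model)
        assert ess == set()

    def test_gene_without_import_rescue_is_unconditional(self):
        model = make_model(
            {"A_e": "e", "A_c": "c", "B_c": "c"},
            {"EX_A": ({"A_e": -1.0}, 0.0, 1000.0, ""),
             "T_A": ({"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, ""),
             "MAKE_B": ({"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, "gOnly"),
             "BIO": ({"B_c": -1.0}, 0.0, 1000.0, "")},
        )
        assert find_unconditional_essentials(model) == {"gOnly"}

    def test_rescued_and_orphan_genes_excluded(self):
        model = make_model(
            {"V_e": "e", "V_c": "c"},
            {"EX_V": ({"V_e": -1.0}, 0.0, 1000.0, ""),
             "T_V": ({"V_e": -1.0, "V_c": 1.0}, 0.0, 1000.0, ""),
             "SYN_V": ({"V_c": 1.0}, 0.0, 1000.0, "gSyn"),
             "BIO": ({"V_c": -1.0}, 0.0, 1000.0, "")},
        )
        import dataclasses
        model = dataclasses.replace(model, genes=model.genes | {"gOrphan"})
        assert find_unconditional_essentials(model) == set()
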