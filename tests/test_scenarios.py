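"""Media construction and the correction classes (supplements,
irreversibilization, isoenzyme reassignment, strain genes, fixed flux)."""

from dataclasses import replace

import pytest

from conftest import make_model
from gemeval.fba_core import WILDTYPE, apply_knockout, knockout_grid, solve_fba
from gemeval.model_io import GeneLiteral, GPRExpression
from gemeval.pipeline import evaluate_predictions, run_simulation
from gemeval.scenarios import (
    MediumSpec,
    ScenarioSpec,
    add_supplement,
    apply_medium,
    apply_scenario,
    fix_flux,
    reassign_isoenzyme,
    remove_strain_genes,
    set_irreversible,
)
from gemeval.synthetic_data import FitnessGenConfig, ToyGemConfig, build_toy_gem, \
    simulate_fitness, toy_scenario


def _ko_grows(model, gene, carbon, scenario=None, **kw):
    table, _ = knockout_grid(model, [gene], [carbon],
                             scenario or toy_scenario(), **kw)
    return bool(table.loc[table["gene"] == gene, "grows"].iloc[0])


class TestMedium:
    def test_components_opened_and_carbon_limited(self, toy_study):
        med = MediumSpec(components={"EX_vit1_e": -1000.0},
                         carbon_source="carb01")
        env = apply_medium(toy_study.model, med)
        assert env.reaction("EX_vit1_e").lower_bound == -1000.0
        assert env.reaction("EX_carb01_e").lower_bound == -10.0
        # every other exchange closed
        assert env.reaction("EX_carb02_e").lower_bound == 0.0

    def test_carbon_bound_wins_on_collision(self, toy_study):
        med = MediumSpec(components={"EX_carb01_e": -1000.0},
                         carbon_source="carb01")
        env = apply_medium(toy_study.model, med)
        assert env.reaction("EX_carb01_e").lower_bound == -10.0

    def test_empty_medium_closes_everything(self, toy_study):
        env = apply_medium(toy_study.model, MediumSpec())
        assert all(r.lower_bound == 0.0 for r in env.exchanges)
        assert solve_fba(env).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_unknown_component_is_an_error(self, toy_study):
        with pytest.raises(KeyError, match="unobtainium"):
            apply_medium(toy_study.model,
                         MediumSpec(components={"unobtainium": -1000.0}))

    def test_positive_component_bound_rejected(self):
        with pytest.raises(ValueError):
            MediumSpec(components={"EX_x": 5.0})


class TestSupplements:
    def test_extracellular_supplement_rescues_vitamin_knockout(self, toy_study):
        model = toy_study.model  # vit1 has exchange + transporter
        assert not _ko_grows(model, "g_v1_1", "carb01")
        supp = add_supplement(model, "vit1_e", "extracellular")
        scen = replace(toy_scenario(),
                       supplements=(("vit1_e", "extracellular"),))
        assert _ko_grows(model, "g_v1_1", "carb01", scen)
        assert supp.reaction("EX_vit1_e").lower_bound == -1000.0

    def test_intracellular_supplement_creates_uptake_only_exchange(self, toy_study):
        model = toy_study.model  # vit3 has no transporter
        scen = replace(toy_scenario(),
                       supplements=(("vit3_c", "intracellular"),))
        assert not _ko_grows(model, "g_v3_1", "carb01")
        assert _ko_grows(model, "g_v3_1", "carb01", scen)
        supp = add_supplement(model, "vit3_c", "intracellular")
        ex = supp.reaction("EX_vit3_c_supplement")
        assert (ex.lower_bound, ex.upper_bound) == (-1000.0, 0.0)
        assert ex.is_exchange

    def test_extracellular_mode_without_exchange_suggests_intracellular(self, toy_study):
        with pytest.raises(KeyError, match="intracellular"):
            add_supplement(toy_study.model, "vit3_c", "extracellular")

    def test_supplement_is_idempotent(self, toy_study):
        once = add_supplement(toy_study.model, "vit1_e", "extracellular")
        twice = add_supplement(once, "vit1_e", "extracellular")
        assert once == twice
        once_i = add_supplement(toy_study.model, "vit3_c", "intracellular")
        twice_i = add_supplement(once_i, "vit3_c", "intracellular")
        assert once_i == twice_i

    def test_each_supplement_individually_then_all_together(self, toy_study):
        # per-vitamin supplementation rescues exactly that pathway's genes
        supplements = toy_study.truth.corrections["supplements"]
        assert len(supplements) == 5
        for j, (met, mode) in enumerate(supplements, start=1):
            scen = replace(toy_scenario(), supplements=((met, mode),))
            assert _ko_grows(toy_study.model, f"g_v{j}_1", "carb01", scen)
            other = 1 if j != 1 else 2
            assert not _ko_grows(toy_study.model, f"g_v{other}_1", "carb01", scen)
        all_scen = replace(toy_scenario(), supplements=tuple(supplements))
        for j in range(1, 6):
            assert _ko_grows(toy_study.model, f"g_v{j}_1", "carb01", all_scen)


class TestIrreversible:
    def test_bypass_irreversibilization_restores_essentiality(self, toy_study):
        model = toy_study.model
        assert _ko_grows(model, "g_byp_1", "carb01")
        scen = replace(toy_scenario(),
                       irreversibilized_reactions=("SER_GLY_REV",))
        assert not _ko_grows(model, "g_byp_1", "carb01", scen)

    def test_already_irreversible_is_noop(self, toy_study):
        m1 = set_irreversible(toy_study.model, "CARB01_S1")
        assert m1 == toy_study.model

    def test_biomass_allowed_with_warning(self, toy_study, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="gemeval.scenarios"):
            bio_rev = toy_study.model.update_bounds({"BIOMASS": (-1.0, 1000.0)})
            set_irreversible(bio_rev, "BIOMASS")
        assert any("biomass" in rec.message.lower() for rec in caplog.records)

    def test_unknown_reaction_is_error(self, toy_study):
        with pytest.raises(KeyError):
            set_irreversible(toy_study.model, "GHOST")


class TestIsoenzymes:
    def test_reassignment_makes_gene_solely_responsible(self, toy_study):
        model = reassign_isoenzyme(toy_study.model, "g_iso1_main", "ISO1")
        assert model.reaction("ISO1").gpr == GPRExpression(
            GeneLiteral("g_iso1_main"))
        # the silent partner no longer rescues
        ko = apply_knockout(model, {"g_iso1_main"})
        assert ko.reaction("ISO1").upper_bound == 0.0

    def test_gene_absent_from_gpr_is_error(self, toy_study):
        with pytest.raises(KeyError):
            reassign_isoenzyme(toy_study.model, "g_iso2_main", "ISO1")

    def test_single_gene_reaction_reassignment_is_noop(self, toy_study):
        model = toy_study.model
        assert reassign_isoenzyme(model, "g_c01_1", "CARB01_S1") \
            .reaction("CARB01_S1").gpr == model.reaction("CARB01_S1").gpr

    def test_per_reaction_reassignment_only_touches_listed_reaction(self):
        # one gene an isoenzyme for two reactions; reassign only one
        model = make_model(
            {"A_c": "c", "B_c": "c", "C_c": "c"},
            {"SRC": ({"A_c": 1.0}, 0.0, 100.0, ""),
             "R1": ({"A_c": -1.0, "B_c": 1.0}, 0.0, 100.0, "gX or gY"),
             "R2": ({"A_c": -1.0, "C_c": 1.0}, 0.0, 100.0, "gX or gZ"),
             "BIO": ({"B_c": -1.0, "C_c": -1.0}, 0.0, 1000.0, "")},
        )
        out = reassign_isoenzyme(model, "gX", "R1")
        assert out.reaction("R1").gpr == GPRExpression(GeneLiteral("gX"))
        assert out.reaction("R2").gpr == model.reaction("R2").gpr


class TestStrainGenes:
    def test_sole_gene_reaction_removed_entirely(self, toy_study):
        out = remove_strain_genes(toy_study.model, ["g_c01_1"])
        assert not out.has_reaction("CARB01_S1")
        assert "g_c01_1" not in out.genes

    def test_or_partner_keeps_reaction(self, toy_study):
        out = remove_strain_genes(toy_study.model, ["g_iso1_alt"])
        assert out.has_reaction("ISO1")
        assert out.reaction("ISO1").gpr.genes() == {"g_iso1_main"}

    def test_empty_and_unknown_lists_are_safe(self, toy_study):
        assert remove_strain_genes(toy_study.model, []) == toy_study.model
        out = remove_strain_genes(toy_study.model, ["ghost"])
        assert out == toy_study.model


class TestFixFlux:
    def test_bounds_overwritten_not_intersected(self, toy_study):
        out = fix_flux(toy_study.model, "EX_carb01_e", -2000.0, 2000.0)
        r = out.reaction("EX_carb01_e")
        assert (r.lower_bound, r.upper_bound) == (-2000.0, 2000.0)

    def test_zeroing_dead_end_changes_nothing(self, toy_study):
        # the forward serine->glycine direction is unused on every carbon
        scen = replace(toy_scenario(), fixed_fluxes=(("GLY_SRC", 0.0, 0.0),))
        genes = ["g_c01_1", "g_v1_1"]
        t1, _ = knockout_grid(toy_study.model, genes, ["carb01"], toy_scenario())
        t2, _ = knockout_grid(toy_study.model, genes, ["carb01"], scen)
        assert t1["grows"].tolist() == t2["grows"].tolist()

    def test_invalid_bounds_and_unknown_reaction(self, toy_study):
        with pytest.raises(ValueError):
            fix_flux(toy_study.model, "EX_carb01_e", 1.0, 0.0)
        with pytest.raises(KeyError):
            fix_flux(toy_study.model, "GHOST", 0.0, 0.0)


class TestScenarioApplication:
    def test_idempotent(self, toy_study):
        c = toy_study.truth.corrections
        scen = ScenarioSpec(
            medium=MediumSpec(carbon_source="carb01"),
            supplements=tuple(c["supplements"]),
            irreversibilized_reactions=tuple(c["irreversible"]),
            isoenzyme_reassignments=tuple(c["isoenzyme_reassignments"]),
        )
        once = apply_scenario(toy_study.model, scen)
        twice = apply_scenario(once, scen)
        assert once == twice

    def test_roundtrips_through_config_dict(self):
        scen = ScenarioSpec(
            medium=MediumSpec(components={"EX_o2_e": -1000.0},
                              carbon_source="glc__D"),
            supplements=(("btn_c", "intracellular"),),
            irreversibilized_reactions=("GHMT2r",),
            isoenzyme_reassignments=(("leuB", "IPMD"),),
            fixed_fluxes=(("TALA", 0.0, 0.0),),
        )
        assert ScenarioSpec.from_dict(scen.to_dict()) == scen

    def test_wildtype_grows_on_every_configured_carbon(self, toy_study):
        wt = toy_study.table[toy_study.table["gene"] == WILDTYPE]
        assert wt["grows"].all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_corrections_never_hurt_and_combine(self, seed):
        model, truth = build_toy_gem(ToyGemConfig(seed=seed), verify=False)
        fitness = simulate_fitness(truth, FitnessGenConfig(seed=seed))
        scen = toy_scenario()
        base = run_simulation(model, fitness, scen)
        base_auc = evaluate_predictions(base["table"])[0].auc_pr
        c = truth.corrections
        single_aucs = []
        for corr in (
            {"supplements": tuple(c["supplements"])},
            {"isoenzyme_reassignments": tuple(c["isoenzyme_reassignments"])},
            {"irreversibilized_reactions": tuple(c["irreversible"])},
        ):
            sim = run_simulation(model, fitness, replace(scen, **corr),
                                 genes=base["genes"], carbons=base["carbons"],
                                 filter_unconditional=False)
            single_aucs.append(evaluate_predictions(sim["table"])[0].auc_pr)
        combined = replace(scen, supplements=tuple(c["supplements"]),
                           isoenzyme_reassignments=tuple(c["isoenzyme_reassignments"]),
                           irreversibilized_reactions=tuple(c["irreversible"]))
        sim = run_simulation(model, fitness, combined, genes=base["genes"],
                             carbons=base["carbons"], filter_unconditional=False)
        combined_auc = evaluate_predictions(sim["table"])[0].auc_pr
        assert all(a >= base_auc for a in single_aucs)
        assert all(combined_auc >= a for a in single_aucs)
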