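"""Shared fixtures: hand-built micro-models and the session-wide toy
study (model + ground truth + fitness + knockout grid with fluxes)."""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parent))

from gemeval import pipeline, synthetic_data as sd
from gemeval.model_io import MetabolicModel, Metabolite, Reaction, parse_gpr


def make_model(mets, rxns, biomass="BIO", model_id="micro"):
    """Terse micro-model builder.

    ``mets``: {id: compartment}; ``rxns``: {id: (stoich, lb, ub, gpr)}.
    """
    metabolites = tuple(Metabolite(id=m, compartment=c) for m, c in mets.items())
    comp = dict(mets)
    reactions = []
    for rid, (stoich, lb, ub, gpr) in rxns.items():
        is_ex = len(stoich) == 1 and comp[next(iter(stoich))] == "e"
        reactions.append(Reaction(id=rid, stoichiometry=dict(stoich),
                                  lower_bound=lb, upper_bound=ub,
                                  gpr=parse_gpr(gpr), is_exchange=is_ex))
    genes = frozenset(g for r in reactions for g in r.gpr.genes())
    return MetabolicModel(id=model_id, metabolites=metabolites,
                          reactions=tuple(reactions), genes=genes,
                          biomass_reaction_id=biomass,
                          compartments={"c": "cytoplasm", "e": "extracellular"})


@pytest.fixture
def chain_model():
    """EX_A (uptake -10) <-> A_e, transport A_e -> A_c, biomass from A_c:
    the hand-solvable 3-variable LP with optimum 10."""
    return make_model(
        {"A_e": "e", "A_c": "c"},
        {
            "EX_A": ({"A_e": -1.0}, -10.0, 1000.0, ""),
            "T_A": ({"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, "gT"),
            "BIO": ({"A_c": -1.0}, 0.0, 1000.0, "gB"),
        },
    )


@pytest.fixture
def two_route_model():
    """Two alternative routes to biomass with equal yield: a direct
    2-reaction route and a 3-reaction detour; pFBA must take the short
    one."""
    return make_model(
        {"A_e": "e", "A_c": "c", "B_c": "c", "C_c": "c"},
        {
            "EX_A": ({"A_e": -1.0}, -10.0, 1000.0, ""),
            "T_A": ({"A_e": -1.0, "A_c": 1.0}, 0.0, 1000.0, ""),
            "DIRECT": ({"A_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, ""),
            "DETOUR1": ({"A_c": -1.0, "C_c": 1.0}, 0.0, 1000.0, ""),
            "DETOUR2": ({"C_c": -1.0, "B_c": 1.0}, 0.0, 1000.0, ""),
            "BIO": ({"B_c": -1.0}, 0.0, 1000.0, ""),
        },
    )


class ToyStudy:
    """Bundle of the default synthetic study, computed once per session."""

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.config = sd.ToyGemConfig(seed=seed)
        self.model, self.truth = sd.build_toy_gem(self.config, verify=False)
        self.fitness = sd.simulate_fitness(self.truth,
                                           sd.FitnessGenConfig(seed=seed))
        self.scenario = sd.toy_scenario()
        self.sim = pipeline.run_simulation(
            self.model, self.fitness, self.scenario, record_fluxes=True,
        )
        self.table = self.sim["table"]
        self.fluxes = self.sim["fluxes"]
        self.reaction_ids = [r.id for r in self.model.reactions]


@pytest.fixture(scope="session")
def toy_study():
    return ToyStudy(seed=0)
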