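"""Toy genome-scale models with known conditional essentiality, plus
matching RB-TnSeq-style fitness tables with injected, labelled error
classes.

The generated network mirrors the structures behind the real analysis:

* per-carbon linear catabolic pathways (transporter + chain) feeding a
  shared ``core_c`` precursor, so pathway knockouts are carbon-specific
  and sit near "their" carbon in the bipartite network;
* vitamin/cofactor biosynthesis chains whose product is a biomass
  component. A configurable subset has an extracellular species with
  exchange and transporter (supplementable extracellularly); the rest
  have only an extracellular *precursor* with a closed exchange, so they
  need an intracellular supplement — and stay conditionally essential
  under the all-exchanges-open filter, as in the real model;
* isoenzyme OR-pairs where the alternative gene is regulatorily silent
  in reality: the model predicts growth for the main gene's knockout,
  the experiment does not (false positive, fixed by GPR reassignment);
* an optional reversible bypass that rescues a serine-like biosynthesis
  pathway only when run backwards (false positives fixed by
  irreversibilization).

Fitness values are Gaussian around -4 for experimentally essential
(gene, carbon) pairs and around 0 otherwise, in duplicate replicates.
The real fitness distribution is heavier-tailed; ordinal separation is
what the evaluation statistics need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gemeval.fba_core import GROWTH_CUTOFF, knockout_grid
from gemeval.model_io import (
    FitnessDataset,
    GPRExpression,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
)
from gemeval.scenarios import MediumSpec, ScenarioSpec

__all__ = [
    "ToyGemConfig",
    "FitnessGenConfig",
    "GroundTruth",
    "build_toy_gem",
    "toy_scenario",
    "simulate_fitness",
    "simulate_fitness_rows",
    "planted_flux_feature",
    "make_flux_signal",
]

MU_ESSENTIAL = -4.0
SIGMA = 0.5
YIELD_RANGE = (0.6, 1.4)  # per-carbon biomass yield spread


@dataclass(frozen=True)
class ToyGemConfig:
    n_carbons: int = 12
    n_pathway_genes: int = 4  # per carbon, transporter included
    n_vitamin_pathways: int = 5  # as many as the vitamins/cofactors studied
    n_vitamin_transporters: int = 2  # pathways with extracellular supply route
    n_isoenzyme_pairs: int = 3  # error genes stay a minority of essentials
    include_reversible_bypass: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.n_carbons, self.n_pathway_genes) < 1:
            raise ValueError("need at least one carbon and one pathway gene")
        if not 0 <= self.n_vitamin_transporters <= self.n_vitamin_pathways:
            raise ValueError("n_vitamin_transporters out of range")

    @property
    def carbons(self) -> list:
        return [f"carb{i:02d}" for i in range(1, self.n_carbons + 1)]


@dataclass(frozen=True)
class FitnessGenConfig:
    mu_essential: float = MU_ESSENTIAL
    sigma: float = SIGMA
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0 or self.n_replicates < 1:
            raise ValueError("sigma must be > 0 and n_replicates >= 1")


@dataclass
class GroundTruth:
    """Per-(gene, carbon) constructive truth with injected error labels.

    ``frame`` columns: gene, carbon, model_essential (uncorrected model),
    exp_essential (what the assay would see), error_class in
    {none, vitamin_carryover, isoenzyme_fp, bypass_fp}.
    ``corrections`` holds the scenario pieces that fix each error class.
    """

    frame: pd.DataFrame
    corrections: dict
    injected: dict  # error_class -> sorted gene list
    config: ToyGemConfig

    @property
    def genes(self) -> list:
        return sorted(self.frame["gene"].unique())


class _Builder:
    def __init__(self):
        self.mets: dict[str, Metabolite] = {}
        self.rxns: list[Reaction] = []

    def met(self, mid: str, compartment: str) -> str:
        if mid not in self.mets:
            self.mets[mid] = Metabolite(id=mid, compartment=compartment)
        return mid

    def rxn(self, rid, stoich, lb=0.0, ub=1000.0, gpr="", exchange=False):
        self.rxns.append(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gpr=parse_gpr(gpr), is_exchange=exchange,
        ))


def build_toy_gem(config: ToyGemConfig | None = None,
                  verify: bool = True) -> tuple[MetabolicModel, GroundTruth]:
    """Construct the toy model and its ground truth; optionally verify
    the constructive essentiality calls by exhaustive single-knockout
    FBA across every carbon."""
    config = config or ToyGemConfig()
    rng = np.random.default_rng(config.seed)
    b = _Builder()
    core = b.met("core_c", "c")
    biomass_stoich = {core: -1.0}
    truth_rows = []
    injected: dict[str, list] = {"vitamin_carryover": [], "isoenzyme_fp": [],
                                 "bypass_fp": []}
    corrections = {"supplements": [], "isoenzyme_reassignments": [],
                   "irreversible": []}
    carbons = config.carbons

    def add_truth(gene, model_ess_carbons, exp_ess_carbons, error_class):
        for c in carbons:
            truth_rows.append({
                "gene": gene, "carbon": c,
                "model_essential": c in model_ess_carbons,
                "exp_essential": c in exp_ess_carbons,
                "error_class": error_class,
            })

    # -- per-carbon catabolic chains ------------------------------------
    # carbon sources differ in biomass yield (final-step stoichiometry),
    # as real substrates do; this also gives the shared core/biomass flux
    # cluster continuous variation across carbons
    yields = rng.uniform(*YIELD_RANGE, size=config.n_carbons)
    for i, carbon in enumerate(carbons, start=1):
        ext = b.met(f"{carbon}_e", "e")
        b.rxn(f"EX_{carbon}_e", {ext: -1.0}, lb=0.0, exchange=True)
        prev = ext
        for k in range(1, config.n_pathway_genes + 1):
            gene = f"g_c{i:02d}_{k}"
            last = k == config.n_pathway_genes
            nxt = core if last else b.met(f"p{i:02d}_{k}_c", "c")
            coef = float(yields[i - 1]) if last else 1.0
            b.rxn(f"CARB{i:02d}_S{k}", {prev: -1.0, nxt: coef}, gpr=gene)
            prev = nxt
            add_truth(gene, {carbon}, {carbon}, "none")

    # -- vitamin/cofactor pathways --------------------------------------
    all_set = set(carbons)
    for j in range(1, config.n_vitamin_pathways + 1):
        vit = b.met(f"vit{j}_c", "c")
        chain_len = int(rng.integers(2, 5))  # 2-4 gene chain
        prev = core
        for k in range(1, chain_len + 1):
            gene = f"g_v{j}_{k}"
            nxt = vit if k == chain_len else b.met(f"w{j}_{k}_c", "c")
            b.rxn(f"VIT{j}_S{k}", {prev: -1.0, nxt: 1.0}, gpr=gene)
            prev = nxt
            add_truth(gene, all_set, set(), "vitamin_carryover")
            injected["vitamin_carryover"].append(gene)
        biomass_stoich[vit] = -0.01
        if j <= config.n_vitamin_transporters:
            # extracellular species + closed exchange + transporter
            ext = b.met(f"vit{j}_e", "e")
            b.rxn(f"EX_vit{j}_e", {ext: -1.0}, lb=0.0, exchange=True)
            b.rxn(f"VIT{j}_T", {ext: -1.0, vit: 1.0})
            corrections["supplements"].append((f"vit{j}_e", "extracellular"))
        else:
            # only an extracellular precursor route exists (closed);
            # supplementation must go directly to the cytoplasm
            pre = b.met(f"pre{j}_e", "e")
            b.rxn(f"EX_pre{j}_e", {pre: -1.0}, lb=0.0, exchange=True)
            b.rxn(f"PRE{j}_U", {pre: -1.0, vit: 1.0})
            corrections["supplements"].append((f"vit{j}_c", "intracellular"))

    # -- isoenzyme OR-pairs ---------------------------------------------
    for k in range(1, config.n_isoenzyme_pairs + 1):
        iso = b.met(f"iso{k}_c", "c")
        main, alt = f"g_iso{k}_main", f"g_iso{k}_alt"
        b.rxn(f"ISO{k}", {core: -1.0, iso: 1.0}, gpr=f"{main} or {alt}")
        biomass_stoich[iso] = -0.01
        add_truth(main, set(), all_set, "isoenzyme_fp")
        add_truth(alt, set(), set(), "none")
        injected["isoenzyme_fp"].append(main)
        corrections["isoenzyme_reassignments"].append((main, f"ISO{k}"))

    # -- reversible bypass (serine-pathway analogue) ---------------------
    if config.include_reversible_bypass:
        ser = b.met("ser_c", "c")
        gly = b.met("gly_c", "c")
        s1 = b.met("s1_c", "c")
        b.rxn("SER_S1", {core: -1.0, s1: 1.0}, gpr="g_byp_1")
        b.rxn("SER_S2", {s1: -1.0, ser: 1.0}, gpr="g_byp_2")
        b.rxn("GLY_SRC", {core: -1.0, gly: 1.0})
        # physiological direction ser -> gly; the reverse direction is the
        # spurious rescue removed by set_irreversible
        b.rxn("SER_GLY_REV", {ser: -1.0, gly: 1.0}, lb=-1000.0)
        biomass_stoich[ser] = -0.01
        for gene in ("g_byp_1", "g_byp_2"):
            add_truth(gene, set(), all_set, "bypass_fp")
            injected["bypass_fp"].append(gene)
        corrections["irreversible"].append("SER_GLY_REV")

    b.rxn("BIOMASS", biomass_stoich, lb=0.0, ub=1000.0)

    gpr_genes = set()
    for r in b.rxns:
        gpr_genes |= r.gpr.genes()
    model = MetabolicModel(
        id=f"toy_gem_seed{config.seed}",
        metabolites=tuple(b.mets.values()),
        reactions=tuple(b.rxns),
        genes=frozenset(gpr_genes),
        biomass_reaction_id="BIOMASS",
        compartments={"c": "cytoplasm", "e": "extracellular"},
    )
    frame = pd.DataFrame(truth_rows)
    truth = GroundTruth(frame=frame, corrections=corrections,
                        injected={k: sorted(set(v)) for k, v in injected.items()},
                        config=config)
    if verify:
        _verify_truth(model, truth)
    return model, truth


def toy_scenario(**medium_kwargs) -> ScenarioSpec:
    """The toy study's base scenario: minimal medium whose only opened
    exchange is the carbon source (all biomass precursors derive from
    the carbon)."""
    return ScenarioSpec(medium=MediumSpec(components={}, **medium_kwargs))


def _verify_truth(model: MetabolicModel, truth: GroundTruth) -> None:
    table, _ = knockout_grid(model, truth.genes, truth.config.carbons,
                             toy_scenario())
    from gemeval.fba_core import WILDTYPE

    wt = table[table["gene"] == WILDTYPE]
    if not wt["grows"].all():
        bad = wt.loc[~wt["grows"], "carbon"].tolist()
        raise RuntimeError(f"generated wild type fails to grow on {bad}")
    merged = truth.frame.merge(table, on=["gene", "carbon"])
    mismatch = merged[merged["model_essential"] == merged["grows"]]
    if len(mismatch):
        raise RuntimeError(
            "constructive ground truth disagrees with FBA for "
            f"{mismatch[['gene', 'carbon']].to_records(index=False).tolist()[:5]}"
        )


def simulate_fitness_rows(truth: GroundTruth,
                          config: FitnessGenConfig | None = None) -> pd.DataFrame:
    """Replicate-level fitness rows (columns gene, carbon, fitness), the
    shape a fitness TSV takes before replicate averaging."""
    config = config or FitnessGenConfig()
    rng = np.random.default_rng(config.seed)
    frame = truth.frame.sort_values(["gene", "carbon"]).reset_index(drop=True)
    mu = np.where(frame["exp_essential"], config.mu_essential, 0.0)
    rows = []
    for (gene, carbon, m) in zip(frame["gene"], frame["carbon"], mu):
        for value in rng.normal(m, config.sigma, size=config.n_replicates):
            rows.append({"gene": gene, "carbon": carbon, "fitness": float(value)})
    return pd.DataFrame(rows)


def simulate_fitness(truth: GroundTruth,
                     config: FitnessGenConfig | None = None) -> FitnessDataset:
    """Replicate-averaged fitness dataset matching the toy model."""
    rows = simulate_fitness_rows(truth, config)
    records = {}
    for (gene, carbon), grp in rows.groupby(["gene", "carbon"], sort=True):
        vals = tuple(grp["fitness"])
        records[(gene, carbon)] = (vals, sum(vals) / len(vals))
    return FitnessDataset(
        records=records,
        carbon_sources=sorted(rows["carbon"].unique()),
        genes=sorted(rows["gene"].unique()),
    )


def planted_flux_feature(matrix, cluster_map, reaction_id: str = "BIOMASS") -> int:
    """Column index of the cluster representative for ``reaction_id``.

    The biomass cluster is the natural place to plant a signal: its flux
    varies continuously across carbons (per-carbon yields), so a signal
    planted there can generalize to unseen carbons.
    """
    col = matrix.reaction_ids.index(reaction_id)
    for cluster, rep in zip(cluster_map.clusters, cluster_map.representatives):
        if col in cluster:
            return rep
    raise ValueError(f"{reaction_id!r} did not survive the variance filter")


def make_flux_signal(matrix, planted_feature: int, effect: float = 3.0,
                     seed: int = 0, intercept: float = -1.1,
                     carbon_sigma: float = 0.75) -> np.ndarray:
    """Plant a logistic false-positive signal in a flux feature.

    FP labels are drawn with probability sigmoid(intercept + effect * z
    + b_carbon) where z is the standardized planted column and b_carbon
    are per-carbon Gaussian offsets (sd ``carbon_sigma``) that make part
    of the signal carbon-specific. ``effect=0`` makes labels independent
    of the feature.
    """
    rng = np.random.default_rng(seed)
    col = matrix.values[:, planted_feature].astype(float)
    sd = col.std()
    z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
    carbons = matrix.carbons
    offsets = dict(zip(carbons, rng.normal(0.0, carbon_sigma, size=len(carbons))))
    logit = intercept + effect * z + np.array(
        [offsets[c] for _, c in matrix.samples]
    )
    p = 1.0 / (1.0 + np.exp(-logit))
    return (rng.random(len(p)) < p).astype(int)
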