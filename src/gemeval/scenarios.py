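"""Simulation environments and model corrections.

A scenario bundles the growth medium (which exchange reactions are open,
and how far) with the correction classes used to reconcile model
predictions with mutant fitness data:

* vitamin/cofactor supplementation — extracellular (open an existing
  exchange) or intracellular (create an uptake-only exchange on the
  cytoplasmic species when the model has no transporter);
* irreversibilization of a bypass reaction (lower bound to 0);
* isoenzyme GPR reassignment (make one gene solely responsible for a
  reaction it previously shared through an OR rule);
* strain gene removal (reactions deleted outright, modelling a permanent
  strain difference);
* fixed-flux constraints (e.g. pinning hydrogen-ion exchange).

Scenario application is idempotent: applying the same spec twice yields
an identical model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from gemeval.model_io import (
    EXTRACELLULAR,
    BoolOp,
    GeneLiteral,
    GPRExpression,
    MetabolicModel,
    Metabolite,
    Reaction,
    resolve_carbon,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MediumSpec",
    "ScenarioSpec",
    "apply_medium",
    "apply_scenario",
    "add_supplement",
    "set_irreversible",
    "reassign_isoenzyme",
    "remove_strain_genes",
    "fix_flux",
]

UNLIMITED_UPTAKE = -1000.0  # mmol/(gdw x h), non-carbon media components
CARBON_UPTAKE = -10.0  # mmol/(gdw x h), carbon sources


@dataclass(frozen=True)
class MediumSpec:
    """Growth medium: non-carbon components at unlimited uptake plus one
    rate-limited carbon source.

    ``components`` maps exchange reaction ids (or extracellular
    metabolite ids) to uptake lower bounds (<= 0). ``carbon_source`` is a
    carbon identifier resolved against the model ("X" -> metabolite
    "X_e"); its exchange lower bound is set to ``carbon_uptake_bound``.
    """

    components: dict = field(default_factory=dict)
    carbon_source: str | None = None
    carbon_uptake_bound: float = CARBON_UPTAKE

    def __post_init__(self):
        bad = {k: v for k, v in self.components.items() if v > 0}
        if bad:
            raise ValueError(f"medium component lower bounds must be <= 0: {bad}")


@dataclass(frozen=True)
class ScenarioSpec:
    medium: MediumSpec
    supplements: tuple = ()  # (metabolite id, "extracellular" | "intracellular")
    irreversibilized_reactions: tuple = ()
    isoenzyme_reassignments: tuple = ()  # (gene id, reaction id)
    removed_genes: tuple = ()
    fixed_fluxes: tuple = ()  # (reaction id, lower, upper)

    def __post_init__(self):
        object.__setattr__(self, "supplements", tuple(tuple(s) for s in self.supplements))
        object.__setattr__(self, "irreversibilized_reactions",
                           tuple(self.irreversibilized_reactions))
        object.__setattr__(self, "isoenzyme_reassignments",
                           tuple(tuple(x) for x in self.isoenzyme_reassignments))
        object.__setattr__(self, "removed_genes", tuple(self.removed_genes))
        object.__setattr__(self, "fixed_fluxes",
                           tuple(tuple(x) for x in self.fixed_fluxes))

    @classmethod
    def from_dict(cls, doc: dict) -> "ScenarioSpec":
        med = doc.get("medium", {})
        return cls(
            medium=MediumSpec(
                components=dict(med.get("components", {})),
                carbon_source=med.get("carbon_source"),
                carbon_uptake_bound=float(med.get("carbon_uptake_bound", CARBON_UPTAKE)),
            ),
            supplements=tuple((s["metabolite"], s["mode"]) if isinstance(s, dict)
                              else tuple(s) for s in doc.get("supplements", [])),
            irreversibilized_reactions=tuple(doc.get("irreversible", [])),
            isoenzyme_reassignments=tuple(
                (x["gene"], x["reaction"]) if isinstance(x, dict) else tuple(x)
                for x in doc.get("isoenzyme_reassign", [])
            ),
            removed_genes=tuple(doc.get("remove_genes", [])),
            fixed_fluxes=tuple(tuple(x) for x in doc.get("fix_flux", [])),
        )

    def to_dict(self) -> dict:
        return {
            "medium": {
                "components": dict(self.medium.components),
                "carbon_source": self.medium.carbon_source,
                "carbon_uptake_bound": self.medium.carbon_uptake_bound,
            },
            "supplements": [list(s) for s in self.supplements],
            "irreversible": list(self.irreversibilized_reactions),
            "isoenzyme_reassign": [list(x) for x in self.isoenzyme_reassignments],
            "remove_genes": list(self.removed_genes),
            "fix_flux": [list(x) for x in self.fixed_fluxes],
        }


def _resolve_exchange(model: MetabolicModel, key: str):
    """Accept an exchange reaction id or an extracellular metabolite id."""
    if model.has_reaction(key):
        r = model.reaction(key)
        if r.is_exchange:
            return r
    for cand in (key, f"{key}_{EXTRACELLULAR}"):
        if model.has_metabolite(cand):
            ex = model.exchange_for(cand)
            if ex is not None:
                return ex
    return None


def _ensure_exchange(model: MetabolicModel, met_id: str,
                     rxn_id: str | None = None) -> tuple[MetabolicModel, str]:
    ex = model.exchange_for(met_id)
    if ex is not None:
        return model, ex.id
    rxn_id = rxn_id or f"EX_{met_id}"
    new = Reaction(id=rxn_id, stoichiometry={met_id: -1.0}, lower_bound=0.0,
                   upper_bound=1000.0, is_exchange=True,
                   name=f"{met_id} exchange")
    return model.with_reactions(model.reactions + (new,)), rxn_id


def apply_medium(model: MetabolicModel, medium: MediumSpec,
                 carbon_overrides: dict | None = None) -> MetabolicModel:
    """Close every exchange, then open the medium components and the
    carbon source.

    Non-carbon components get their stated bounds (typically -1000 for
    unlimited uptake); the carbon source's exchange lower bound is set to
    ``medium.carbon_uptake_bound`` (-10 by default) and takes precedence
    over a colliding component entry.
    """
    bounds = {r.id: (0.0, r.upper_bound) for r in model.exchanges}
    component_exchanges = set()
    missing = []
    for key, lb in medium.components.items():
        ex = _resolve_exchange(model, key)
        if ex is None:
            missing.append(key)
        else:
            bounds[ex.id] = (float(lb), ex.upper_bound)
            component_exchanges.add(ex.id)
    if missing:
        raise KeyError(f"medium components with no exchange reaction: {missing}")
    model = model.update_bounds(bounds)
    if medium.carbon_source is not None:
        met = resolve_carbon(model, medium.carbon_source, carbon_overrides)
        if met is None:
            raise KeyError(
                f"carbon source {medium.carbon_source!r} has no extracellular "
                "metabolite in the model"
            )
        model, ex_id = _ensure_exchange(model, met)
        if ex_id in component_exchanges:
            logger.info("carbon source %s collides with a base medium component; "
                        "carbon bound %.3g wins", medium.carbon_source,
                        medium.carbon_uptake_bound)
        ex = model.reaction(ex_id)
        model = model.update_bounds(
            {ex_id: (float(medium.carbon_uptake_bound), ex.upper_bound)}
        )
    return model


def add_supplement(model: MetabolicModel, met_id: str, mode: str) -> MetabolicModel:
    """Make a vitamin/cofactor freely available.

    ``extracellular``: open the existing exchange of the extracellular
    species to -1000. ``intracellular``: create (or reuse) an uptake-only
    exchange (-1000, 0) directly on the cytoplasmic species — the minimal
    mechanism when the model lacks a transporter, and uptake-only so the
    supplement cannot earn secretion credit.
    """
    if mode == "extracellular":
        ex = _resolve_exchange(model, met_id)
        if ex is None:
            raise KeyError(
                f"no exchange reaction for {met_id!r}; if the model lacks a "
                "transporter, use mode='intracellular'"
            )
        return model.update_bounds({ex.id: (UNLIMITED_UPTAKE, ex.upper_bound)})
    if mode == "intracellular":
        if not model.has_metabolite(met_id):
            raise KeyError(f"unknown metabolite {met_id!r}")
        rxn_id = f"EX_{met_id}_supplement"
        if model.has_reaction(rxn_id):
            return model.update_bounds({rxn_id: (UNLIMITED_UPTAKE, 0.0)})
        new = Reaction(id=rxn_id, stoichiometry={met_id: -1.0},
                       lower_bound=UNLIMITED_UPTAKE, upper_bound=0.0,
                       is_exchange=True, name=f"{met_id} intracellular supplement")
        return model.with_reactions(model.reactions + (new,))
    raise ValueError(f"unknown supplement mode {mode!r}")


def set_irreversible(model: MetabolicModel, rxn_id: str) -> MetabolicModel:
    """Forbid reverse flux through a reaction (lower bound to 0)."""
    r = model.reaction(rxn_id)
    if rxn_id == model.biomass_reaction_id:
        logger.warning("irreversibilizing the biomass reaction %s", rxn_id)
    if r.lower_bound >= 0:
        return model
    return model.update_bounds({rxn_id: (0.0, r.upper_bound)})


def reassign_isoenzyme(model: MetabolicModel, gene: str, rxn_id: str) -> MetabolicModel:
    """Make ``gene`` solely responsible for ``rxn_id``: the reaction's
    GPR, previously an OR involving the gene, becomes the single
    literal."""
    r = model.reaction(rxn_id)
    if gene not in r.gpr.genes():
        raise KeyError(f"gene {gene!r} does not appear in the GPR of {rxn_id!r}")
    return model.update_reaction(rxn_id, gpr=GPRExpression(GeneLiteral(gene)))


def _prune_gpr(node, removed: frozenset):
    """Drop literals of removed genes; returns the pruned node or the
    sentinel False when the expression can no longer be satisfied."""
    if isinstance(node, GeneLiteral):
        return False if node.gene in removed else node
    kept = [_prune_gpr(c, removed) for c in node.children]
    if node.op == "and":
        if any(c is False for c in kept):
            return False
        kept = [c for c in kept if c is not False]
    else:
        kept = [c for c in kept if c is not False]
        if not kept:
            return False
    return kept[0] if len(kept) == 1 else BoolOp(node.op, tuple(kept))


def remove_strain_genes(model: MetabolicModel, genes) -> MetabolicModel:
    """Delete genes absent from the assayed strain, removing outright any
    reaction whose GPR can no longer be satisfied (a permanent strain
    difference, unlike the zero-bounding used for knockouts)."""
    genes = frozenset(genes)
    unknown = genes - model.genes
    if unknown:
        logger.info("skipping unknown strain genes %s", sorted(unknown))
    removed = genes & model.genes
    if not removed:
        return model
    new_rxns = []
    for r in model.reactions:
        if r.gpr.is_empty or not (r.gpr.genes() & removed):
            new_rxns.append(r)
            continue
        pruned = _prune_gpr(r.gpr.root, removed)
        if pruned is False:
            continue
        new_rxns.append(replace(r, gpr=GPRExpression(pruned)))
    return replace(model, reactions=tuple(new_rxns),
                   genes=frozenset(model.genes - removed))


def fix_flux(model: MetabolicModel, rxn_id: str, lower: float,
             upper: float) -> MetabolicModel:
    """Overwrite a reaction's bounds exactly (not intersected with the
    originals), e.g. to pin hydrogen-ion exchange during a sweep."""
    if lower > upper:
        raise ValueError(f"lower {lower} > upper {upper}")
    model.reaction(rxn_id)  # raises on unknown id
    return model.update_bounds({rxn_id: (float(lower), float(upper))})


def apply_scenario(model: MetabolicModel, spec: ScenarioSpec,
                   carbon_overrides: dict | None = None) -> MetabolicModel:
    """Apply a full scenario: strain gene removal, medium, supplements,
    irreversibilizations, isoenzyme reassignments, fixed fluxes.

    The medium is applied before supplements so supplement exchanges stay
    open, and the whole application is idempotent.
    """
    model = remove_strain_genes(model, spec.removed_genes)
    model = apply_medium(model, spec.medium, carbon_overrides)
    for met_id, mode in spec.supplements:
        model = add_supplement(model, met_id, mode)
    for rxn_id in spec.irreversibilized_reactions:
        model = set_irreversible(model, rxn_id)
    for gene, rxn_id in spec.isoenzyme_reassignments:
        model = reassign_isoenzyme(model, gene, rxn_id)
    for rxn_id, lo, hi in spec.fixed_fluxes:
        model = fix_flux(model, rxn_id, lo, hi)
    return model
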