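"""Carbon-source-to-gene distances on the bipartite metabolite-reaction
graph.

The model is converted to an undirected bipartite graph (one node per
metabolite and per reaction, one edge per nonzero stoichiometric entry).
High-degree hub nodes (currency metabolites such as water or ATP, and
the biomass reaction) are removed so distances follow substrate-specific
routes rather than cofactor shortcuts; hubs a user designates (e.g.
pyruvate, which is itself a carbon source) are kept.

The distance from a carbon source to a gene is the number of reactions
traversed from the extracellular carbon metabolite to the nearest
reaction the gene's knockout removes: 0 when that reaction consumes the
carbon metabolite directly, 1 when it is one metabolite further, etc.
Edges are unweighted, so shortest paths are breadth-first searches.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from gemeval.fba_core import WILDTYPE, apply_knockout
from gemeval.model_io import MetabolicModel, resolve_carbon

logger = logging.getLogger(__name__)

HUB_DEGREE_THRESHOLD = 50  # "more than 50 connections" counts as a hub
UNREACHABLE = math.inf

__all__ = [
    "HUB_DEGREE_THRESHOLD",
    "UNREACHABLE",
    "build_graph",
    "remove_hubs",
    "gene_removed_reactions",
    "carbon_gene_distance",
    "distance_distributions",
]

_MET = "met:"
_RXN = "rxn:"


def build_graph(model: MetabolicModel) -> nx.Graph:
    """Bipartite metabolite-reaction graph. Node names are prefixed
    (``met:``/``rxn:``) so metabolite and reaction ids cannot collide;
    each node carries a ``kind`` attribute."""
    g = nx.Graph()
    for m in model.metabolites:
        g.add_node(_MET + m.id, kind="metabolite")
    for r in model.reactions:
        g.add_node(_RXN + r.id, kind="reaction")
        for mid, coef in r.stoichiometry.items():
            if coef != 0:
                g.add_edge(_RXN + r.id, _MET + mid)
    return g


def remove_hubs(graph: nx.Graph, degree_threshold: int = HUB_DEGREE_THRESHOLD,
                keep=()) -> nx.Graph:
    """Drop every node with degree > ``degree_threshold`` unless it is in
    ``keep`` (unprefixed metabolite/reaction ids)."""
    keep_nodes = {_MET + k for k in keep} | {_RXN + k for k in keep} | set(keep)
    out = graph.copy()
    hubs = [n for n, d in graph.degree() if d > degree_threshold
            and n not in keep_nodes]
    out.remove_nodes_from(hubs)
    return out


def gene_removed_reactions(model: MetabolicModel, gene: str) -> set:
    """Reactions disabled by the single knockout of ``gene`` (i.e. the
    reactions the gene "essentially encodes")."""
    ko = apply_knockout(model, {gene})
    return {r.id for r, k in zip(model.reactions, ko.reactions)
            if (r.lower_bound, r.upper_bound) != (k.lower_bound, k.upper_bound)}


def carbon_gene_distance(graph: nx.Graph, carbon_met: str, reactions) -> float:
    """Reactions traversed from the carbon metabolite to the nearest
    target reaction; ``UNREACHABLE`` (inf) when no path exists."""
    src = _MET + carbon_met
    if src not in graph:
        raise KeyError(
            f"carbon metabolite {carbon_met!r} is not in the graph; if it was "
            "removed as a hub, add it to the keep list of remove_hubs"
        )
    targets = {_RXN + r for r in reactions if _RXN + r in graph}
    if not targets:
        return UNREACHABLE
    lengths = nx.single_source_shortest_path_length(graph, src)
    best = min((lengths[t] for t in targets if t in lengths), default=None)
    if best is None:
        return UNREACHABLE
    # a metabolite->reaction path has an odd edge count 2k+1 and passes
    # k reaction nodes before the target
    return (best - 1) // 2


@dataclass
class DistanceTable:
    rows: pd.DataFrame  # gene, carbon, distance, subset flags
    mean_all: float
    mean_no_growth: float
    mean_carbon_specific: float
    n_unreachable: int


def distance_distributions(model: MetabolicModel, table: pd.DataFrame,
                           carbon_specific_fraction: float = 0.8,
                           degree_threshold: int = HUB_DEGREE_THRESHOLD,
                           keep=(), carbon_overrides: dict | None = None
                           ) -> DistanceTable:
    """Per-experiment network distances with the three nested subsets.

    ``all``: experiments whose gene disrupts at least one reaction;
    ``model_no_growth``: the no-growth subset; ``carbon_specific``:
    no-growth experiments of genes that are essential on at most
    ``carbon_specific_fraction`` of the assayed carbons. Means are taken
    over reachable rows; unreachable rows are counted, not imputed.
    """
    graph = remove_hubs(build_graph(model), degree_threshold, keep)
    exps = table[table["gene"] != WILDTYPE]
    removed_cache = {g: gene_removed_reactions(model, g)
                     for g in exps["gene"].unique() if g in model.genes}
    no_growth_frac = (~exps["grows"].astype(bool)).groupby(exps["gene"]).mean()
    carbon_src = {c: resolve_carbon(model, c, carbon_overrides)
                  for c in exps["carbon"].unique()}
    dist_cache: dict = {}
    rows = []
    for rec in exps.itertuples(index=False):
        removed = removed_cache.get(rec.gene, set())
        if not removed:
            continue
        met = carbon_src[rec.carbon]
        if met is None:
            continue
        key = (met, rec.gene)
        if key not in dist_cache:
            dist_cache[key] = carbon_gene_distance(graph, met, removed)
        no_growth = not rec.grows
        rows.append({
            "gene": rec.gene, "carbon": rec.carbon, "distance": dist_cache[key],
            "subset_all": True,
            "subset_no_growth": no_growth,
            "subset_carbon_specific": bool(
                no_growth and no_growth_frac[rec.gene] <= carbon_specific_fraction
            ),
        })
    frame = pd.DataFrame(rows, columns=["gene", "carbon", "distance", "subset_all",
                                        "subset_no_growth",
                                        "subset_carbon_specific"])
    reachable = frame[frame["distance"] < UNREACHABLE]
    n_unreach = int(len(frame) - len(reachable))
    if n_unreach:
        logger.info("%d experiments unreachable on the hub-removed graph",
                    n_unreach)

    def _mean(mask_col: str) -> float:
        sub = reachable[reachable[mask_col]]
        return float(sub["distance"].mean()) if len(sub) else float("nan")

    return DistanceTable(
        rows=frame,
        mean_all=_mean("subset_all"),
        mean_no_growth=_mean("subset_no_growth"),
        mean_carbon_specific=_mean("subset_carbon_specific"),
        n_unreachable=n_unreach,
    )
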