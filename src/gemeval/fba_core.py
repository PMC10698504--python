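"""Constraint-based simulation: FBA, parsimonious FBA, Boolean knockout
propagation, growth binarization, and unconditional-essentiality
filtering.

FBA maximizes the biomass flux v_bio subject to steady state S v = 0 and
flux bounds l <= v <= u. Parsimonious FBA (pFBA) fixes the biomass flux
at its optimum and minimizes total absolute flux sum |v_i| via the
standard forward/reverse split. Both stages are solved with the HiGHS
simplex through scipy, which is deterministic across restarts.

Knockouts never delete reactions: a reaction whose GPR evaluates false
under the knocked-out gene set has both bounds set to zero, so flux
vectors keep a fixed reaction index across simulations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from gemeval.model_io import MetabolicModel, resolve_carbon

logger = logging.getLogger(__name__)

GROWTH_CUTOFF = 0.001  # biomass flux [1/h] at and above which growth is called
WILDTYPE = "wild_type"  # gene-column marker for no-knockout rows

__all__ = [
    "GROWTH_CUTOFF",
    "WILDTYPE",
    "FluxSolution",
    "GrowthCall",
    "UnboundedModelError",
    "solve_fba",
    "solve_pfba",
    "apply_knockout",
    "knockout_grid",
    "find_unconditional_essentials",
]


class UnboundedModelError(RuntimeError):
    """The biomass LP is unbounded; names reactions with infinite bounds."""


@dataclass(frozen=True)
class FluxSolution:
    status: str  # "optimal" | "infeasible"
    objective_value: float
    fluxes: dict  # reaction id -> flux; empty when infeasible

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class GrowthCall:
    biomass_flux: float
    grows: bool


def growth_call(biomass_flux: float, growth_cutoff: float = GROWTH_CUTOFF) -> GrowthCall:
    """Binarize a biomass flux; the cutoff itself counts as growth."""
    return GrowthCall(biomass_flux, biomass_flux >= growth_cutoff)


# --------------------------------------------------------------------------
# Compiled LP representation
# --------------------------------------------------------------------------

class _CompiledLP:
    """Numeric arrays for one model, reused across knockout solves."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.reaction_ids = [r.id for r in model.reactions]
        self.rxn_pos = {rid: i for i, rid in enumerate(self.reaction_ids)}
        met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            for mid, coef in r.stoichiometry.items():
                rows.append(met_pos[mid])
                cols.append(j)
                vals.append(float(coef))
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
        )
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.biomass_idx = self.rxn_pos[model.biomass_reaction_id]
        # GPR-bearing reactions indexed by gene for fast knockout propagation
        self.gene_to_rxns: dict[str, list[int]] = {}
        for j, r in enumerate(model.reactions):
            for g in r.gpr.genes():
                self.gene_to_rxns.setdefault(g, []).append(j)

    def disabled_by(self, knocked_out: frozenset | set) -> list[int]:
        candidates = set()
        for g in knocked_out:
            candidates.update(self.gene_to_rxns.get(g, ()))
        ko = frozenset(knocked_out)
        return [j for j in sorted(candidates)
                if not self.model.reactions[j].gpr.evaluate(ko)]

    def solve(self, disabled: list[int] | None = None) -> tuple[str, float, np.ndarray]:
        lb, ub = self.lb, self.ub
        if disabled:
            lb = lb.copy()
            ub = ub.copy()
            lb[disabled] = 0.0
            ub[disabled] = 0.0
        c = np.zeros(len(lb))
        c[self.biomass_idx] = -1.0
        res = linprog(c, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=np.column_stack([lb, ub]), method="highs")
        if res.status == 3:
            unbounded = [self.reaction_ids[j] for j in range(len(lb))
                         if math.isinf(lb[j]) or math.isinf(ub[j])]
            raise UnboundedModelError(
                f"biomass objective unbounded; reactions with infinite bounds: {unbounded}"
            )
        if res.status != 0:
            return "infeasible", 0.0, np.zeros(len(lb))
        return "optimal", float(res.x[self.biomass_idx]), res.x

    def solve_parsimonious(self, disabled: list[int] | None = None
                           ) -> tuple[str, float, np.ndarray]:
        status, opt, _ = self.solve(disabled)
        if status != "optimal":
            return status, 0.0, np.zeros(len(self.lb))
        lb, ub = self.lb.copy(), self.ub.copy()
        if disabled:
            lb[disabled] = 0.0
            ub[disabled] = 0.0
        n = len(lb)
        # forward/reverse split: v = f - r, f,r >= 0, minimize sum(f + r)
        f_lo, f_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
        r_lo, r_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
        # pin biomass at its optimum (tiny slack keeps the LP feasible)
        bi = self.biomass_idx
        if opt >= 0:
            f_lo[bi], f_hi[bi] = max(0.0, opt - 1e-9), max(0.0, opt)
            r_lo[bi] = r_hi[bi] = 0.0
        else:  # pragma: no cover - negative biomass optimum is pathological
            r_lo[bi], r_hi[bi] = max(0.0, -opt - 1e-9), max(0.0, -opt)
            f_lo[bi] = f_hi[bi] = 0.0
        A = sparse.hstack([self.S, -self.S], format="csr")
        bounds = np.column_stack(
            [np.concatenate([f_lo, r_lo]), np.concatenate([f_hi, r_hi])]
        )
        res = linprog(np.ones(2 * n), A_eq=A, b_eq=np.zeros(self.S.shape[0]),
                      bounds=bounds, method="highs")
        if res.status != 0:  # pragma: no cover - guarded by the slack above
            return "infeasible", 0.0, np.zeros(n)
        v = res.x[:n] - res.x[n:]
        return "optimal", float(v[bi]), v


def _compiled(model: MetabolicModel) -> _CompiledLP:
    lp = getattr(model, "_lp_cache", None)
    if lp is None:
        lp = _CompiledLP(model)
        object.__setattr__(model, "_lp_cache", lp)
    return lp


def _to_solution(lp: _CompiledLP, status: str, obj: float, v: np.ndarray) -> FluxSolution:
    if status != "optimal":
        return FluxSolution("infeasible", 0.0, {})
    return FluxSolution("optimal", obj, dict(zip(lp.reaction_ids, v.tolist())))


def solve_fba(model: MetabolicModel) -> FluxSolution:
    """Maximize biomass flux subject to S v = 0 and the flux bounds."""
    lp = _compiled(model)
    return _to_solution(lp, *lp.solve())


def solve_pfba(model: MetabolicModel) -> FluxSolution:
    """Parsimonious FBA: biomass held at the FBA optimum, total absolute
    flux minimized."""
    lp = _compiled(model)
    return _to_solution(lp, *lp.solve_parsimonious())


# --------------------------------------------------------------------------
# Knockouts
# --------------------------------------------------------------------------

def apply_knockout(model: MetabolicModel, genes) -> MetabolicModel:
    """Zero the bounds of every reaction whose GPR evaluates false with
    ``genes`` absent; the input model is not mutated."""
    genes = frozenset(genes)
    unknown = genes - model.genes
    if unknown:
        raise KeyError(f"unknown genes {sorted(unknown)}")
    lp = _compiled(model)
    disabled = lp.disabled_by(genes)
    if not disabled:
        return model
    return model.update_bounds({lp.reaction_ids[j]: (0.0, 0.0) for j in disabled})


def knockout_grid(model: MetabolicModel, genes, carbons, scenario=None,
                  fitness=None, record_fluxes: bool = False,
                  growth_cutoff: float = GROWTH_CUTOFF,
                  carbon_overrides: dict | None = None):
    """Simulate every (gene, carbon) single knockout plus a wild-type row
    per carbon.

    ``scenario`` is a :class:`gemeval.scenarios.ScenarioSpec`; its medium
    is re-targeted at each carbon source in ``carbons``. Returns a
    prediction table (DataFrame with columns gene, carbon, biomass_flux,
    grows, fitness) and, when ``record_fluxes``, a dict mapping
    (gene-or-wild_type, carbon) to the parsimonious flux vector over
    ``model.reactions`` order for every optimal growth simulation.
    """
    from gemeval import scenarios as _sc

    if scenario is None:
        scenario = _sc.ScenarioSpec(medium=_sc.MediumSpec(components={}))
    genes = list(genes)
    rows = []
    fluxes: dict = {}
    for carbon in carbons:
        env = _sc.apply_scenario(
            model, replace(scenario, medium=replace(scenario.medium, carbon_source=carbon)),
            carbon_overrides=carbon_overrides,
        )
        lp = _CompiledLP(env)
        if record_fluxes:
            status, wt_obj, wt_v = lp.solve_parsimonious()
        else:
            status, wt_obj, wt_v = lp.solve()
        wt_grows = status == "optimal" and wt_obj >= growth_cutoff
        if not wt_grows:
            logger.warning("wild type does not grow on carbon %s (status=%s)",
                           carbon, status)
        rows.append({"gene": WILDTYPE, "carbon": carbon,
                     "biomass_flux": wt_obj if status == "optimal" else 0.0,
                     "grows": wt_grows, "fitness": float("nan")})
        if record_fluxes and status == "optimal":
            fluxes[(WILDTYPE, carbon)] = wt_v
        wt_status = status
        for gene in genes:
            disabled = lp.disabled_by({gene})
            # a knockout that only removes reactions carrying zero flux in
            # the wild-type optimum leaves that optimum feasible (and, for
            # pFBA, still minimal), so the solution can be reused
            if wt_status == "optimal" and (
                    not disabled or np.all(np.abs(wt_v[disabled]) <= 1e-8)):
                status, obj, v = wt_status, wt_obj, wt_v
            elif record_fluxes:
                status, obj, v = lp.solve_parsimonious(disabled)
            else:
                status, obj, v = lp.solve(disabled)
            obj = obj if status == "optimal" else 0.0
            grows = status == "optimal" and obj >= growth_cutoff
            fit = fitness.mean_fitness(gene, carbon) if fitness is not None else None
            rows.append({"gene": gene, "carbon": carbon, "biomass_flux": obj,
                         "grows": grows,
                         "fitness": float("nan") if fit is None else fit})
            if record_fluxes and status == "optimal" and grows:
                fluxes[(gene, carbon)] = v
    table = pd.DataFrame(rows, columns=["gene", "carbon", "biomass_flux",
                                        "grows", "fitness"])
    return (table, fluxes) if record_fluxes else (table, None)


def find_unconditional_essentials(model: MetabolicModel,
                                  growth_cutoff: float = GROWTH_CUTOFF) -> set:
    """Genes whose single knockout abolishes growth even with every
    exchange lower bound opened to -1000 (everything importable).

    These genes are essential regardless of the carbon source and are
    excluded from the conditional-essentiality evaluation.
    """
    opened = model.update_bounds(
        {r.id: (-1000.0, r.upper_bound) for r in model.exchanges}
    )
    lp = _CompiledLP(opened)
    essential = set()
    for gene in sorted(model.genes):
        disabled = lp.disabled_by({gene})
        if not disabled:
            continue
        status, obj, _ = lp.solve(disabled)
        if status != "optimal" or obj < growth_cutoff:
            essential.add(gene)
    return essential
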