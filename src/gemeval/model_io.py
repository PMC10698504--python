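"""Read/write metabolic models and fitness tables; parse GPR rules.

The in-memory data model is deliberately small: a stoichiometric network
with flux bounds, Boolean gene-protein-reaction (GPR) expressions, and a
designated biomass reaction. Models are read from the constraint-based
JSON dialect natively or from SBML through cobrapy; fitness tables are
plain TSV with one row per replicate.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

EXTRACELLULAR = "e"

__all__ = [
    "ModelIntegrityError",
    "GPRParseError",
    "GeneLiteral",
    "BoolOp",
    "GPRExpression",
    "parse_gpr",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FitnessDataset",
    "read_model",
    "write_model",
    "read_fitness",
    "match_dataset_to_model",
]


class ModelIntegrityError(ValueError):
    """Raised when a model violates a structural invariant."""


class GPRParseError(ValueError):
    """Raised on malformed GPR strings; carries the token position."""


# --------------------------------------------------------------------------
# GPR expression trees
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLiteral:
    gene: str

    def evaluate(self, knocked_out: frozenset | set) -> bool:
        return self.gene not in knocked_out

    def genes(self) -> set[str]:
        return {self.gene}

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple

    def evaluate(self, knocked_out: frozenset | set) -> bool:
        vals = (c.evaluate(knocked_out) for c in self.children)
        return all(vals) if self.op == "and" else any(vals)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize a looser-binding OR inside an AND
            if self.op == "and" and isinstance(c, BoolOp) and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


@dataclass(frozen=True)
class GPRExpression:
    """Boolean expression over gene literals; ``root=None`` means the
    reaction has no gene requirement and is never disabled by knockout."""

    root: GeneLiteral | BoolOp | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, knocked_out: frozenset | set) -> bool:
        """True iff the reaction remains catalyzable with ``knocked_out``
        genes absent (all other genes present)."""
        if self.root is None:
            return True
        return self.root.evaluate(knocked_out)

    def genes(self) -> set[str]:
        return set() if self.root is None else self.root.genes()

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def truth_table(self) -> dict[frozenset, bool]:
        """Exhaustive evaluation over all knockout subsets (<= ~12 genes);
        the canonical equality check for GPR round-trips."""
        gs = sorted(self.genes())
        if len(gs) > 16:  # pragma: no cover - guard against blow-up
            raise ValueError("truth_table limited to 16 genes")
        table = {}
        for mask in range(1 << len(gs)):
            ko = frozenset(g for i, g in enumerate(gs) if mask >> i & 1)
            table[ko] = self.evaluate(ko)
        return table

    def __eq__(self, other):
        if not isinstance(other, GPRExpression):
            return NotImplemented
        if self.genes() != other.genes():
            return False
        if self.root is None or other.root is None:
            return self.root is None and other.root is None
        return self.truth_table() == other.truth_table()

    def __hash__(self):
        return hash(frozenset(self.genes()))


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(expr: str) -> GPRExpression:
    """Parse a GPR string such as ``"(b0001 and b0002) or b0003"``.

    ``and``/``or`` are case-insensitive; ``and`` binds tighter than
    ``or``; the empty string yields the empty expression.
    """
    tokens = _tokenize(expr)
    if not tokens:
        return GPRExpression(None)
    idx = 0

    def peek():
        return tokens[idx][0].lower() if idx < len(tokens) else None

    def parse_or():
        nonlocal idx
        terms = [parse_and()]
        while peek() == "or":
            idx += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else BoolOp("or", tuple(terms))

    def parse_and():
        nonlocal idx
        factors = [parse_atom()]
        while peek() == "and":
            idx += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else BoolOp("and", tuple(factors))

    def parse_atom():
        nonlocal idx
        if idx >= len(tokens):
            raise GPRParseError(f"unexpected end of expression in {expr!r}")
        tok, pos = tokens[idx]
        low = tok.lower()
        if tok == "(":
            idx += 1
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis at position {pos} in {expr!r}")
            idx += 1
            return node
        if tok == ")" or low in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} at position {pos} in {expr!r}")
        idx += 1
        return GeneLiteral(tok)

    root = parse_or()
    if idx != len(tokens):
        tok, pos = tokens[idx]
        raise GPRParseError(f"stray token {tok!r} at position {pos} in {expr!r}")
    return GPRExpression(root)


# --------------------------------------------------------------------------
# Model data classes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: dict  # metabolite id -> signed coefficient
    lower_bound: float
    upper_bound: float
    gpr: GPRExpression = field(default_factory=GPRExpression)
    is_exchange: bool = False
    name: str = ""

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not any(c != 0 for c in self.stoichiometry.values()):
            raise ModelIntegrityError(f"reaction {self.id!r} has empty stoichiometry")


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometric network with GPR rules and a biomass objective.

    Immutable: all edits (media, knockouts, corrections) return new
    models, so scenario application never mutates its input.
    """

    id: str
    metabolites: tuple
    reactions: tuple
    genes: frozenset
    biomass_reaction_id: str
    compartments: dict = field(default_factory=dict)

    def __post_init__(self):
        met_ids = {m.id for m in self.metabolites}
        if len(met_ids) != len(self.metabolites):
            raise ModelIntegrityError("duplicate metabolite ids")
        rxn_ids = {r.id for r in self.reactions}
        if len(rxn_ids) != len(self.reactions):
            raise ModelIntegrityError("duplicate reaction ids")
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_ids
            if missing:
                raise ModelIntegrityError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
        if self.biomass_reaction_id not in rxn_ids:
            raise ModelIntegrityError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        gpr_genes = set()
        for r in self.reactions:
            gpr_genes |= r.gpr.genes()
        if not gpr_genes <= self.genes:
            raise ModelIntegrityError(
                f"GPR genes missing from gene set: {sorted(gpr_genes - self.genes)}"
            )

    # -- lookups ----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index()

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def _met_index(self):
        idx = getattr(self, "_mets", None)
        if idx is None:
            idx = {m.id: m for m in self.metabolites}
            object.__setattr__(self, "_mets", idx)
        return idx

    def _rxn_index(self):
        idx = getattr(self, "_rxns", None)
        if idx is None:
            idx = {r.id: r for r in self.reactions}
            object.__setattr__(self, "_rxns", idx)
        return idx

    @property
    def exchanges(self) -> tuple:
        return tuple(r for r in self.reactions if r.is_exchange)

    def exchange_for(self, met_id: str) -> Reaction | None:
        """The exchange reaction touching exactly this metabolite, if any."""
        for r in self.reactions:
            if r.is_exchange and list(r.stoichiometry) == [met_id]:
                return r
        return None

    # -- functional updates ------------------------------------------------
    def with_reactions(self, new_reactions) -> "MetabolicModel":
        return replace(self, reactions=tuple(new_reactions))

    def update_reaction(self, rxn_id: str, **changes) -> "MetabolicModel":
        if not self.has_reaction(rxn_id):
            raise KeyError(f"unknown reaction {rxn_id!r}")
        return self.with_reactions(
            replace(r, **changes) if r.id == rxn_id else r for r in self.reactions
        )

    def update_bounds(self, bound_map: dict) -> "MetabolicModel":
        """Set (lower, upper) bounds for several reactions at once."""
        unknown = set(bound_map) - {r.id for r in self.reactions}
        if unknown:
            raise KeyError(f"unknown reactions {sorted(unknown)}")
        return self.with_reactions(
            replace(r, lower_bound=bound_map[r.id][0], upper_bound=bound_map[r.id][1])
            if r.id in bound_map
            else r
            for r in self.reactions
        )


def _flag_exchange(stoich: dict, met_compartments: dict) -> bool:
    if len(stoich) != 1:
        return False
    (mid,) = stoich
    return met_compartments.get(mid) == EXTRACELLULAR


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _model_from_parts(model_id, metabolites, reactions, declared_genes, biomass_id,
                      compartments):
    gpr_genes = set()
    for r in reactions:
        gpr_genes |= r.gpr.genes()
    genes = frozenset(gpr_genes | set(declared_genes))
    if biomass_id is None:
        # fall back on the conventional id pattern
        candidates = [r.id for r in reactions if "biomass" in r.id.lower()]
        if len(candidates) != 1:
            raise ModelIntegrityError(
                "no objective flagged and no unique biomass-named reaction"
            )
        biomass_id = candidates[0]
    return MetabolicModel(
        id=model_id,
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        genes=genes,
        biomass_reaction_id=biomass_id,
        compartments=dict(compartments),
    )


def _read_json(path) -> MetabolicModel:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("metabolites", "reactions"):
        if key not in doc:
            raise ModelIntegrityError(f"model JSON missing {key!r} section")
    compartments = dict(doc.get("compartments", {}))
    mets = []
    for m in doc["metabolites"]:
        mets.append(
            Metabolite(id=m["id"], name=m.get("name", ""),
                       compartment=m.get("compartment", "c"))
        )
    met_comp = {m.id: m.compartment for m in mets}
    biomass_id = None
    rxns = []
    for r in doc["reactions"]:
        stoich = {k: float(v) for k, v in r["metabolites"].items()}
        gpr = parse_gpr(r.get("gene_reaction_rule", ""))
        rxn = Reaction(
            id=r["id"],
            stoichiometry=stoich,
            lower_bound=float(r.get("lower_bound", 0.0)),
            upper_bound=float(r.get("upper_bound", 1000.0)),
            gpr=gpr,
            is_exchange=_flag_exchange(stoich, met_comp),
            name=r.get("name", ""),
        )
        rxns.append(rxn)
        if float(r.get("objective_coefficient", 0.0)) != 0.0:
            biomass_id = rxn.id
    declared = [g["id"] for g in doc.get("genes", [])]
    return _model_from_parts(doc.get("id", "model"), mets, rxns, declared,
                             biomass_id, compartments)


def _read_sbml(path) -> MetabolicModel:
    # cobrapy handles the SBML/fbc machinery; we convert to our data model
    from cobra.io import read_sbml_model

    cm = read_sbml_model(str(path))
    mets = [Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
            for m in cm.metabolites]
    met_comp = {m.id: m.compartment for m in mets}
    biomass_id = None
    rxns = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=parse_gpr(r.gene_reaction_rule or ""),
                is_exchange=_flag_exchange(stoich, met_comp),
                name=r.name or "",
            )
        )
        if r.objective_coefficient:
            biomass_id = r.id
    declared = [g.id for g in cm.genes]
    return _model_from_parts(cm.id or "model", mets, rxns, declared, biomass_id,
                             dict(cm.compartments))


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read a metabolic model from constraint-based JSON or SBML.

    ``format`` is inferred from the file suffix when omitted.
    """
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "json"
    if format == "json":
        return _read_json(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path) -> None:
    """Write the model in the constraint-based JSON dialect."""
    doc = {
        "id": model.id,
        "compartments": model.compartments,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "metabolites": r.stoichiometry,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gene_reaction_rule": r.gpr.to_string(),
                "objective_coefficient": 1.0 if r.id == model.biomass_reaction_id else 0.0,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g} for g in sorted(model.genes)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# --------------------------------------------------------------------------
# Fitness tables
# --------------------------------------------------------------------------

@dataclass
class FitnessDataset:
    """Replicate-averaged gene x carbon fitness values.

    ``records`` maps (gene, carbon) -> (replicate values tuple, mean).
    """

    records: dict
    carbon_sources: list
    genes: list
    exclusions: list = field(default_factory=list)
    n_dropped_missing: int = 0

    def mean_fitness(self, gene: str, carbon: str) -> float | None:
        rec = self.records.get((gene, carbon))
        return None if rec is None else rec[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "carbon": c, "fitness": mean, "n_replicates": len(reps)}
            for (g, c), (reps, mean) in sorted(self.records.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "carbon", "fitness", "n_replicates"])


def read_fitness(path, exclusions: list | None = None) -> FitnessDataset:
    """Read a replicate-level fitness TSV (columns gene, carbon, fitness),
    average replicates per (gene, carbon) and drop excluded carbons.

    Rows with missing fitness are dropped and counted; RB-TnSeq carbon
    experiments come in duplicate replicates, which are averaged.
    """
    exclusions = list(exclusions or [])
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    required = {"gene", "carbon", "fitness"}
    if not required <= set(df.columns):
        raise ValueError(
            f"fitness table missing required columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        logger.warning("fitness table %s is empty", path)
        return FitnessDataset({}, [], [], exclusions)
    n_missing = int(df["fitness"].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with missing fitness", n_missing)
        df = df.dropna(subset=["fitness"])
    df = df[~df["carbon"].isin(exclusions)]
    records = {}
    for (gene, carbon), grp in df.groupby(["gene", "carbon"], sort=True):
        vals = tuple(float(v) for v in grp["fitness"])
        records[(gene, carbon)] = (vals, sum(vals) / len(vals))
    carbons = sorted({c for _, c in records})
    genes = sorted({g for g, _ in records})
    return FitnessDataset(records, carbons, genes, exclusions, n_missing)


def resolve_carbon(model: MetabolicModel, carbon: str,
                   overrides: dict | None = None) -> str | None:
    """Map a carbon-source identifier to an extracellular metabolite id.

    Default rule: carbon ``"X"`` matches metabolite ``"X_e"`` (or ``"X"``
    itself if already compartment-suffixed); ``overrides`` handles
    irregular names.
    """
    if overrides and carbon in overrides:
        cand = overrides[carbon]
        return cand if model.has_metabolite(cand) else None
    for cand in (f"{carbon}_{EXTRACELLULAR}", carbon):
        if model.has_metabolite(cand):
            m = model.metabolite(cand)
            if m.compartment == EXTRACELLULAR:
                return cand
    return None


def match_dataset_to_model(model: MetabolicModel, dataset: FitnessDataset,
                           carbon_overrides: dict | None = None):
    """Intersect dataset genes/carbons with the model.

    Returns (matched_genes, matched_carbons, report) where the report is a
    DataFrame enumerating every unmatched identifier and the reason.
    """
    matched_genes = sorted(set(dataset.genes) & model.genes)
    unmatched = [
        {"id": g, "kind": "gene", "reason": "not in model gene set"}
        for g in dataset.genes if g not in model.genes
    ]
    matched_carbons = []
    for c in dataset.carbon_sources:
        met = resolve_carbon(model, c, carbon_overrides)
        if met is None:
            unmatched.append(
                {"id": c, "kind": "carbon",
                 "reason": "no extracellular metabolite for this carbon id"}
            )
        else:
            matched_carbons.append(c)
    report = pd.DataFrame(unmatched, columns=["id", "kind", "reason"])
    return matched_genes, matched_carbons, report
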