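"""Independent brute-force oracles used to validate the package.

Everything here is deliberately naive and self-contained (no imports
from gemeval's computational internals beyond data-model construction),
so each oracle stays an independent route against the implementation it
checks:

* flux polytope vertex enumeration (LP optimum by exhaustion);
* threshold-loop precision-recall AUC;
* breadth-first-search distances on adjacency dicts;
* pairwise-correlation union-find clustering;
* random generators for small networks, prediction tables and bipartite
  graphs.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from gemeval.model_io import MetabolicModel, Metabolite, Reaction, parse_gpr


# --------------------------------------------------------------------------
# Flux polytope vertex enumeration
# --------------------------------------------------------------------------

def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-9) -> list:
    """All vertices of {v : S v = 0, lb <= v <= ub} (bounded polytope).

    A vertex has n linearly independent active constraints: the m' rank
    rows of S plus n - m' bounds pinned at lb or ub. Enumerate every
    choice of pinned variables and pin sides, solve the square system
    for the free variables, and keep consistent, in-bounds solutions.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[1]
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_pin = n - r
    vertices = []
    for pinned_tuple in combinations(range(n), n_pin):
        pinned = list(pinned_tuple)
        free = [j for j in range(n) if j not in pinned]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue  # free part underdetermined: not a vertex basis
        for sides in product((0, 1), repeat=n_pin):
            v = np.empty(n)
            for j, side in zip(pinned, sides):
                v[j] = ub[j] if side else lb[j]
            rhs = -S[:, pinned] @ v[pinned] if n_pin else np.zeros(S.shape[0])
            if free:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue  # inconsistent pin assignment
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(np.clip(v, lb, ub))
    return vertices


def lp_max_by_enumeration(S, lb, ub, obj_idx: int) -> float:
    """Maximum of v[obj_idx] over the flux polytope, by vertex
    exhaustion; the polytope must be bounded and contain 0."""
    verts = enumerate_vertices(S, np.asarray(lb, float), np.asarray(ub, float))
    if not verts:
        raise RuntimeError("no vertices found (unexpected for 0-feasible bounds)")
    return max(float(v[obj_idx]) for v in verts)


def alternative_optima_vertices(S, lb, ub, obj_idx: int, opt: float,
                                tol: float = 1e-6) -> list:
    """Vertices attaining the optimal objective value (within tol)."""
    verts = enumerate_vertices(S, np.asarray(lb, float), np.asarray(ub, float))
    return [v for v in verts if abs(v[obj_idx] - opt) <= tol]


def random_network(rng: np.random.Generator, max_reactions: int = 8):
    """Random small stoichiometric network with finite bounds containing
    zero. Returns (model, S, lb, ub, obj_idx)."""
    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(1, max(2, n - 1)))
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        if np.all(np.any(S != 0, axis=0)):  # every reaction touches a metabolite
            break
    lb = np.where(rng.random(n) < 0.5, -10.0, 0.0)
    ub = np.where(rng.random(n) < 0.8, 10.0, 0.0)
    ub = np.maximum(ub, lb)  # keep lb <= 0 <= ub feasible
    obj_idx = int(rng.integers(0, n))
    mets = [Metabolite(id=f"M{i}", compartment="c") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"M{i}": float(S[i, j]) for i in range(m) if S[i, j] != 0}
        rxns.append(Reaction(id=f"R{j}", stoichiometry=stoich,
                             lower_bound=float(lb[j]), upper_bound=float(ub[j])))
    model = MetabolicModel(id="random", metabolites=tuple(mets),
                           reactions=tuple(rxns), genes=frozenset(),
                           biomass_reaction_id=f"R{obj_idx}",
                           compartments={"c": "cytoplasm"})
    return model, S, lb, ub, obj_idx


# --------------------------------------------------------------------------
# Precision-recall AUC by explicit threshold loop
# --------------------------------------------------------------------------

def pr_auc_bruteforce(essential, fitness) -> float:
    """PR-AUC with positive class = essential, threshold loop over the
    unique fitness values (predicted positive when fitness <= t),
    trapezoid with the (recall 0, precision 1) anchor."""
    essential = np.asarray(essential, dtype=bool)
    fitness = np.asarray(fitness, dtype=float)
    n_pos = int(essential.sum())
    if n_pos == 0:
        return float("nan")
    points = [(0.0, 1.0)]
    for t in np.sort(np.unique(fitness)):
        called = fitness <= t
        tp = int((called & essential).sum())
        points.append((tp / n_pos, tp / int(called.sum())))
    auc = 0.0
    for (r0, p0), (r1, p1) in zip(points[:-1], points[1:]):
        auc += (r1 - r0) * (p0 + p1) / 2
    return auc


def random_prediction_table(rng: np.random.Generator, n: int = 500):
    """Random prediction-table columns: bimodal fitness with ties and a
    weakly informative essentiality call."""
    import pandas as pd

    essential = rng.random(n) < rng.uniform(0.05, 0.5)
    fitness = np.where(essential & (rng.random(n) < 0.7),
                       rng.normal(-4, 1, n), rng.normal(0, 1, n))
    fitness = np.round(fitness, 2)  # induce ties
    return pd.DataFrame({
        "gene": [f"g{i}" for i in range(n)],
        "carbon": rng.choice(["c1", "c2", "c3"], size=n),
        "biomass_flux": np.where(essential, 0.0, 1.0),
        "grows": ~essential,
        "fitness": fitness,
    })


# --------------------------------------------------------------------------
# Graph distances by plain BFS
# --------------------------------------------------------------------------

def bfs_distances(adj: dict, source) -> dict:
    """Hop counts from source over an adjacency dict."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def random_bipartite_adjacency(rng: np.random.Generator, n_mets: int = 12,
                               n_rxns: int = 14, p_edge: float = 0.18):
    """Random metabolite-reaction adjacency dict with prefixed node
    names matching the package's graph convention."""
    adj: dict = {}
    mets = [f"met:m{i}" for i in range(n_mets)]
    rxns = [f"rxn:r{j}" for j in range(n_rxns)]
    for node in mets + rxns:
        adj[node] = set()
    for m in mets:
        for r in rxns:
            if rng.random() < p_edge:
                adj[m].add(r)
                adj[r].add(m)
    return adj, mets, rxns


# --------------------------------------------------------------------------
# Correlation clustering by pairwise union-find
# --------------------------------------------------------------------------

def cluster_bruteforce(X: np.ndarray, var_min: float, corr_min: float) -> list:
    """Connected components of the |Pearson| > corr_min graph over
    variance-retained columns, with per-pair correlation computed from
    the definition."""
    X = np.asarray(X, dtype=float)
    retained = [j for j in range(X.shape[1]) if X[:, j].var() >= var_min]
    parent = {j: j for j in retained}

    def find(j):
        while parent[j] != j:
            j = parent[j]
        return j

    for a, b in combinations(retained, 2):
        xa = X[:, a] - X[:, a].mean()
        xb = X[:, b] - X[:, b].mean()
        denom = np.sqrt((xa ** 2).sum() * (xb ** 2).sum())
        if denom == 0:
            continue
        if abs(float((xa * xb).sum()) / denom) > corr_min:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    groups: dict = {}
    for j in retained:
        groups.setdefault(find(j), []).append(j)
    return sorted(sorted(v) for v in groups.values())
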