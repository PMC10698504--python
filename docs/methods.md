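# Methods

## Growth simulation

A metabolic model is a stoichiometric matrix S (metabolites ×
reactions) with flux bounds l ≤ v ≤ u, Boolean gene–protein–reaction
(GPR) rules, and a designated biomass reaction. FBA maximizes biomass
flux subject to steady state (S v = 0) and the bounds; the LP is solved
with HiGHS through `scipy.optimize.linprog`, which is deterministic
across restarts. Infeasible knockout LPs are reported as biomass 0 /
no-growth rather than errors — knockouts legitimately make the problem
infeasible, and the two cases (infeasible vs. tiny positive biomass)
are distinguished in the solution status. An unbounded objective raises
an error naming the reactions with infinite bounds, since it indicates
a missing constraint rather than a biological outcome.

Parsimonious FBA is the standard two-stage LP: fix the biomass flux at
its FBA optimum (with 1e-9 slack so the second stage stays feasible),
split each flux into non-negative forward and reverse parts, and
minimize their sum. The reported Σ|v| is therefore minimal among
alternative optima, and detached reversible cycles carry exactly zero
flux.

Knockouts evaluate each reaction's GPR tree with the knocked-out genes
false and all others true; reactions that evaluate false get both
bounds set to zero. Zero-bounding (rather than deletion) keeps the
reaction index of flux vectors fixed across simulations, which the
flux-ML stage requires. Strain-difference gene removal, by contrast,
deletes unsatisfiable reactions outright — a permanent difference, not
an experimental perturbation. One optimization: a knockout that only
disables reactions carrying zero flux in the wild-type optimum reuses
the wild-type solution, which is exact (the solution remains feasible
and optimal, and for pFBA remains total-flux-minimal).

Growth is binarized at biomass flux 0.001 h⁻¹, with the cutoff value
itself counting as growth. Media are built by closing every exchange
lower bound, opening the listed components (−1000 mmol gDW⁻¹ h⁻¹ for
unrestricted uptake), and setting the carbon source's exchange to −10;
when the carbon source collides with a base component the carbon bound
wins, because carbon limitation is the experimentally meaningful
constraint.

Genes essential even with every exchange opened to −1000
("unconditionally essential") are excluded from evaluation once, on the
uncorrected model; corrected model variants are scored on the same
experiment set so correction effects are not confounded with gene-set
changes.

## Accuracy metrics

The precision–recall curve uses model-predicted essentiality
(no-growth) as the positive class and fitness as the score: at
threshold t an experiment is called experimentally essential when
fitness ≤ t (ties collapse to one threshold; the ≤ convention is a
documented choice — AUC is unaffected for continuous fitness). The AUC
is the trapezoid over the (recall, precision) points anchored at
(0, 1). Undefined metrics (no essential predictions, single-class ROC)
are NaN with a warning, never silently 0.

The confusion matrix, overall accuracy and balanced accuracy use a
fixed experimental threshold, fitness < −2 (strict), matching the
labelling rule of the ML stage. The null model appends nonfunctional
genes (fitness exactly 0, predicted growth) until a target experiment
count is reached; because every null row is a true positive, accuracy
metrics inflate while the PR-AUC barely moves — the property that
motivates the choice of metric.

Error rankings aggregate genes by mean fitness within their prediction
class: high-fitness genes among essential predictions are
false-negative candidates, low-fitness genes among growth predictions
false-positive candidates; ties break by gene id for determinism.

## Corrections

* **Supplementation** — extracellular mode opens the existing exchange
  to −1000; intracellular mode creates an uptake-only exchange
  (−1000, 0) directly on the cytoplasmic species. Uptake-only is the
  minimal mechanism and prevents the supplement from earning secretion
  flux; the upper bound 0 is a choice the data cannot pin down, flagged
  for sensitivity analysis.
* **Irreversibilization** — lower bound to 0, upper bound untouched.
* **Isoenzyme reassignment** — the reaction's GPR becomes the single
  literal of the experimentally essential gene, removing the silent
  partner's rescue.

Scenario application (strain genes → medium → supplements →
irreversibilizations → reassignments → fixed fluxes) is idempotent; the
medium precedes supplements so supplement exchanges stay open.

## Network distance

The model becomes an undirected bipartite graph with one node per
metabolite and reaction and an edge per nonzero stoichiometric entry.
Nodes with more than 50 connections are removed as hubs (currency
metabolites, biomass) except those in a keep list (carbon sources such
as pyruvate in real models). Distances are breadth-first searches —
with unit edges Dijkstra reduces to BFS, and BFS is deterministic. A
metabolite-to-reaction path of 2k+1 edges traverses k reactions before
the target, so a reaction consuming the carbon source directly has
distance 0. The distance of a gene is the minimum over the reactions
its knockout removes. Unreachable experiments are excluded from means
and counted, rather than imputed with an arbitrary sentinel. The three
experiment subsets are nested: all experiments whose gene removes ≥ 1
reaction ⊇ model no-growth ⊇ carbon-specific no-growth (no-growth on at
most 80 % of carbons).

## Flux-based misprediction analysis

Growth-predicted knockouts contribute their parsimonious flux vectors
to a samples × reactions matrix (plus per-carbon wild-type rows).
Columns with variance < 1e-7 are dropped; the rest are grouped into
connected components of the |Pearson r| > 0.99 graph. The sign-agnostic
threshold is an interpretation choice: exactly counter-running reaction
pairs (e.g. a proton and a sodium symporter moving the same metabolite
oppositely) are one redundant feature. Single-linkage components and
the lowest-index representative are likewise deliberate, auditable
choices where no canonical rule exists.

The classifier separates false positives (fitness < −2 despite
predicted growth; the threshold is configurable, and a −1 relabelling
run checks robustness of the importance ranking) from true positives:
LightGBM gradient-boosted trees, 5 leaves, 100 trees, learning rate
0.1, other parameters at defaults, seeded and single-threaded for
determinism. Evaluation repeats 100 train/test splits: each draws a
uniform 80 % of carbons and 80 % of genes (floor, minimum 1); training
rows need both in the training sets, the full test set is everything
else, and the unseen subset requires both gene and carbon to be absent
from training. A split whose training rows are single-class is replaced
by a deterministic redraw (seed offset 1 000 000) — rare at realistic
false-positive rates. Scores are PR-AUCs for the false-positive class,
plus a permuted-label baseline. The expected PR-AUC of a random ranking
is the prevalence of the evaluated test set (with a small positive
finite-sample bias from the trapezoid anchor), so the harness records
per-split test prevalences for that comparison.

Feature attribution uses exact TreeSHAP as implemented natively by
LightGBM (`pred_contrib`); values are reported for the true-positive
class (the negative of the binary model's raw-score contributions) and
averaged across the 100 splits. Additivity — base value plus
contributions equals the raw margin per sample — is asserted in tests.

## Synthetic study design

The toy GEM mirrors the structures that generate each error class in
real reconstructions:

* **Per-carbon catabolic chains** (default 12 carbons × 4 genes):
  transporter plus linear pathway feeding a shared `core_c` precursor.
  Knockouts are carbon-specific and sit near "their" carbon in the
  network. Final-step stoichiometries (biomass yields) are drawn
  uniformly from 0.6–1.4 per carbon: real substrates differ in yield,
  and this gives the core/biomass flux cluster continuous cross-carbon
  variation.
* **Vitamin pathways** (default 5, chain lengths 2–4): products are
  biomass components, so every pathway gene is model-essential on all
  carbons. Two pathways have an extracellular species with exchange and
  transporter (supplementable extracellularly); three have only an
  extracellular *precursor* with a closed exchange and need the
  intracellular supplement. The precursor route also keeps these genes
  conditionally essential under the all-exchanges-open filter, as their
  real counterparts are. All vitamin genes carry the carry-over error:
  experimentally non-essential despite model essentiality.
* **Isoenzyme pairs** (default 3): `main or alt` GPRs on reactions
  feeding biomass; the alternative gene is regulatorily silent, so the
  main gene is experimentally essential while the model predicts
  growth.
* **Reversible bypass**: a two-gene serine-like pathway whose product
  can also be made by running a reversible reaction backwards from a
  spontaneous side product; the pathway genes are false positives until
  the reaction is irreversibilized.

Error genes are deliberately a minority relative to correctly predicted
conditional essentials, matching the structure of real
model-vs-fitness comparisons; with the ratio inverted, threshold-free
metrics behave qualitatively differently.

Fitness values are Gaussian: N(−4, 0.5) per replicate when the
*experimental* truth says essential (the model truth adjusted by the
error class), N(0, 0.5) otherwise, two replicates per condition,
averaged on ingestion. The real fitness distribution is heavier-tailed
and asymmetric; Gaussian noise suffices because every statistic used
downstream depends only on the ordinal separation of the two classes.
Passing tests on this fixture therefore demonstrate the *machinery* —
metric correctness, correction logic, recovery of planted structure —
not that any particular real model achieves a given score.

Ground truth is constructed analytically and then verified by
exhaustive single-knockout FBA over every gene × carbon pair at
generation time; a non-growing wild type is a generation error, never a
silent return.

For classifier benchmarks, a logistic false-positive signal can be
planted in a flux feature: P(FP) = σ(intercept + effect·z +
b_carbon), with z the standardized planted column (the biomass-cluster
representative by default, so the signal generalizes across carbons),
effect 3.0 (a strong planted signal), intercept −1.1, and per-carbon
offsets b ~ N(0, 0.75) that make part of the signal carbon-specific —
hence full cross-validation is designed to score at least as well as
the unseen-carbon/gene subset.

## Problem sizes and numerics

The default study is 12 carbons × 72 genes (864 experiments, ~640
growth flux vectors of 94 reactions), small enough that exhaustive
oracles — flux-polytope vertex enumeration on ≤ 8-reaction random
networks, brute-force threshold loops, BFS, union-find — verify every
computational path exactly. LP equality assertions use 1e-6; PR-AUC
oracle agreement is exact to 1e-12; SHAP additivity to 1e-6.
Tie-breaks are deterministic everywhere (lowest column index, sorted
gene ids, seeded RNGs), so every pipeline stage is rerun-identical
given its configuration.

## Limitations

* FBA/pFBA only: no MOMA or ROOM knockout models, no flux variability
  analysis, no thermodynamic or enzyme-capacity constraints.
* The generator does not emulate replicate-level noise structure,
  t-score shrinkage, or the empirical fitness distribution of real
  RB-TnSeq data.
* Correction candidates are ranked, not chosen: applying a correction
  remains a user decision, as automated selection would need evidence
  weighting the framework does not model.
* Real-data runs require a user-supplied carbon-to-metabolite override
  map for irregular names; there is no automatic identifier matching.
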