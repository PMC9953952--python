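# Methods

## Problem and scope

`kgxplain` classifies single-nucleotide variants as pathogenic or benign from
integrated database annotations and explains each call with ranked,
template-rendered sentences. It operates on simplified tab-separated
emulations of ClinVar, COSMIC, dbNSFP and dbscSNV (schemas documented in
`kgxplain.annotations`), not on the real databases: the real sources are
terabyte-scale and partly proprietary, while everything this package is meant
to demonstrate — hub-joined graph integration, leakage-safe evaluation,
perturbation-based attribution, rule-based explanation — is a property of the
method, not of the data volume.

## Knowledge graph

Nodes are typed (`variant_hub`, `gene_hub`, `clinvar_record`,
`cosmic_record`, `dbnsfp_record`/`dbnsfp_score`, `dbscsnv_record`/`_score`,
`publication`, `literal_value`) and carry a source-database tag. Edges are
(subject, predicate, object) triples with set semantics: re-adding a triple
is a no-op and the triple count is the unit of graph size. Every annotation
record attaches to exactly one hub (enforced; violating it raises an
integrity error), and variant hubs link to gene hubs. Coordinates are
1-based fully closed; alleles are uppercased and chromosome labels stored
without a `chr` prefix.

Traversal (`reachable_subgraph`) follows stored edge directions, except that
incoming edges are crossed in reverse at hub nodes. This is a deliberate
choice: the explanation subgraph must reach the records of neighboring
variants, which sit on the far side of their hubs; a purely directed walk
from a hub would never see the records that point *into* it.

N-Triples serialization writes exactly one triple per edge. Node type,
source and scalar payload are encoded in synthesized IRIs under a fixed
project namespace; `literal_value` nodes serialize as typed RDF literals.
Two consequences are documented rather than hidden: isolated nodes are not
representable in `.nt` (standard for triple stores), and a literal node
shared by several parents would split on reload — the builders in this
package never create such sharing. Round trips preserve node payloads
exactly and graph content up to renaming of literal-node identifiers.

## Feature subgraphs and the two models

The neighbor window is 100 bases, center-position distance, inclusive at
100. Neighbor expansion is one hop: neighbors of neighbors are not pulled
in, matching how a curator scans the immediate locus. The neighbor set is
drawn from all variants present in any loaded source.

Two trained models exist because ClinVar provides the training labels:

* the **estimation** model never sees the target's ClinVar record, and its
  target dbNSFP features are restricted to six non-ensemble algorithms;
  ensemble scores (CADD, REVEL, MetaLR, ...) are themselves trained on
  ClinVar and would inflate apparent performance through label circularity.
  Neighbor ClinVar records remain visible in both modes — they are evidence
  about the locus, not the target's label.
* the **explanation** model sees everything, but a seeded random half of its
  training variants are built without their own ClinVar record
  (`make_mask_plan`), so the model retains explanatory power for variants
  absent from ClinVar.

The `explain` entry point refuses an estimation-mode model, and estimation
graphs are checked at construction time for ClinVar leakage and whitelist
violations.

## Classifier backend

The scoring backend is a graph-feature-hashing logistic model. Each edge
yields one token describing what it asserts, with the target/neighbor role
as a prefix; numeric payloads (scores, log10 sample counts, scaled star
counts) become the token's value, categorical payloads join the token
string. Tokens hash (BLAKE2, stable across processes) into a
4096-dimensional signed vector; a graph's vector is the sum over its edges;
an L2-regularized logistic regression (C = 1.0, deterministic lbfgs) maps it
to a score in [0, 1]. The `epochs` knob scales the optimizer's iteration
budget. Scores are monotone calibrated by construction (sigmoid output) but
are not claimed to be probabilities; evaluation relies on rank consistency
for AUC plus the fixed 0.5 decision threshold (score ≥ 0.5 ⇒ pathogenic,
boundary included).

No GNN backend ships in this build: the hashing model is the deterministic,
CPU-scale reference implementation of the backend contract
(train / predict / edge_contributions), and the contract point is exactly so
a heavier graph learner can be slotted in later.

## Attribution

`edge_contributions` fits a local linear surrogate over edge-masking
perturbations. Masks are uniform over edge subsets; masked graphs are
re-scored (vectorized, since the backend is linear in edge presence before
the sigmoid); the surrogate is fitted with a small ridge penalty (1e-3) on
sampled masks (default 256), or as an exact unpenalized least-squares fit
when the full 2^E mask space fits the budget — on such graphs the output
equals the exact surrogate to numerical precision, which the tests assert
against an independent normal-equations oracle.

Edge-to-node folding uses signed max magnitude over incident edges: it
reduces to equality for a single incident edge and does not double-count
evidence the way summation would. `sum` and `mean` are selectable. The same
max-magnitude convention aggregates node contributions over a sentence's
support set, and the impact weight is taken from the node type of the
max-magnitude supporter.

## Explanation rules and ranking

Ten rules cover: neighbor ClinVar tallies, outstanding dbNSFP algorithms,
prediction/conservation score averages, same-residue neighbors, neighbor
publication counts, neighbor COSMIC registrations, per-algorithm dbNSFP
sentences, target literature references, the target's ClinVar entry, and the
variant type. Conventions fixed by the reference sentence set:

* qualifier bands for "outstanding" algorithms: high ≥ 0.70, moderate
  [0.50, 0.70), below 0.50 omitted; scores print to 2 decimals;
* count formatting is a per-template attribute: tally rules spell counts as
  English words ("Fourteen ... three of which ...", "twenty-six papers"),
  score/record rules use digits ("14 prediction algorithms", "3 stars") —
  the reference sentences themselves mix the two styles, so a single global
  rule cannot reproduce them;
* same-residue matching parses the residue number out of HGVS-p-like strings
  from COSMIC records (no transcript model exists here);
* algorithm classes: conservation = {phyloP100way_vertebrate, GERP++_RS,
  SiPhy_29way_logOdds, phastCons100way_vertebrate}; all other registered
  algorithms count as prediction. The registry holds 19 algorithms (6
  estimation + 13 explanation-only).

X-Impact defaults (clinvar_record 2.0, cosmic_record 1.5, dbnsfp_score 1.0,
publication 1.0, baseline 0.5) encode that a database listing is the first
thing a physician checks; they are not fitted quantities and are fully
overridable via the YAML config (`load_explainer_config`).

Sentences are sorted by **descending** X-Factor and truncated to top-N, with
ties broken by rule table order then text. X-Factor is computed with the
overflow-safe sigmoid and clamped to the open unit interval so extreme
attribution products still rank.

## Baseline flattening

The fixed-length vector contains: the six estimation dbNSFP scores (−1
sentinel when missing), COSMIC registration flag, log10 sample-count bin
(1→0, (1,10]→1, ..., >10000→5) and publication total, and neighbor tallies
within four distance bins (1–10, 11–25, 26–50, 51–100 bases): counts,
per-significance counts, the two categorical crosses
(consequence × significance, and consequence × star-band × significance,
with stars banded at ≥ 2), per-publisher ClinVar publication counts, and
COSMIC registration/publication totals. Per-base bins are configurable; the
coarse default keeps the vector in the hundreds of features, which is where
tree baselines behave well. Vector length depends only on the schema —
never on neighbor, record or publication counts — and flattening is
invariant to input record order.

Baselines are scikit-learn `DecisionTreeClassifier` (default depth 9) and
`RandomForestClassifier` (200 trees), scored by pathogenic-class
probability.

## Evaluation protocol

Estimation answer set: missense records with ≥ 2 review stars and an exact
Pathogenic/Benign call; Likely_* and VUS excluded. Explanation answer set:
Likely_* mapped to parent labels, all SNV consequences admitted, majority
class downsampled to parity. Balancing always preserves the minority class
completely and is seed-reproducible.

Chromosomes are packed into five folds greedily, largest variant count
first, into the lightest fold (seeded shuffle breaks ties among equal-sized
chromosomes). Every variant inherits its chromosome's fold; cross-validation
re-checks disjointness per fold and raises on any overlap rather than
silently reporting optimistic numbers. Metrics are accuracy, precision,
recall and F1 at the fixed 0.5 threshold (pathogenic = positive class) plus
rank AUC and ROC points; the reported performance is the arithmetic mean
over folds. A parameter-sweep helper reproduces the
"best-parameter-is-the-performance" protocol over epochs (graph model) or
depth (trees).

## Synthetic data

Defaults: 10 chromosomes × 5 genes × 40 variants = 2000 variants,
pathogenic fraction 0.5, near-exponential inter-variant gaps with mean 60
bases (so most variants have a neighbor within the 100-base window),
clustering 0.5, score separation 0.3 around a benign mean of 0.35
(Beta-distributed with concentration 10 — bounded support matches rank-style
scores), COSMIC counts log-uniform over two decades plus a one-decade
pathogenic shift, coverages 0.9/0.6/0.95/0.3 for
ClinVar/COSMIC/dbNSFP/dbscSNV, ClinVar significance noise 0.02 with a
0.7/0.2/0.1 split of exact/Likely/VUS records. Everything is driven by one
seed and regenerates byte-identical tables.

`SimulationConfig.null()` zeroes all three signal channels (score
separation, clustering, COSMIC shift); with it the full pipeline's CV AUC is
statistically indistinguishable from 0.5, which is the global negative
control the test suite asserts.

What the generator does **not** emulate: real genome coordinates and
transcript structure, linkage between consequence and scores, multi-record
variants, inter-algorithm score correlation (scores are conditionally
independent given the class), and realistic class imbalance. Passing the
synthetic benchmark therefore shows that the pipeline recovers a planted
signal without leakage at desk scale — not that its absolute accuracy
transfers to real ClinVar data.

## Numerical and degenerate-input choices

* variant with no annotations → a hub-only feature graph, valid score;
* zero-edge graph → empty attribution map; nodes without contributing
  incident edges get contribution 0;
* ties in sentence ranking break by rule table order, then lexicographic
  text; ties in max-magnitude aggregation prefer the larger signed value;
* loaders reject rows (with a reason) rather than repairing them; a missing
  column is a schema error, not a row rejection;
* problem sizes in the test suite (2000-variant benchmarks, 100-seed
  attribution studies, 100-fixture integrity sweeps) were chosen as the
  smallest sizes at which the stochastic criteria are stable across seeds.

## Known limitations

* The hashing backend is linear in edge presence; interactions between
  evidence items are not modeled (the random forest baseline captures some).
* Hash collisions at 4096 dimensions are rare for these token counts but not
  impossible; the dimension is configurable.
* Explanation sentences are templates: coverage is exactly the ten rules,
  and grammatical number is not adjusted inside slots (a one-neighbor tally
  still reads "One neighboring variants ...", faithful to the template).
* No ACMG criteria engine: sentences present evidence, they do not apply the
  guideline's combination rules.
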