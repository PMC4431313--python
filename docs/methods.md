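# Methods

## Scope and data model

The pipeline treats a multi-ingredient drug as a perturbation of a layered
network. All identifiers (molecule, target, pathway, disease, symptom,
tag) are opaque strings — no validation beyond non-emptiness — so the
package is agnostic to whether the data came from UNPD-style molecule ids,
UniProt accessions or KEGG pathway/disease ids. Annotation layers are
set-valued many-to-many maps stored in one GMT-style dialect
(`set id<TAB>description<TAB>members...`); networks are undirected simple
bipartite graphs (parallel edges collapse, so each molecule–target pair
counts once in any degree).

## Hit selection

A pair is a hit iff best score > per-target minimum reference score and
best score > 6.0, both strict (ties excluded). When a target has several
crystal structures, the per-(molecule, target) maximum score is compared
against the per-target minimum reference — the most permissive composition
of the duplicate records; a different convention would only shrink the hit
set. Scores follow the higher-is-better convention; data with inverted
sign must be flipped at ingest. Eligibility then requires a
case-insensitive organism match (default label "human"), a nonempty
pathway set, and at least one pathway with a disease annotation; unknown
pathway ids contribute no disease rather than erroring, since annotation
maps are routinely incomplete.

## Network statistics

Betweenness uses fractional credit over equally short paths and is
normalized by (n−1)(n−2)/2 with n the size of the node's connected
component (components smaller than 3 get 0). Per-component normalization
keeps values in [0, 1] on disconnected layers, which bipartite hit
networks usually are; the computation runs on the bipartite graph itself,
not a projection. The implementation delegates to networkx per component;
the test oracle is an independent breadth-first enumeration of all
shortest paths, compared to 1e-12 on random graphs of ≤ 12 nodes.

Degree strata default to low [1, 10], middle [11, 30], high [31, ∞). The
high stratum is open-ended: the largest observed hub degree in any given
data set is an observation, not a rule, and synthetic data with larger
hubs must remain classifiable. Degree-0 declared nodes belong to no
stratum and are skipped with a logged notice.

The pathway relevance score counts (molecule, target, pathway) incidence
triples rather than distinct pathways per molecule: a pathway touched by
many stratum interactions should outweigh one touched once. Scores over
pathways with ≥ 1 triple form a probability vector, and merging two strata
yields the triple-count-weighted mixture of their score vectors (a tested
invariant).

## Projection and mechanism extraction

The drug–pathway edge weight is the number of shared targets and the sum
of all weights equals the number of (drug, target, pathway) triples
exactly (tested on random layers). Degree tables for the projected layer
use the unweighted projection — "how many pathways does this molecule
reach" — with weights retained as an edge attribute. Mechanism
subnetworks are pure extraction (no statistics): in-pathway targets with
≥ 1 hit, their drugs, and those edges; cross-pathway comparisons report
plain set intersections of target sets.

## Phenotype layers

Category percentages are shares of (disease, category) assignments, not of
diseases, because multi-category diseases are common; the full table is
reported and sums to 100% up to rounding (2 decimals). Symptom counts are
distinct diseases per symptom (within-disease repeats collapse in the set
map). ZHENG counting is inclusive: the Cold and Hot totals each include
dual-labeled diseases, the only convention under which the three reported
strata and the distinct total are mutually consistent.

## Connectivity scoring

The KS-style statistic is the classic connectivity-map construction
(rank 1 = most up-regulated). Design choices:

- Raw score zeroing when KS_up and KS_down share a strict sign; a zero on
  either side does not count as sign agreement.
- Batch scaling divides by the maximum absolute raw score over all scored
  instances, so every nonzero batch has an instance of magnitude 1. A
  degenerate batch whose raw scores are all zero stays zero.
- The permutation null redraws the signature's tags uniformly without
  replacement from the universe (list sizes preserved), rescoring the
  whole batch under each permutation's own scale, with the add-one
  estimate p = (1 + k)/(1 + N) so p is never 0. Permuting signature tags
  rather than profile labels keeps the null meaningful with few instances
  per combination.
- Up-only (or down-only) signatures are supported: the raw score is then
  the single KS statistic (respectively its negation).
- Swapping the up and down lists negates every raw score exactly. By
  contrast, reversing a profile's ranking maps the KS pair (a, b) to
  (b − 1/n, a + 1/n), so it negates the raw score only up to O(1/n) — an
  inherent discretization asymmetry of the (j−1)/t term, asserted in the
  tests with a 2/n tolerance.

## Synthetic data

The generator's defaults are the package's study conditions: 90 molecules
screened against 270 targets, 40 pathways, 130 diseases, 60 symptoms — the
molecule side kept full-size and the downstream panels scaled down roughly
uniformly from a 2715-target / 200-pathway / 668-disease screen so the
end-to-end suite runs in seconds. Other defaults, each chosen once:

- `hit_fraction` 0.006: with the eleven planted hubs (degree sequence
  62, 40, 34, 32, 22, 18, 16, 16, 14, 12, 10 contributing 316 edges) this
  lands the drug–target layer near 440 edges.
- Reference scores ~ Normal(6.0, 0.5); planted hits exceed
  max(reference, 6.0) by ≥ 0.2 and all other scores fall strictly below
  min(reference, 6.0), so the filter recovers exactly the planted pairs
  and hub degrees are exact, not approximate.
- Annotation set sizes are truncated Poisson (1 + Poisson(mean − 1)):
  means 4.6 pathways/target, 3 diseases/pathway, 19 symptoms/disease.
  No distributional information about real annotation multiplicities is
  assumed beyond the means.
- `dominant_pathway_prob` 0.5: each target is additionally annotated to
  the first pathway with this probability, planting a pathway whose
  relevance score dominates every stratum — the recoverable "signal" for
  the relevance-scoring stage.
- ZHENG proportions are inclusive (cold, hot, both) fractions among 117
  labeled diseases, defaulting to 28/117, 94/117, 5/117; the generator
  draws the exclusive strata from the normalized
  (cold − both, hot − both, both) weights.
- The connectivity reference holds 20 perturbagens × 3 cell lines × 2
  instances (120 profiles over 100 tags) — a density comparable to large
  public connectivity references (~5–6 instances per compound). One
  perturbagen is a planted mimic (signature tags shifted by
  `mimic_strength` 3.0 on a standard-normal base score before ranking),
  one a reverser, the rest null.

What the generator does **not** emulate: docking-energy physics and
score–affinity correlation structure, correlated pathway membership
(real pathways overlap systematically, not independently), disease
comorbidity structure, and microarray noise models. Passing tests
therefore demonstrate that the pipeline recovers structure that is
genuinely present in its inputs under realistic magnitudes — not that the
statistics are robust to the specific correlation patterns of any real
database.

## Numerical and degenerate-input choices

- Identical inputs and seed give byte-identical outputs: all writers sort
  rows (attribute tables by decreasing degree then node id, mirroring the
  usual hub-first presentation) and floats are formatted to fixed
  precision.
- Empty hit sets flow through every stage: empty networks, empty tables,
  no crash; the relevance scorer is the one operation that refuses an
  empty stratum (it would have to normalize by zero), and the pipeline
  simply skips unpopulated strata.
- Mean degree of an empty side is NaN, not an error.
- All randomness flows through `numpy.random.default_rng` seeded from the
  spec/config seed; independent generator stages use separate
  deterministic streams so adding draws to one stage does not shift
  another.

## Problem sizes

The default test suite runs the full study conditions (90 × 270 screen,
1000-permutation connectivity tests, 20-seed planted-recovery sweeps,
1000-signature null calibration at 199 permutations each) in well under a
minute on one core; the acceptance script regenerates and remeasures
everything in a few seconds.

## Known limitations

- Printed averages in some published pathway–disease summaries are not
  internally consistent with any single edge count; the package reports
  means computed from its own degree tables and does not attempt to match
  such figures.
- Node accounting follows the data model (nodes = declared endpoints);
  no attempt is made to reproduce external tools' node-count conventions.
- The permutation p-value is exchangeable-valid for the combination being
  tested but is not corrected for multiplicity across combinations;
  apply a multiple-testing correction downstream if many perturbagens are
  screened for significance.
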