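# netpharm

A multiscale network-pharmacology pipeline for multi-ingredient drugs
(herbal formulae in particular): it links docking-derived drug–target
interactions through biological pathways and diseases down to clinical
symptoms and traditional-Chinese-medicine Cold/Hot ZHENG labels, and
compares query expression signatures against a connectivity reference set.

## Who this is for

Researchers studying how a mixture of chemical ingredients perturbs a
protein-interaction landscape: rather than one drug / one target, the unit
of analysis is a layered network — drug–target, target–pathway,
drug–pathway, pathway–disease — plus the phenotype annotations hanging off
the disease layer. The package covers the full chain from a raw
docking-score table to phenotype tables and connectivity scores, and ships
a seeded synthetic-data generator so every stage is testable without
external databases.

## The model

**Hit filter.** A molecule–target pair is a virtual-screening *hit* when
its docking score s (higher = stronger predicted binding) satisfies
s > s_ref and s > 6.0, both strict, where s_ref is the score of the
target structure's original co-crystal ligand. Targets must then be
human, carry ≥ 1 pathway annotation, and have ≥ 1 pathway with a disease
annotation.

**Network statistics.** Each layer is an undirected simple bipartite
graph. Reported per node: degree and normalized shortest-path betweenness
(fractional credit over equally short paths, divided by (n−1)(n−2)/2 per
connected component, so values lie in [0, 1]). Molecules are stratified by
degree into low [1, 10], middle [11, 30] and high [31, ∞).

**Pathway relevance score.** Within one stratum, every
(molecule, target, pathway) incidence triple counts once and a pathway's
score is its triple share: score(p) = N(p) / Σ_q N(q).

**Projection.** Drug–pathway edges exist where a shared target links the
two layers; the edge weight is the number of shared targets, while degree
statistics use the unweighted projection. Mechanism subnetworks extract,
for one disease pathway, the in-pathway targets with ≥ 1 hit, the drugs
hitting them, and those edges.

**Phenotype layers.** Disease-category proportions (one assignment per
(disease, category) pair), symptom frequencies (distinct diseases per
symptom), and the ZHENG partition: each labeled disease carries a nonempty
subset of {Cold, Hot}; reported Cold/Hot totals are inclusive of
dual-labeled diseases, so distinct = |Cold| + |Hot| − |both|.

**Connectivity score.** For a tag list of size t against a ranking of n
tags with sorted tag ranks V(j):

    a = max_j ( j/t − V(j)/n ),   b = max_j ( V(j)/n − (j−1)/t )
    KS = a if a > b else −b

The raw instance score is 0 when the up- and down-list KS statistics share
a sign, else KS_up − KS_down; scores are scaled batch-wide by the maximum
absolute raw score into [−1, 1]; per (perturbagen, cell line) the mean
scaled score gets a permutation p-value by redrawing the signature's tags
from the universe, p = (1 + #{|permuted mean| ≥ |observed mean|}) / (1 + N).

## Worked example

```python
import netpharm as npm

spec = npm.SimulationSpec(seed=1)          # default synthetic study
records = npm.generate_docking_table(spec)
hits = npm.select_hits(records, threshold=6.0)
dt = npm.build_bipartite(hits)
print("hits:", len(hits), "molecules:", len(dt.left), "targets:", len(dt.right))

strata = npm.stratify_by_degree(dt, "left")
top = max(dt.left, key=dt.degree_of)
print("top molecule:", top, "degree:", dt.degree_of(top), "stratum:", strata[top])

bundle = npm.generate_annotations(spec)
part = npm.classify_zheng(bundle.zheng_labels)
print("ZHENG cold=%d hot=%d both=%d total=%d"
      % (part.n_cold, part.n_hot, part.n_both, part.n_total))

sig = npm.make_signature(spec)
profiles = npm.generate_profiles(spec, sig)
for r in npm.mean_scores_with_pvalues(sig, profiles, n_perm=1000, seed=1)[:3]:
    print("%-10s %-5s mean=%+.3f p=%.4f" % (r.perturbagen, r.cell_line,
                                            r.mean_score, r.p_value))
```

prints

```
hits: 399 molecules: 71 targets: 216
top molecule: MOL0000 degree: 62 stratum: high
ZHENG cold=23 hot=98 both=4 total=117
mimic      PC3   mean=+0.980 p=0.0020
mimic      HL60  mean=+0.944 p=0.0010
mimic      MCF7  mean=+0.891 p=0.0060
```

The 399 hits are the planted hub edges (the top molecule's 62 hits are
planted exactly) plus a small random background; the 117 labeled diseases
split near the expected 28/94/5 inclusive Cold/Hot/both counts; and the
planted mimic perturbagen tops the connectivity report in all three cell
lines with small permutation p-values.

The same chain runs from the shell:

```sh
netpharm simulate --out-dir study --seed 1
netpharm -v run-all --config study/config.yaml
```

which writes the hit list, the four network layers (SIF + GraphML + node
attribute tables), stratum-wise pathway relevance scores, phenotype
tables, the ZHENG partition and the connectivity report under
`study/results/`. See `netpharm --help` for the stage-by-stage
subcommands (`filter`, `build`, `project`, `phenotype`, `mechanism`,
`cmap-score`).

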