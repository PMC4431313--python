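"""Seeded generators for every pipeline input, with planted structure.

The generator emulates a virtual-screening campaign of a multi-ingredient
herbal injection against a human target panel: a docking-score table with
a small planted hit fraction and a few hub molecules of prescribed degree,
GMT-style annotation layers (target→pathway, pathway→disease,
disease→symptom, disease→category), Cold/Hot ZHENG labels over a fixed
number of diseases, and a connectivity reference set with one planted
"mimic" and one planted "reverser" perturbagen.

Everything is deterministic under the spec's seed; planted structure
(hub degrees, the dominant pathway, the mimic) is exactly recoverable by
the downstream stages, which is what the end-to-end tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationMap
from .connectivity import RankedProfile, TagSignature
from .hit_filter import DockingRecord, TargetMeta
from .phenotype import ZhengLabelSet

__all__ = [
    "SimulationSpec",
    "AnnotationBundle",
    "generate_docking_table",
    "generate_annotations",
    "generate_profiles",
    "make_signature",
    "write_fixture",
]

# Table-like hub degrees for the molecule side: eleven ingredients spanning
# the high/middle/low strata exactly as the reported degree sequence does.
DEFAULT_HUB_SPEC: tuple[tuple[int, int], ...] = (
    (0, 62), (1, 40), (2, 34), (3, 32), (4, 22), (5, 18),
    (6, 16), (7, 16), (8, 14), (9, 12), (10, 10),
)

DISEASE_CATEGORIES: tuple[str, ...] = (
    "Inherited metabolic disease", "Cancer", "Nervous system disease",
    "Developmental disorder", "Hematologic disease", "Skeletal dysplasia",
    "Infectious disease", "Skin and connective tissue disease",
    "Primary immunodeficiency", "Immune system disease",
    "Neurodegenerative disease", "Endocrine disease", "Kidney disease",
)

CELL_LINES: tuple[str, ...] = ("MCF7", "HL60", "PC3")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic cohort.

    Network magnitudes mirror a 90-ingredient screen against 270 targets
    mapped onto 40 pathways and 130 diseases (a uniform scale-down of a
    2715-target / 200-pathway / 668-disease panel that keeps the molecule
    side full-size).  ``hit_fraction`` 0.006 plus the eleven planted hub
    molecules (``hub_spec``, the reported degree sequence) lands the
    drug-target layer near 440 edges.  ZHENG proportions are inclusive (cold,
    hot, both) fractions among the labeled diseases, defaulting to
    28/117, 94/117, 5/117.
    """

    n_molecules: int = 90
    n_targets: int = 270
    n_pathways: int = 40
    n_diseases: int = 130
    n_symptoms: int = 60
    hit_fraction: float = 0.006
    hub_spec: tuple[tuple[int, int], ...] = DEFAULT_HUB_SPEC
    mean_pathways_per_target: float = 4.6
    mean_diseases_per_pathway: float = 3.0
    mean_symptoms_per_disease: float = 19.0
    dominant_pathway_prob: float = 0.5
    n_zheng: int = 117
    zheng_cold: float = 28 / 117
    zheng_hot: float = 94 / 117
    zheng_both: float = 5 / 117
    frac_nonhuman: float = 0.0
    frac_unannotated: float = 0.0
    n_perturbagens: int = 20
    n_instances: int = 2
    n_tags: int = 100
    mimic_strength: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_molecules", "n_targets", "n_pathways", "n_diseases",
                     "n_symptoms", "n_perturbagens", "n_instances", "n_tags"):
            if getattr(self, name) < 1:
                raise ValueError("%s must be >= 1" % name)
        if not (0.0 <= self.hit_fraction < 1.0):
            raise ValueError("hit_fraction must lie in [0, 1)")
        for i, k in self.hub_spec:
            if not (0 <= i < self.n_molecules):
                raise ValueError("hub molecule index %d out of range" % i)
            if not (1 <= k <= self.n_targets):
                raise ValueError("intended hub degree %d exceeds n_targets" % k)
        if len({i for i, _ in self.hub_spec}) != len(self.hub_spec):
            raise ValueError("repeated molecule index in hub_spec")
        for name in ("mean_pathways_per_target", "mean_diseases_per_pathway",
                     "mean_symptoms_per_disease"):
            if getattr(self, name) < 1.0:
                raise ValueError("%s must be >= 1" % name)
        for name in ("zheng_cold", "zheng_hot", "zheng_both",
                     "dominant_pathway_prob", "frac_nonhuman",
                     "frac_unannotated"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError("%s must lie in [0, 1]" % name)
        if self.zheng_both > min(self.zheng_cold, self.zheng_hot):
            raise ValueError("zheng_both exceeds an inclusive stratum fraction")
        if self.zheng_cold + self.zheng_hot - self.zheng_both <= 0:
            raise ValueError("ZHENG proportions leave no labeled disease")
        if self.n_zheng > self.n_diseases:
            raise ValueError("n_zheng exceeds n_diseases")
        if self.n_perturbagens < 2:
            raise ValueError("need at least mimic + reverser perturbagens")

    # identifier helpers -------------------------------------------------
    def molecule_ids(self) -> list[str]:
        return ["MOL%04d" % i for i in range(self.n_molecules)]

    def target_ids(self) -> list[str]:
        return ["TGT%04d" % i for i in range(self.n_targets)]

    def pathway_ids(self) -> list[str]:
        return ["PWY%04d" % i for i in range(self.n_pathways)]

    def disease_ids(self) -> list[str]:
        return ["DIS%04d" % i for i in range(self.n_diseases)]

    def symptom_ids(self) -> list[str]:
        return ["SYM%04d" % i for i in range(self.n_symptoms)]

    def tag_ids(self) -> list[str]:
        return ["TAG%04d" % i for i in range(self.n_tags)]


@dataclass(frozen=True)
class AnnotationBundle:
    """All annotation layers produced by `generate_annotations`."""

    target_pathway: AnnotationMap
    pathway_disease: AnnotationMap
    disease_symptom: AnnotationMap
    disease_category: AnnotationMap
    zheng_labels: tuple[ZhengLabelSet, ...]
    targets: tuple[TargetMeta, ...] = field(default_factory=tuple)


def _rng(spec: SimulationSpec, stream: int) -> np.random.Generator:
    # separate deterministic streams so each generator is independent
    return np.random.default_rng([stream, spec.seed & 0x7FFFFFFF])


def generate_docking_table(spec: SimulationSpec) -> list[DockingRecord]:
    """Full docking-score table for every (molecule, target) pair.

    Reference-ligand scores are drawn around the 6.0 cutoff.  A planted
    hit's score strictly clears both the reference and the cutoff by a
    margin; every other score falls strictly below both, so the hit filter
    recovers exactly the planted pairs and hub molecules achieve their
    intended post-filter degree exactly.
    """
    rng = _rng(spec, 1)
    n_mol, n_tgt = spec.n_molecules, spec.n_targets
    thr = 6.0
    refs = thr + 0.5 * rng.standard_normal(n_tgt)

    hit = rng.random((n_mol, n_tgt)) < spec.hit_fraction
    for i, k in spec.hub_spec:
        hit[i, :] = False
        hit[i, rng.choice(n_tgt, size=k, replace=False)] = True

    margin = 0.2 + rng.exponential(0.4, size=(n_mol, n_tgt))
    slack = 0.1 + np.abs(rng.standard_normal((n_mol, n_tgt))) * 0.8
    upper = np.maximum(refs, thr)[None, :] + margin
    lower = np.minimum(refs, thr)[None, :] - slack
    scores = np.where(hit, upper, lower)

    mols = spec.molecule_ids()
    tgts = spec.target_ids()
    return [
        DockingRecord(mols[i], tgts[j], float(scores[i, j]), float(refs[j]))
        for i in range(n_mol)
        for j in range(n_tgt)
    ]


def _truncated_poisson_sizes(
    rng: np.random.Generator, mean: float, n: int
) -> np.ndarray:
    # sizes >= 1 with mean `mean`: 1 + Poisson(mean - 1)
    return 1 + rng.poisson(mean - 1.0, size=n)


def generate_annotations(spec: SimulationSpec) -> AnnotationBundle:
    """Annotation layers with satisfiable eligibility criteria.

    Every target gets >= 1 pathway and every pathway >= 1 disease (set
    sizes truncated-Poisson around the spec means), unless the spec asks
    for a nonhuman or unannotated fraction to exercise the filter.  The
    first pathway is additionally assigned to each target with probability
    ``dominant_pathway_prob``, planting a dominant pathway whose relevance
    score should top every stratum.  ZHENG labels are drawn over
    ``n_zheng`` diseases with the given inclusive proportions.
    """
    rng = _rng(spec, 2)
    tgts, pwys = spec.target_ids(), spec.pathway_ids()
    diss, syms = spec.disease_ids(), spec.symptom_ids()

    # target -> pathways, with a planted dominant pathway
    tp: dict[str, set[str]] = {}
    sizes = _truncated_poisson_sizes(rng, spec.mean_pathways_per_target, spec.n_targets)
    dominant_draw = rng.random(spec.n_targets)
    for i, t in enumerate(tgts):
        k = min(int(sizes[i]), spec.n_pathways)
        chosen = {pwys[j] for j in rng.choice(spec.n_pathways, size=k, replace=False)}
        if dominant_draw[i] < spec.dominant_pathway_prob:
            chosen.add(pwys[0])
        tp[t] = chosen

    # pathway -> diseases (every pathway annotated)
    pd_: dict[str, set[str]] = {}
    sizes = _truncated_poisson_sizes(rng, spec.mean_diseases_per_pathway, spec.n_pathways)
    for i, p in enumerate(pwys):
        k = min(int(sizes[i]), spec.n_diseases)
        pd_[p] = {diss[j] for j in rng.choice(spec.n_diseases, size=k, replace=False)}

    # disease -> symptoms
    ds: dict[str, set[str]] = {}
    sizes = _truncated_poisson_sizes(rng, spec.mean_symptoms_per_disease, spec.n_diseases)
    for i, d in enumerate(diss):
        k = min(int(sizes[i]), spec.n_symptoms)
        ds[d] = {syms[j] for j in rng.choice(spec.n_symptoms, size=k, replace=False)}

    # disease -> categories (1 or 2 per disease)
    dc: dict[str, set[str]] = {}
    two = rng.random(spec.n_diseases) < 0.15
    for i, d in enumerate(diss):
        k = 2 if two[i] else 1
        dc[d] = {
            DISEASE_CATEGORIES[j]
            for j in rng.choice(len(DISEASE_CATEGORIES), size=k, replace=False)
        }

    # ZHENG labels: inclusive (cold, hot, both) -> exclusive draw weights
    labeled = [diss[j] for j in rng.choice(spec.n_diseases, size=spec.n_zheng, replace=False)]
    w = np.array([
        spec.zheng_cold - spec.zheng_both,
        spec.zheng_hot - spec.zheng_both,
        spec.zheng_both,
    ])
    w = w / w.sum()
    strata = rng.choice(3, size=spec.n_zheng, p=w)
    label_sets = {
        0: frozenset({"Cold"}),
        1: frozenset({"Hot"}),
        2: frozenset({"Cold", "Hot"}),
    }
    zheng = tuple(
        ZhengLabelSet(d, label_sets[int(s)]) for d, s in zip(labeled, strata)
    )

    # target metadata (organism + pathway memberships)
    nonhuman = rng.random(spec.n_targets) < spec.frac_nonhuman
    unannotated = rng.random(spec.n_targets) < spec.frac_unannotated
    metas = []
    for i, t in enumerate(tgts):
        if unannotated[i]:
            tp.pop(t, None)
        metas.append(
            TargetMeta(
                target_id=t,
                organism="mouse" if nonhuman[i] else "human",
                pathway_ids=frozenset() if unannotated[i] else frozenset(tp[t]),
            )
        )

    return AnnotationBundle(
        target_pathway=AnnotationMap("target_pathway", tp),
        pathway_disease=AnnotationMap("pathway_disease", pd_),
        disease_symptom=AnnotationMap("disease_symptom", ds),
        disease_category=AnnotationMap("disease_category", dc),
        zheng_labels=zheng,
        targets=tuple(metas),
    )


def make_signature(spec: SimulationSpec, n_up: int = 10, n_down: int = 10) -> TagSignature:
    """Deterministic query signature over the spec's tag universe: the
    first *n_up* tags up, the last *n_down* tags down."""
    tags = spec.tag_ids()
    if n_up + n_down > spec.n_tags:
        raise ValueError("signature larger than tag universe")
    return TagSignature(
        up=tuple(tags[:n_up]),
        down=tuple(tags[spec.n_tags - n_down:]) if n_down else (),
    )


def generate_profiles(
    spec: SimulationSpec, sig: TagSignature
) -> list[RankedProfile]:
    """Reference profiles with one planted mimic and one planted reverser.

    Each instance ranks every tag by a standard-normal base score; the
    mimic perturbagen's instances add ``mimic_strength`` to the signature's
    up tags and subtract it from the down tags (the reverser does the
    opposite), so the mimic's rankings place up tags early and down tags
    late.  All remaining perturbagens rank uniformly at random.  Every
    perturbagen is profiled ``n_instances`` times in each cell line of the
    panel, so each (perturbagen, cell line) combination averages several
    instances, as a connectivity reference set does.
    """
    rng = _rng(spec, 3)
    tags = spec.tag_ids()
    universe = set(tags)
    for tag in sig.tags:
        if tag not in universe:
            raise KeyError("signature tag %r absent from tag universe" % tag)
    if spec.n_tags < len(sig.tags):
        raise ValueError("tag universe smaller than the signature")

    idx = {t: i for i, t in enumerate(tags)}
    up_idx = [idx[t] for t in sig.up]
    down_idx = [idx[t] for t in sig.down]

    perturbagens = ["mimic", "reverser"] + [
        "null%02d" % i for i in range(spec.n_perturbagens - 2)
    ]
    profiles = []
    for pert in perturbagens:
        for cell in CELL_LINES:
            for j in range(spec.n_instances):
                base = rng.standard_normal(spec.n_tags)
                if pert == "mimic":
                    base[up_idx] += spec.mimic_strength
                    base[down_idx] -= spec.mimic_strength
                elif pert == "reverser":
                    base[up_idx] -= spec.mimic_strength
                    base[down_idx] += spec.mimic_strength
                order = tuple(tags[i] for i in np.argsort(-base, kind="stable"))
                profiles.append(
                    RankedProfile(
                        instance_id="%s_%s_%02d" % (pert, cell, j),
                        perturbagen=pert,
                        cell_line=cell,
                        order=order,
                    )
                )
    return profiles


def write_fixture(spec: SimulationSpec, out_dir) -> "PipelineConfig":
    """Materialize a complete input directory for one simulated study.

    Writes the docking table, target metadata, the four GMT annotation
    maps, ZHENG labels, the query signature, the reference profiles and a
    ready-to-run YAML config; returns the corresponding PipelineConfig.
    """
    from pathlib import Path

    from . import io as npio
    from .pipeline import PipelineConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_docking_table(spec)
    bundle = generate_annotations(spec)
    sig = make_signature(spec)
    profiles = generate_profiles(spec, sig)

    npio.write_docking_table(records, out / "docking.tsv")
    npio.write_targets_table(bundle.targets, out / "targets.tsv")
    npio.write_gmt(bundle.target_pathway, out / "target_pathway.gmt")
    npio.write_gmt(bundle.pathway_disease, out / "pathway_disease.gmt")
    npio.write_gmt(bundle.disease_symptom, out / "disease_symptom.gmt")
    npio.write_gmt(bundle.disease_category, out / "disease_category.gmt")
    npio.write_zheng_labels(bundle.zheng_labels, out / "zheng.gmt")
    npio.write_signature(sig, out / "signature.tsv")
    npio.write_profiles(profiles, out / "profiles.tsv")

    config = PipelineConfig(
        docking_path=str(out / "docking.tsv"),
        targets_path=str(out / "targets.tsv"),
        target_pathway_path=str(out / "target_pathway.gmt"),
        pathway_disease_path=str(out / "pathway_disease.gmt"),
        disease_symptom_path=str(out / "disease_symptom.gmt"),
        disease_category_path=str(out / "disease_category.gmt"),
        zheng_path=str(out / "zheng.gmt"),
        signature_path=str(out / "signature.tsv"),
        profiles_path=str(out / "profiles.tsv"),
        out_dir=str(out / "results"),
        seed=spec.seed,
    )
    config.to_yaml(out / "config.yaml")
    return config
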