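"""Pipeline configuration and end-to-end orchestration.

Stages run in the method's order: hit filtering, drug-target network with
node attributes, degree stratification and pathway relevance scores,
target-pathway network, drug-pathway projection, pathway-disease network,
phenotype tables (categories, symptoms, ZHENG partition), and an optional
connectivity report when a signature and reference profiles are
configured.  Every stage logs its row/edge counts; any stage failure
aborts with the stage name and cause.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as npio
from .hit_filter import eligible_targets, restrict_hits, select_hits
from .network import (
    DegreeStrata,
    build_bipartite,
    pathway_relevance_score,
    stratify_by_degree,
)
from .phenotype import category_proportions, classify_zheng, symptom_counts
from .projection import build_pathway_disease, project_drug_pathway

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs and file paths for one pipeline run."""

    docking_path: str
    targets_path: str
    target_pathway_path: str
    pathway_disease_path: str
    disease_symptom_path: str
    disease_category_path: str
    zheng_path: str
    out_dir: str
    signature_path: str | None = None
    profiles_path: str | None = None
    score_threshold: float = 6.0
    strata_bounds: tuple[int, int] = (10, 30)
    organism: str = "human"
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not math.isfinite(self.score_threshold):
            raise ValueError("score_threshold must be finite")
        c1, c2 = self.strata_bounds
        if not (1 <= c1 < c2):
            raise ValueError("strata bounds must be strictly increasing and >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata_bounds" in raw:
            raw["strata_bounds"] = tuple(raw["strata_bounds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("stage %r failed: %s" % (name, exc)) from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage in order and return the artifact paths by name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _art(name: str, filename: str) -> Path:
        artifacts[name] = out / filename
        return artifacts[name]

    # -- stage: read inputs ------------------------------------------------
    @_stage("read_inputs")
    def _read():
        records = npio.read_docking_table(config.docking_path)
        tp_map = npio.read_gmt(config.target_pathway_path, "target_pathway")
        pd_map = npio.read_gmt(config.pathway_disease_path, "pathway_disease")
        ds_map = npio.read_gmt(config.disease_symptom_path, "disease_symptom")
        dc_map = npio.read_gmt(config.disease_category_path, "disease_category")
        zheng = npio.read_zheng_labels(config.zheng_path)
        targets = npio.read_targets_table(config.targets_path, tp_map)
        npio.stage_log(
            "read_inputs",
            docking_rows=len(records),
            targets=len(targets),
            pathways=len(tp_map.all_values),
        )
        return records, tp_map, pd_map, ds_map, dc_map, zheng, targets

    records, tp_map, pd_map, ds_map, dc_map, zheng, targets = _read()

    # -- stage: hit filter ---------------------------------------------------
    @_stage("hit_filter")
    def _filter():
        hits = select_hits(records, config.score_threshold)
        kept = eligible_targets(targets, pd_map, organism=config.organism)
        hits2 = restrict_hits(hits, kept)
        best: dict[tuple[str, str], float] = {}
        ref: dict[str, float] = {}
        for r in records:
            key = (r.molecule_id, r.target_id)
            best[key] = max(best.get(key, -math.inf), r.score)
            ref[r.target_id] = min(ref.get(r.target_id, math.inf), r.reference_score)
        path = _art("hits", "hits.tsv")
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("molecule_id\ttarget_id\tscore\treference_score\n")
            for m, t in sorted(hits2):
                fh.write("%s\t%s\t%r\t%r\n" % (m, t, best[(m, t)], ref[t]))
        npio.stage_log(
            "hit_filter",
            raw_hits=len(hits),
            eligible_targets=len(kept),
            hits=len(hits2),
        )
        return hits2

    hits = _filter()

    # -- stage: drug-target network -----------------------------------------
    @_stage("drug_target_network")
    def _dt():
        net = build_bipartite(hits)
        npio.write_network(net, _art("dt_network", "drug_target.sif"), "sif", "binds")
        npio.write_network(net, _art("dt_graphml", "drug_target.graphml"), "graphml")
        npio.write_node_attributes(net, _art("dt_attributes", "drug_target_attributes.tsv"))
        npio.stage_log("drug_target_network", nodes=net.n_nodes, edges=net.n_edges)
        return net

    dt = _dt()

    # -- stage: strata + relevance scores -----------------------------------
    @_stage("relevance_scores")
    def _relevance():
        strata = DegreeStrata(*config.strata_bounds)
        assignment = stratify_by_degree(dt, "left", strata)
        path = _art("relevance_scores", "relevance_scores.tsv")
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("stratum\tpathway\tscore\n")
            for stratum in ("high", "middle", "low"):
                stratum_hits = {
                    (m, t) for m, t in hits if assignment.get(m) == stratum
                }
                if not stratum_hits:
                    continue
                scores = pathway_relevance_score(stratum_hits, tp_map)
                for pw, s in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])):
                    fh.write("%s\t%s\t%.6f\n" % (stratum, pw, s))
        npio.stage_log("relevance_scores", molecules=len(assignment))
        return assignment

    _relevance()

    # -- stage: target-pathway network --------------------------------------
    @_stage("target_pathway_network")
    def _tp():
        hit_targets = {t for _, t in hits}
        pairs = [
            (t, pw) for t in sorted(hit_targets) for pw in sorted(tp_map.get(t))
        ]
        net = build_bipartite(pairs)
        npio.write_network(net, _art("tp_network", "target_pathway.sif"), "sif", "member")
        npio.write_node_attributes(net, _art("tp_attributes", "target_pathway_attributes.tsv"))
        npio.stage_log("target_pathway_network", nodes=net.n_nodes, edges=net.n_edges)
        return net

    tp = _tp()

    # -- stage: drug-pathway projection --------------------------------------
    @_stage("drug_pathway_network")
    def _dp():
        net = project_drug_pathway(dt, tp)
        npio.write_network(net, _art("dp_network", "drug_pathway.sif"), "sif", "affects")
        npio.write_network(net, _art("dp_graphml", "drug_pathway.graphml"), "graphml")
        npio.write_node_attributes(net, _art("dp_attributes", "drug_pathway_attributes.tsv"))
        npio.stage_log("drug_pathway_network", nodes=net.n_nodes, edges=net.n_edges)
        return net

    dp = _dp()

    # -- stage: pathway-disease network --------------------------------------
    @_stage("pathway_disease_network")
    def _pd():
        net = build_pathway_disease(dp.right, pd_map)
        npio.write_network(net, _art("pd_network", "pathway_disease.sif"), "sif", "causes")
        npio.stage_log("pathway_disease_network", nodes=net.n_nodes, edges=net.n_edges)
        return net

    pd_net = _pd()

    # -- stage: phenotype ------------------------------------------------------
    @_stage("phenotype")
    def _phenotype():
        diseases = set(pd_net.right)
        cats = category_proportions(dc_map, diseases)
        cats.to_csv(
            _art("disease_categories", "disease_categories.tsv"),
            sep="\t", index=False, float_format="%.2f", lineterminator="\n",
        )
        syms = symptom_counts(ds_map, diseases)
        syms.to_csv(
            _art("symptom_counts", "symptom_counts.tsv"),
            sep="\t", index=False, lineterminator="\n",
        )
        part = classify_zheng([z for z in zheng if z.disease_id in diseases])
        npio.write_zheng_partition(
            part,
            _art("zheng_partition", "zheng_partition.tsv"),
            _art("zheng_summary", "zheng_summary.tsv"),
        )
        npio.stage_log(
            "phenotype",
            diseases=len(diseases),
            zheng_cold=part.n_cold,
            zheng_hot=part.n_hot,
            zheng_both=part.n_both,
        )

    _phenotype()

    # -- stage: connectivity (optional) ---------------------------------------
    if config.signature_path and config.profiles_path:

        @_stage("connectivity")
        def _connectivity():
            from .connectivity import mean_scores_with_pvalues

            sig = npio.read_signature(config.signature_path)
            profiles = npio.read_profiles(config.profiles_path)
            results = mean_scores_with_pvalues(
                sig, profiles, n_perm=config.n_permutations, seed=config.seed
            )
            path = _art("connectivity", "connectivity.tsv")
            with path.open("w", encoding="utf-8", newline="\n") as fh:
                fh.write("perturbagen\tcell_line\tmean_score\tp_value\tn_instances\n")
                for r in results:
                    fh.write(
                        "%s\t%s\t%.6f\t%.6g\t%d\n"
                        % (r.perturbagen, r.cell_line, r.mean_score, r.p_value, r.n_instances)
                    )
            npio.stage_log("connectivity", combinations=len(results))

        _connectivity()

    return artifacts
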