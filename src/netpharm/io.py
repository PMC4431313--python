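"""Readers and writers for every on-disk format the pipeline touches.

Tables are tab-separated UTF-8 with a header row.  Annotation maps use a
GMT-style line format (set id, description, members...).  Networks go out
as SIF ("nodeA<TAB>relation<TAB>nodeB", one line per edge) or GraphML with
side and weight attributes.  All writers emit deterministically ordered
output so identical inputs give byte-identical files.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .annotations import AnnotationMap
from .connectivity import RankedProfile, TagSignature
from .hit_filter import DockingRecord, TargetMeta
from .network import BipartiteNetwork, betweenness, degree
from .phenotype import ZhengLabelSet, ZhengPartition

__all__ = [
    "FormatError",
    "read_docking_table",
    "write_docking_table",
    "read_gmt",
    "write_gmt",
    "read_targets_table",
    "write_targets_table",
    "read_zheng_labels",
    "write_zheng_labels",
    "write_network",
    "read_network",
    "read_sif",
    "write_node_attributes",
    "read_signature",
    "write_signature",
    "read_profiles",
    "write_profiles",
    "write_zheng_partition",
    "stage_log",
]

logger = logging.getLogger("netpharm")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def stage_log(stage: str, **kv) -> None:
    """One pipeline log line: ``stage<TAB>key=value ...``."""
    logger.info("%s\t%s", stage, " ".join("%s=%s" % (k, v) for k, v in kv.items()))


# ---------------------------------------------------------------------------
# docking table
# ---------------------------------------------------------------------------

_DOCKING_COLS = ("molecule_id", "target_id", "score", "reference_score")


def read_docking_table(path: str | Path) -> list[DockingRecord]:
    """Parse a docking-score TSV into records.

    Requires the header columns molecule_id, target_id, score and
    reference_score; duplicate (molecule, target) rows are preserved for
    the filter stage to resolve.  A missing column raises a FormatError
    naming it; a non-numeric score raises one carrying the line number.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _DOCKING_COLS:
            if col not in header:
                raise FormatError("%s: missing column %r" % (path, col))
        records = []
        for lineno, row in enumerate(reader, start=2):
            try:
                score = float(row["score"])
                ref = float(row["reference_score"])
            except (TypeError, ValueError):
                raise FormatError(
                    "%s: non-numeric score on line %d" % (path, lineno)
                ) from None
            try:
                records.append(
                    DockingRecord(row["molecule_id"], row["target_id"], score, ref)
                )
            except ValueError as exc:
                raise FormatError("%s: line %d: %s" % (path, lineno, exc)) from None
    return records


def write_docking_table(records: Iterable[DockingRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_DOCKING_COLS) + "\n")
        for r in records:
            fh.write(
                "%s\t%s\t%r\t%r\n"
                % (r.molecule_id, r.target_id, r.score, r.reference_score)
            )


# ---------------------------------------------------------------------------
# GMT-style set maps
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, name: str | None = None) -> AnnotationMap:
    """GMT-style map: each line is ``set_id<TAB>description<TAB>member...``.

    Lines with no members are rejected: a stored key must be annotated.
    """
    path = Path(path)
    forward: dict[str, set[str]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    "%s: line %d has no members (need id, description, members...)"
                    % (path, lineno)
                )
            forward.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
    return AnnotationMap(name or path.stem, forward)


def write_gmt(amap: AnnotationMap, path: str | Path, description: str = "na") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(amap.keys()):
            fh.write("\t".join([key, description, *sorted(amap[key])]) + "\n")


# ---------------------------------------------------------------------------
# target metadata
# ---------------------------------------------------------------------------

def read_targets_table(
    path: str | Path, target_pathway: AnnotationMap | None = None
) -> list[TargetMeta]:
    """Target TSV (target_id, organism); pathway memberships are joined in
    from the target→pathway map when one is given."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in ("target_id", "organism"):
            if col not in (reader.fieldnames or []):
                raise FormatError("%s: missing column %r" % (path, col))
        metas = []
        for row in reader:
            pw = target_pathway.get(row["target_id"]) if target_pathway else frozenset()
            metas.append(TargetMeta(row["target_id"], row["organism"], pw))
    return metas


def write_targets_table(targets: Iterable[TargetMeta], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("target_id\torganism\n")
        for t in sorted(targets, key=lambda t: t.target_id):
            fh.write("%s\t%s\n" % (t.target_id, t.organism))


# ---------------------------------------------------------------------------
# ZHENG labels (GMT dialect with the two label sets)
# ---------------------------------------------------------------------------

def read_zheng_labels(path: str | Path) -> list[ZhengLabelSet]:
    amap = read_gmt(path, name="zheng")
    by_disease: dict[str, set[str]] = {}
    for label in amap.keys():
        if label not in ("Cold", "Hot"):
            raise FormatError("%s: unknown ZHENG set %r" % (path, label))
        for d in amap[label]:
            by_disease.setdefault(d, set()).add(label)
    return [
        ZhengLabelSet(d, frozenset(ls)) for d, ls in sorted(by_disease.items())
    ]


def write_zheng_labels(labels: Iterable[ZhengLabelSet], path: str | Path) -> None:
    cold = sorted({l.disease_id for l in labels if "Cold" in l.labels})
    hot = sorted({l.disease_id for l in labels if "Hot" in l.labels})
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if cold:
            fh.write("\t".join(["Cold", "zheng", *cold]) + "\n")
        if hot:
            fh.write("\t".join(["Hot", "zheng", *hot]) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(
    net: BipartiteNetwork,
    path: str | Path,
    format: str = "sif",
    relation: str = "interacts",
) -> None:
    """Export a network as SIF or GraphML.

    SIF: one ``a<TAB>relation<TAB>b`` line per edge plus a bare line per
    declared isolate.  GraphML: side attribute per node, weight per edge.
    """
    fmt = format.strip().lower()
    path = Path(path)
    if fmt == "sif":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for a, b in sorted(net.edges):
                fh.write("%s\t%s\t%s\n" % (a, relation, b))
            for n in net.nodes:
                if net.degree_of(n) == 0:
                    fh.write("%s\n" % n)
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError("unknown network format %r (expected sif or graphml)" % format)


def read_network(path: str | Path, format: str = "graphml") -> BipartiteNetwork:
    """Read a GraphML export back into the bipartite data model."""
    fmt = format.strip().lower()
    if fmt != "graphml":
        raise ValueError("only graphml round-trips the full data model")
    g = nx.read_graphml(Path(path))
    left = [n for n, d in g.nodes(data=True) if d.get("side") == "left"]
    right = [n for n, d in g.nodes(data=True) if d.get("side") == "right"]
    if len(left) + len(right) != g.number_of_nodes():
        raise FormatError("%s: node(s) missing the side attribute" % path)
    lset = set(left)
    edges = []
    weights = {}
    for a, b, d in g.edges(data=True):
        a, b = (a, b) if a in lset else (b, a)
        edges.append((a, b))
        weights[(a, b)] = int(d.get("weight", 1))
    return BipartiteNetwork(sorted(left), sorted(right), edges, weights)


def read_sif(path: str | Path) -> list[tuple[str, str, str]]:
    """SIF edge lines as (nodeA, relation, nodeB); isolates are skipped."""
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 3:
                out.append((parts[0], parts[1], parts[2]))
            elif len(parts) != 1:
                raise FormatError("%s: malformed SIF line %r" % (path, line))
    return out


def write_node_attributes(net: BipartiteNetwork, path: str | Path) -> pd.DataFrame:
    """Node attribute table (node, side, degree, betweenness), ordered by
    decreasing degree then node id; also written to *path*."""
    deg = degree(net)
    btw = betweenness(net, normalized=True)
    df = pd.DataFrame(
        {
            "node": list(net.nodes),
            "side": [net.side_of(n) for n in net.nodes],
            "degree": [deg[n] for n in net.nodes],
            "betweenness": [btw[n] for n in net.nodes],
        }
    )
    if len(df):
        df = df.sort_values(
            ["degree", "node"], ascending=[False, True], ignore_index=True
        )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")
    return df


# ---------------------------------------------------------------------------
# connectivity inputs
# ---------------------------------------------------------------------------

def read_signature(path: str | Path) -> TagSignature:
    """Two-column TSV (tag, direction in {up, down})."""
    path = Path(path)
    up, down = [], []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in ("tag", "direction"):
            if col not in (reader.fieldnames or []):
                raise FormatError("%s: missing column %r" % (path, col))
        for lineno, row in enumerate(reader, start=2):
            d = row["direction"].strip().lower()
            if d == "up":
                up.append(row["tag"])
            elif d == "down":
                down.append(row["tag"])
            else:
                raise FormatError(
                    "%s: line %d: direction must be up or down" % (path, lineno)
                )
    return TagSignature(up=tuple(up), down=tuple(down))


def write_signature(sig: TagSignature, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("tag\tdirection\n")
        for t in sig.up:
            fh.write("%s\tup\n" % t)
        for t in sig.down:
            fh.write("%s\tdown\n" % t)


def read_profiles(path: str | Path) -> list[RankedProfile]:
    """Long-format profile TSV: instance_id, perturbagen, cell_line, tag, rank."""
    path = Path(path)
    meta: dict[str, tuple[str, str]] = {}
    ranks: dict[str, dict[int, str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = ("instance_id", "perturbagen", "cell_line", "tag", "rank")
        for col in need:
            if col not in (reader.fieldnames or []):
                raise FormatError("%s: missing column %r" % (path, col))
        for lineno, row in enumerate(reader, start=2):
            try:
                rank = int(row["rank"])
            except ValueError:
                raise FormatError(
                    "%s: non-integer rank on line %d" % (path, lineno)
                ) from None
            iid = row["instance_id"]
            meta[iid] = (row["perturbagen"], row["cell_line"])
            bucket = ranks.setdefault(iid, {})
            if rank in bucket:
                raise FormatError(
                    "%s: duplicate rank %d in instance %s" % (path, rank, iid)
                )
            bucket[rank] = row["tag"]
    profiles = []
    for iid in sorted(meta):
        n = len(ranks[iid])
        if sorted(ranks[iid]) != list(range(1, n + 1)):
            raise FormatError(
                "%s: instance %s ranks are not a permutation of 1..%d" % (path, iid, n)
            )
        pert, cell = meta[iid]
        order = tuple(ranks[iid][r] for r in range(1, n + 1))
        profiles.append(RankedProfile(iid, pert, cell, order))
    return profiles


def write_profiles(profiles: Iterable[RankedProfile], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("instance_id\tperturbagen\tcell_line\ttag\trank\n")
        for p in profiles:
            for r, tag in enumerate(p.order, start=1):
                fh.write(
                    "%s\t%s\t%s\t%s\t%d\n"
                    % (p.instance_id, p.perturbagen, p.cell_line, tag, r)
                )


def write_zheng_partition(
    part: ZhengPartition, path: str | Path, summary_path: str | Path | None = None
) -> None:
    """Partition TSV (disease, stratum) plus a 4-line summary table."""
    rows = (
        [(d, "cold_only") for d in sorted(part.cold_only)]
        + [(d, "hot_only") for d in sorted(part.hot_only)]
        + [(d, "both") for d in sorted(part.both)]
    )
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("disease\tstratum\n")
        for d, s in sorted(rows):
            fh.write("%s\t%s\n" % (d, s))
    if summary_path is not None:
        with Path(summary_path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("cold\t%d\n" % part.n_cold)
            fh.write("hot\t%d\n" % part.n_hot)
            fh.write("both\t%d\n" % part.n_both)
            fh.write("total\t%d\n" % part.n_total)
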