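"""Physical clustering of NBS-LRR genes.

A cluster is a maximal chain of two or more focal (NBS-LRR) genes in which
every consecutive pair, taken in positional order along the chromosome, is
(i) closer than ``max_gap_bp`` and (ii) separated by at most
``max_intervening`` non-focal genes.  The rule chains transitively, so a
cluster's total span may exceed the pairwise distance cap.  Strand is
ignored throughout.

Distances default to nearest-edge (start of the downstream gene minus end of
the upstream gene, floored at zero for overlapping models); midpoint and
start-to-start anchors are available since the rule's source leaves the
anchor unstated.  Intervening genes are counted by rank in the per-sequence
(start, end, gene_id) total order, which is unambiguous even for overlapping
or nested annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import GeneModel, GenomeAnnotation

DISTANCE_ANCHORS = ("edge", "midpoint", "start")


@dataclass(frozen=True)
class ClusterRule:
    """Two-condition chaining rule: distance cap and intervening-gene cap.

    The distance condition is strict (< max_gap_bp); the intervening
    condition is inclusive (<= max_intervening).
    """

    max_gap_bp: int = 200_000
    max_intervening: int = 8
    min_members: int = 2
    distance_anchor: str = "edge"

    def __post_init__(self) -> None:
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be > 0")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")
        if self.min_members < 2:
            raise ValueError("min_members must be >= 2")
        if self.distance_anchor not in DISTANCE_ANCHORS:
            raise ValueError(f"distance_anchor must be one of {DISTANCE_ANCHORS}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ClusterRule":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown cluster rule keys {sorted(unknown)}")
        return cls(**data)


@dataclass(slots=True)
class GeneCluster:
    cluster_id: str
    seq_id: str
    members: list[str]  # gene ids in positional order
    span_start: int
    span_end: int
    homogeneous_by_family: bool | None = None
    homogeneous_by_clade: bool | None = None
    partial_member_count: int | None = None
    families: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def gene_gap(upstream: GeneModel, downstream: GeneModel, rule: ClusterRule) -> float:
    """Distance between two genes under the rule's anchor convention."""
    if rule.distance_anchor == "edge":
        return max(0, downstream.start - upstream.end)
    if rule.distance_anchor == "midpoint":
        return abs(downstream.midpoint - upstream.midpoint)
    return abs(downstream.start - upstream.start)


def pair_linked(
    upstream: GeneModel,
    downstream: GeneModel,
    n_intervening: int,
    rule: ClusterRule,
) -> bool:
    """'closer than' is strict; 'no more than' intervening is inclusive."""
    return (gene_gap(upstream, downstream, rule) < rule.max_gap_bp
            and n_intervening <= rule.max_intervening)


def find_clusters(
    annotation: GenomeAnnotation,
    focal_ids: Iterable[str],
    rule: ClusterRule | None = None,
) -> tuple[list[GeneCluster], list[str], list[str]]:
    """Partition focal genes into clusters, singletons and unmapped.

    Returns ``(clusters, singletons, unmapped)``: focal genes on anchored
    sequences end up in a cluster or as a singleton; focal genes on
    unanchored sequences are reported unmapped and never clustered.
    """
    rule = rule or ClusterRule()
    focal = set(focal_ids)
    unknown = focal - set(annotation.gene_ids())
    if unknown:
        raise KeyError(f"unknown focal gene ids: {sorted(unknown)[:10]}"
                       f"{'...' if len(unknown) > 10 else ''}")

    unmapped: list[str] = []
    clusters: list[GeneCluster] = []
    singletons: list[str] = []

    by_seq: dict[str, list[tuple[int, GeneModel]]] = {}
    for gid in focal:
        g = annotation.gene(gid)
        if not g.anchored:
            unmapped.append(gid)
        else:
            by_seq.setdefault(g.seq_id, []).append((annotation.rank(gid), g))
    unmapped.sort()

    for seq_id in sorted(by_seq):
        focal_here = sorted(by_seq[seq_id], key=lambda t: t[0])
        chains: list[list[GeneModel]] = [[focal_here[0][1]]]
        prev_rank, prev_gene = focal_here[0]
        for rank, gene in focal_here[1:]:
            n_intervening = rank - prev_rank - 1
            if pair_linked(prev_gene, gene, n_intervening, rule):
                chains[-1].append(gene)
            else:
                chains.append([gene])
            prev_rank, prev_gene = rank, gene
        for chain in chains:
            if len(chain) >= rule.min_members:
                clusters.append(GeneCluster(
                    cluster_id="",  # assigned after global sort
                    seq_id=seq_id,
                    members=[g.gene_id for g in chain],
                    span_start=min(g.start for g in chain),
                    span_end=max(g.end for g in chain),
                ))
            else:
                singletons.extend(g.gene_id for g in chain)

    clusters.sort(key=lambda c: (c.seq_id, c.span_start, c.span_end))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"C{i:03d}"
    return clusters, sorted(singletons), unmapped


def label_homogeneity(
    cluster: GeneCluster,
    calls: Mapping[str, "ArchitectureCall"],  # noqa: F821 - duck-typed
    clade_map: Mapping[str, str] | None = None,
) -> GeneCluster:
    """Set the homogeneity flags of a cluster in place (and return it).

    Family homogeneity considers only full-length members (TNL_type or
    CNL_type); partial members are counted but do not break homogeneity.  A
    cluster whose members are all partial is vacuously homogeneous.  Clade
    homogeneity is left undefined when no clade map is supplied.
    """
    missing = [m for m in cluster.members if m not in calls]
    if missing:
        raise KeyError(f"cluster {cluster.cluster_id}: no call for {missing}")
    families = [calls[m].family for m in cluster.members]
    cluster.families = families
    full_length = {f for f in families if f in ("TNL_type", "CNL_type")}
    cluster.partial_member_count = sum(f == "partial" for f in families)
    cluster.homogeneous_by_family = len(full_length) <= 1
    if clade_map is not None:
        clades = {clade_map.get(m) for m in cluster.members}
        cluster.homogeneous_by_clade = len(clades) == 1 and None not in clades
    return cluster


def chromosome_summary(
    clusters: Sequence[GeneCluster],
    singletons: Sequence[str],
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Per-chromosome accounting of mapped focal genes and their clusters."""
    per: dict[str, dict] = {}

    def row(seq_id: str) -> dict:
        return per.setdefault(seq_id, {"n_genes": 0, "n_clusters": 0,
                                       "n_singletons": 0, "cluster_sizes": []})

    for c in clusters:
        r = row(c.seq_id)
        r["n_clusters"] += 1
        r["n_genes"] += c.size
        r["cluster_sizes"].append(c.size)
    for gid in singletons:
        r = row(annotation.gene(gid).seq_id)
        r["n_singletons"] += 1
        r["n_genes"] += 1
    table = pd.DataFrame(
        [{"seq_id": s, **v} for s, v in sorted(per.items())],
        columns=["seq_id", "n_genes", "n_clusters", "n_singletons", "cluster_sizes"],
    )
    return table


def merge_superclusters(
    clusters: Sequence[GeneCluster],
    singletons: Sequence[str],
    annotation: GenomeAnnotation,
    window_bp: int = 1_000_000,
) -> list[dict]:
    """Optional, descriptive-only merge of clusters/singletons within a window.

    This "supercluster" view groups any clusters or singletons whose spans lie
    within *window_bp* of each other on the same sequence.  It is a reporting
    convenience, not part of the cluster definition.
    """
    items: list[tuple[str, int, int, list[str]]] = []
    for c in clusters:
        items.append((c.seq_id, c.span_start, c.span_end, list(c.members)))
    for gid in singletons:
        g = annotation.gene(gid)
        items.append((g.seq_id, g.start, g.end, [gid]))
    items.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[dict] = []
    for seq_id, start, end, members in items:
        if (merged and merged[-1]["seq_id"] == seq_id
                and start - merged[-1]["span_end"] <= window_bp):
            m = merged[-1]
            m["span_end"] = max(m["span_end"], end)
            m["members"].extend(members)
        else:
            merged.append({"seq_id": seq_id, "span_start": start,
                           "span_end": end, "members": members})
    return [m for m in merged]


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append({
            "cluster_id": c.cluster_id,
            "seq_id": c.seq_id,
            "span_start": c.span_start,
            "span_end": c.span_end,
            "size": c.size,
            "members": ",".join(c.members),
            "homogeneous_by_family": c.homogeneous_by_family,
            "homogeneous_by_clade": c.homogeneous_by_clade,
            "n_partial_members": c.partial_member_count,
        })
    return pd.DataFrame(rows, columns=["cluster_id", "seq_id", "span_start",
                                       "span_end", "size", "members",
                                       "homogeneous_by_family",
                                       "homogeneous_by_clade",
                                       "n_partial_members"])
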