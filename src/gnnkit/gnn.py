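"""Genome neighborhood networks.

Neighbors pooled from every query's +/-N window form a second SSN — the
GNN — clustered at its own e-value cutoff (default 1e-20, loose enough to
keep a protein family in one component). Each neighbor node carries the
color(s) of the query cluster(s) whose windows collected it; a GNN
cluster's color composition then says which query families co-occur with
that neighbor family in genomes, and per-color query coverage separates
pathway partners (many queries of one family contribute) from background
genes that land near queries at random.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .genomes import Neighborhood
from .seqio import AnnotationTable, SequenceRecord
from .similarity import SimilarityEdge
from .ssn import (
    PALETTE,
    SINGLETON,
    ClusterAssignment,
    apply_threshold,
    build_graph,
    components,
    number_and_color,
)

SIGNAL = "SIGNAL"
BACKGROUND = "BACKGROUND"

#: ColorBag: per neighbor protein, the set of (query_cluster_number,
#: query_id) collection events. Cluster number SINGLETON (0) is the
#: reserved color for neighborhoods of singleton queries.
ColorBag = dict[str, set[tuple[int, str]]]


@dataclass
class CompositionRow:
    """One color's contribution to a GNN cluster."""

    color: int
    node_count: int
    distinct_query_count: int
    query_coverage: float


@dataclass
class GnnCluster:
    """A neighbor-protein family: one GNN connected component (size >= 2)."""

    number: int
    members: frozenset[str]
    color: str = ""
    composition: dict[int, CompositionRow] = field(default_factory=dict)
    label: str = "unannotated"
    flag: str = BACKGROUND

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def colors(self) -> frozenset[int]:
        return frozenset(self.composition)


@dataclass
class MapBackResult:
    """Contributing SSN query nodes of one GNN cluster, by SSN cluster."""

    gnn_cluster_number: int
    queries_by_ssn_cluster: dict[int, frozenset[str]]

    @property
    def query_ids(self) -> frozenset[str]:
        return frozenset(q for qs in self.queries_by_ssn_cluster.values() for q in qs)

    @property
    def colors(self) -> frozenset[int]:
        return frozenset(self.queries_by_ssn_cluster)


def collect_neighbors(
    neighborhoods: Iterable[Neighborhood],
    query_assignment: ClusterAssignment,
    sequences: Optional[dict[str, str]] = None,
) -> tuple[list[SequenceRecord], ColorBag]:
    """Pool neighbor proteins from all query windows, tracking provenance.

    Neighbors are deduplicated by protein id — the same protein collected
    by queries of two different clusters becomes one node holding both
    colors. Query proteins never enter through their own window (offset 0
    is excluded upstream), but a query-family member sitting at a nonzero
    offset of another query IS retained, which is what lets the query
    family itself appear in the GNN when members are genome-proximal.
    """
    records: dict[str, SequenceRecord] = {}
    colors: ColorBag = defaultdict(set)
    for nbh in neighborhoods:
        qid = nbh.query_protein_id
        if qid not in query_assignment.membership:
            raise KeyError(f"neighborhood query {qid!r} is not in the SSN assignment")
        color = query_assignment.membership[qid]
        for _offset, feat in nbh.neighbors:
            colors[feat.protein_id].add((color, qid))
            if feat.protein_id not in records:
                residues = feat.translation or (sequences or {}).get(feat.protein_id, "")
                if not residues:
                    raise ValueError(
                        f"neighbor {feat.protein_id!r} has no protein sequence"
                    )
                records[feat.protein_id] = SequenceRecord(
                    seq_id=feat.protein_id,
                    residues=residues,
                    description=feat.product,
                )
    ordered_ids = sorted(records)
    return [records[i] for i in ordered_ids], dict(colors)


def build_gnn(
    neighbor_records: list[SequenceRecord],
    edges: Iterable[SimilarityEdge],
    colors: ColorBag,
    query_assignment: ClusterAssignment,
    cutoff: float = 1e-20,
    annotations: Optional[AnnotationTable] = None,
    min_size: int = 3,
    min_coverage: float = 0.5,
    palette: Sequence[str] = PALETTE,
) -> tuple[nx.Graph, list[GnnCluster]]:
    """Cluster the pooled neighbors into the GNN and score compositions.

    The graph is thresholded at ``cutoff``; components of size >= 2 become
    numbered GNN clusters (same deterministic numbering rules as the SSN),
    each with its color composition, plurality annotation label, and
    SIGNAL/BACKGROUND flag. Singleton neighbors stay in the graph,
    unclustered.
    """
    graph = build_graph(neighbor_records, edges)
    filtered = apply_threshold(graph, cutoff)
    assignment = number_and_color(components(filtered, threshold=cutoff), palette)
    annotations = annotations if annotations is not None else AnnotationTable()

    for node in filtered.nodes:
        bag = sorted(colors.get(node, ()))
        filtered.nodes[node]["colors"] = sorted({c for c, _q in bag})
        filtered.nodes[node]["collected_by"] = [q for _c, q in bag]
        filtered.nodes[node]["gnn_cluster"] = assignment.membership.get(node, SINGLETON)
        filtered.nodes[node]["annotation"] = annotations.label(node)

    clusters: list[GnnCluster] = []
    for number, members in enumerate(assignment.clusters, start=1):
        comp = composition(members, colors, query_assignment)
        label_counts = Counter(annotations.label(m) for m in members)
        top = max(label_counts.values())
        label = min(lbl for lbl, n in label_counts.items() if n == top)
        clusters.append(
            GnnCluster(
                number=number,
                members=members,
                color=assignment.cluster_colors[number],
                composition=comp,
                label=label,
            )
        )
    classify_clusters(clusters, min_size=min_size, min_coverage=min_coverage)
    return filtered, clusters


def composition(
    members: Iterable[str],
    colors: ColorBag,
    query_assignment: ClusterAssignment,
) -> dict[int, CompositionRow]:
    """Tally a cluster's members by query color.

    Per color: the number of member nodes holding it (multi-color nodes
    count once per color), the number of distinct queries of that color
    that contributed, and the query coverage — contributing queries over
    all queries in that SSN cluster. The reserved singleton color has
    coverage 0 by construction.
    """
    node_counts: Counter[int] = Counter()
    queries: dict[int, set[str]] = defaultdict(set)
    for member in members:
        bag = colors.get(member, set())
        for color in {c for c, _q in bag}:
            node_counts[color] += 1
        for color, query in bag:
            queries[color].add(query)
    rows: dict[int, CompositionRow] = {}
    for color in sorted(node_counts):
        total = query_assignment.cluster_sizes.get(color, 0)
        coverage = len(queries[color]) / total if total else 0.0
        rows[color] = CompositionRow(
            color=color,
            node_count=node_counts[color],
            distinct_query_count=len(queries[color]),
            query_coverage=coverage,
        )
    return rows


def classify_clusters(
    clusters: Iterable[GnnCluster], min_size: int = 3, min_coverage: float = 0.5
) -> dict[int, str]:
    """Flag each GNN cluster as SIGNAL or BACKGROUND.

    SIGNAL requires the cluster to be large enough (size >= min_size) and
    systematically collected: some query cluster must contribute via at
    least ``min_coverage`` of its queries. Everything else — small
    clusters, and multi-color confetti picked up sporadically across many
    genomes — is background noise. The singleton query color never
    confers SIGNAL.
    """
    flags: dict[int, str] = {}
    for cluster in clusters:
        best = max(
            (
                row.query_coverage
                for color, row in cluster.composition.items()
                if color != SINGLETON
            ),
            default=0.0,
        )
        cluster.flag = (
            SIGNAL if cluster.size >= min_size and best >= min_coverage else BACKGROUND
        )
        flags[cluster.number] = cluster.flag
    return flags


def map_back(
    gnn_cluster: GnnCluster | int,
    clusters: Sequence[GnnCluster] | None,
    colors: ColorBag,
    query_assignment: ClusterAssignment,
) -> MapBackResult:
    """Project a GNN cluster back onto the SSN.

    Returns the query nodes whose neighborhoods contributed at least one
    member to the GNN cluster, grouped by their SSN cluster number — the
    map of which query families share this genome-context partner.
    """
    if isinstance(gnn_cluster, int):
        if clusters is None:
            raise ValueError("cluster list required when passing a cluster number")
        match = [c for c in clusters if c.number == gnn_cluster]
        if not match:
            raise KeyError(f"unknown GNN cluster {gnn_cluster}")
        gnn_cluster = match[0]
    grouped: dict[int, set[str]] = defaultdict(set)
    for member in gnn_cluster.members:
        for color, query in colors.get(member, set()):
            grouped[color].add(query)
    return MapBackResult(
        gnn_cluster_number=gnn_cluster.number,
        queries_by_ssn_cluster={c: frozenset(qs) for c, qs in grouped.items()},
    )
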