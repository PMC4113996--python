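"""Sequence similarity networks: thresholding, clustering, numbering, colors.

An SSN is an undirected graph whose nodes are unique protein sequences and
whose edges connect pairs more similar than an e-value cutoff. Clusters are
the connected components with at least two members at the displayed cutoff;
isolated nodes are singletons and are counted separately. Clusters receive
deterministic numbers (by size, largest first, ties broken by smallest
member id) and colors from a fixed palette, so that downstream genome-
context coloring is reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .seqio import SequenceRecord
from .similarity import SimilarityEdge

#: Sentinel cluster number for singleton nodes in membership tables.
SINGLETON = 0

#: Default 28-color palette of named colors used for query clusters, in
#: numbering order; cycles with a numeric suffix if there are more clusters.
PALETTE: tuple[str, ...] = (
    "magenta", "blue", "red", "brown", "navy", "olive", "orange",
    "pale green", "teal", "light sky blue", "dark green", "gold",
    "purple", "cyan", "salmon", "dark red", "slate blue", "lime green",
    "chocolate", "orchid", "steel blue", "khaki", "crimson", "turquoise",
    "indigo", "coral", "sea green", "plum",
)


@dataclass
class ClusterAssignment:
    """Partition of SSN nodes into numbered clusters and singletons.

    ``membership`` maps every node to its cluster number (>= 1) or to
    :data:`SINGLETON` (0). Before :func:`number_and_color` is applied,
    ``clusters`` holds the raw components and the numbering-dependent
    fields are empty.
    """

    threshold: float
    clusters: list[frozenset[str]] = field(default_factory=list)
    singletons: frozenset[str] = frozenset()
    membership: dict[str, int] = field(default_factory=dict)
    cluster_colors: dict[int, str] = field(default_factory=dict)
    cluster_sizes: dict[int, int] = field(default_factory=dict)
    numbered: bool = False

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return len(self.singletons)

    def members_of(self, cluster_number: int) -> frozenset[str]:
        if not self.numbered:
            raise ValueError("assignment is not numbered yet")
        return self.clusters[cluster_number - 1]

    def color_of_node(self, seq_id: str) -> str | None:
        num = self.membership.get(seq_id, SINGLETON)
        return self.cluster_colors.get(num)


def build_graph(
    unique: Iterable[SequenceRecord | str], edges: Iterable[SimilarityEdge]
) -> nx.Graph:
    """Assemble the SSN from unique sequences and merged edges.

    All unique sequences become nodes, including isolated ones. An edge
    referencing an id outside the node set is an error.
    """
    graph = nx.Graph()
    for rec in unique:
        if isinstance(rec, SequenceRecord):
            graph.add_node(rec.seq_id, length=rec.length, description=rec.description)
        else:
            graph.add_node(rec)
    for edge in edges:
        for endpoint in (edge.id_a, edge.id_b):
            if endpoint not in graph:
                raise ValueError(f"edge endpoint {endpoint!r} is not a known sequence")
        graph.add_edge(
            edge.id_a,
            edge.id_b,
            evalue=edge.evalue,
            bit_score=edge.bit_score,
            pct_identity=edge.pct_identity,
        )
    return graph


def apply_threshold(graph: nx.Graph, cutoff: float) -> nx.Graph:
    """Keep edges with evalue <= cutoff; the node set is unchanged."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    filtered = nx.Graph()
    filtered.add_nodes_from(graph.nodes(data=True))
    filtered.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True) if d["evalue"] <= cutoff
    )
    return filtered


def components(graph: nx.Graph, threshold: float = float("inf")) -> ClusterAssignment:
    """Partition nodes into clusters (components of size >= 2) and singletons."""
    clusters: list[frozenset[str]] = []
    singles: set[str] = set()
    for comp in nx.connected_components(graph):
        if len(comp) >= 2:
            clusters.append(frozenset(comp))
        else:
            singles.update(comp)
    membership = {node: SINGLETON for node in singles}
    return ClusterAssignment(
        threshold=threshold,
        clusters=clusters,
        singletons=frozenset(singles),
        membership=membership,
    )


def number_and_color(
    assignment: ClusterAssignment, palette: Sequence[str] = PALETTE
) -> ClusterAssignment:
    """Assign deterministic cluster numbers 1..C and palette colors.

    Clusters are ordered by size (descending), ties broken by the
    lexicographically smallest member id. Colors cycle through the palette
    with a numeric suffix past one full cycle. The result is a pure
    function of the partition, independent of input order.
    """
    if not palette:
        raise ValueError("palette must not be empty")
    ordered = sorted(assignment.clusters, key=lambda c: (-len(c), min(c)))
    membership = dict.fromkeys(assignment.singletons, SINGLETON)
    colors: dict[int, str] = {}
    sizes: dict[int, int] = {}
    for idx, cluster in enumerate(ordered, start=1):
        for node in cluster:
            membership[node] = idx
        base = palette[(idx - 1) % len(palette)]
        cycle = (idx - 1) // len(palette)
        colors[idx] = base if cycle == 0 else f"{base} {cycle + 1}"
        sizes[idx] = len(cluster)
    return ClusterAssignment(
        threshold=assignment.threshold,
        clusters=ordered,
        singletons=assignment.singletons,
        membership=membership,
        cluster_colors=colors,
        cluster_sizes=sizes,
        numbered=True,
    )


def cluster_graph(graph: nx.Graph, cutoff: float, palette: Sequence[str] = PALETTE) -> ClusterAssignment:
    """Threshold, find components, and number them — the common path."""
    return number_and_color(components(apply_threshold(graph, cutoff), threshold=cutoff), palette)


@dataclass
class SweepLevel:
    cutoff: float
    n_clusters: int
    n_singletons: int
    n_edges: int
    assignment: ClusterAssignment
    #: strict cluster number -> cluster number at this (more relaxed) level;
    #: singletons that join a relaxed cluster are keyed as ('singleton', id).
    merge_map: dict[int, int] = field(default_factory=dict)


def threshold_sweep(graph: nx.Graph, cutoffs: Sequence[float]) -> list[SweepLevel]:
    """Cluster the SSN at a descending-stringency series of cutoffs.

    ``cutoffs`` must be numerically increasing (strictest first). Each
    level's merge map records which strictest-level clusters coalesce at
    that relaxation; the strict partition must refine every relaxed one,
    which is verified and enforced.
    """
    if len(cutoffs) < 2:
        raise ValueError("need at least two cutoffs")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly increasing (strictest first)")
    strict = cluster_graph(graph, cutoffs[0])
    levels: list[SweepLevel] = []
    for cutoff in cutoffs:
        filtered = apply_threshold(graph, cutoff)
        assignment = number_and_color(components(filtered, threshold=cutoff))
        merge_map: dict[int, int] = {}
        for num, cluster in enumerate(strict.clusters, start=1):
            targets = {assignment.membership[node] for node in cluster}
            if len(targets) != 1:
                raise AssertionError(
                    f"strict cluster {num} split across relaxed clusters at {cutoff:g}"
                )
            merge_map[num] = targets.pop()
        levels.append(
            SweepLevel(
                cutoff=cutoff,
                n_clusters=assignment.n_clusters,
                n_singletons=assignment.n_singletons,
                n_edges=filtered.number_of_edges(),
                assignment=assignment,
                merge_map=merge_map,
            )
        )
    return levels


def refines(fine: ClusterAssignment, coarse: ClusterAssignment) -> bool:
    """True iff every cluster of ``fine`` lies inside one block of ``coarse``.

    Singletons of the fine partition are single-node blocks and always
    refine. Used as the sweep's monotonicity check.
    """
    coarse_block: dict[str, int | tuple[str, str]] = {}
    for i, cluster in enumerate(coarse.clusters):
        for node in cluster:
            coarse_block[node] = i
    for node in coarse.singletons:
        coarse_block[node] = ("s", node)
    for cluster in fine.clusters:
        blocks = {coarse_block[node] for node in cluster}
        if len(blocks) != 1:
            return False
    return True
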