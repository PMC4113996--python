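"""High-level composition of the SSN -> neighborhoods -> GNN stages.

Thin orchestration over the per-stage modules, shared by the command-line
interface, the test suite, and the reproduction script. Edge computation
picks a backend automatically: the exact internal aligner at desk scale,
``blastp`` (if on PATH) for superfamily-scale inputs.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .genomes import GeneFeature, Neighborhood, extract_neighborhood
from .gnn import ColorBag, GnnCluster, build_gnn, collect_neighbors
from .seqio import AnnotationTable, SequenceRecord, deduplicate
from .similarity import (
    PairwiseHit,
    ScoringModel,
    SimilarityEdge,
    all_by_all,
    merge_reciprocal,
    run_blast,
)
from .ssn import ClusterAssignment, build_graph, cluster_graph
from .synthetic import GenomeSimulation, SimulationConfig, simulate

#: Above this many sequences the auto backend switches to blastp.
_INTERNAL_MAX_SEQS = 60


def compute_edges(
    records: list[SequenceRecord],
    max_evalue: float = 10.0,
    backend: str = "auto",
    scoring: Optional[ScoringModel] = None,
) -> list[SimilarityEdge]:
    """All-by-all similarities merged to undirected edges."""
    if backend == "auto":
        blast_ok = shutil.which("blastp") is not None
        backend = "blast" if blast_ok and len(records) > _INTERNAL_MAX_SEQS else "internal"
    if backend == "internal":
        hits: list[PairwiseHit] = all_by_all(records, scoring, max_evalue=max_evalue)
    elif backend == "blast":
        hits = run_blast(records, max_evalue=max_evalue)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return merge_reciprocal(hits)


def build_ssn(
    records: list[SequenceRecord],
    cutoff: float,
    backend: str = "auto",
    max_evalue: Optional[float] = None,
) -> tuple[nx.Graph, ClusterAssignment, dict[str, str]]:
    """Deduplicate, compute edges, and cluster at the display cutoff.

    Returns the full (unthresholded) graph, the numbered assignment at
    ``cutoff``, and the duplicate-to-representative map.
    """
    unique, rep_map = deduplicate(records)
    edges = compute_edges(unique, max_evalue=max_evalue or max(cutoff, 1e-5),
                          backend=backend)
    graph = build_graph(unique, edges)
    assignment = cluster_graph(graph, cutoff)
    return graph, assignment, rep_map


def neighborhoods_for(
    features: list[GeneFeature],
    assignment: ClusterAssignment,
    window: int = 10,
    rep_map: Optional[dict[str, str]] = None,
) -> list[Neighborhood]:
    """Extract the +/-window neighborhood of every SSN query found in the
    gene tables. Queries absent from every replicon are skipped (their
    genome is simply not in the input set)."""
    rep_map = rep_map or {}
    by_replicon: dict[str, list[GeneFeature]] = {}
    locus: dict[str, str] = {}
    for feat in features:
        by_replicon.setdefault(feat.replicon_id, []).append(feat)
        node = rep_map.get(feat.protein_id, feat.protein_id)
        if node in assignment.membership:
            locus[feat.protein_id] = feat.replicon_id
    out: list[Neighborhood] = []
    for protein_id in sorted(locus):
        node = rep_map.get(protein_id, protein_id)
        cluster = assignment.membership[node]
        nbh = extract_neighborhood(
            by_replicon[locus[protein_id]],
            protein_id,
            window=window,
            query_cluster=cluster,
            query_color=assignment.cluster_colors.get(cluster),
        )
        out.append(nbh)
    return out


@dataclass
class GnnResult:
    graph: nx.Graph
    clusters: list[GnnCluster]
    colors: ColorBag
    neighbor_records: list[SequenceRecord]


def gnn_from_neighborhoods(
    neighborhoods: Sequence[Neighborhood],
    assignment: ClusterAssignment,
    cutoff: float = 1e-20,
    backend: str = "auto",
    annotations: Optional[AnnotationTable] = None,
    min_size: int = 3,
    min_coverage: float = 0.5,
    sequences: Optional[dict[str, str]] = None,
) -> GnnResult:
    """Pool neighbors, compute their all-by-all edges, and build the GNN."""
    records, colors = collect_neighbors(neighborhoods, assignment, sequences=sequences)
    edges = compute_edges(records, max_evalue=cutoff, backend=backend)
    graph, clusters = build_gnn(
        records, edges, colors, assignment,
        cutoff=cutoff, annotations=annotations,
        min_size=min_size, min_coverage=min_coverage,
    )
    return GnnResult(graph=graph, clusters=clusters, colors=colors,
                     neighbor_records=records)


@dataclass
class SyntheticRun:
    """Everything one end-to-end run over simulated data produces."""

    records: list[SequenceRecord]
    sim: GenomeSimulation
    ssn_graph: nx.Graph
    assignment: ClusterAssignment
    neighborhoods: list[Neighborhood]
    gnn: GnnResult


def run_synthetic(
    config: SimulationConfig,
    ssn_cutoff: float = 1e-50,
    gnn_cutoff: float = 1e-20,
    window: int = 10,
    backend: str = "auto",
    min_size: int = 3,
    min_coverage: float = 0.5,
) -> SyntheticRun:
    """Simulate a superfamily plus genomes and run the full pipeline.

    The default cutoffs are the synthetic study conditions (see the methods
    note): 1e-50 separates the planted families cleanly at the generator's
    divergence settings, 1e-20 keeps each neighbor family in one GNN
    component, mirroring the roles the stricter real-data defaults play.
    """
    records, sim = simulate(config)
    graph, assignment, rep_map = build_ssn(records, ssn_cutoff, backend=backend)
    neighborhoods = neighborhoods_for(sim.features, assignment, window=window,
                                      rep_map=rep_map)
    gnn = gnn_from_neighborhoods(
        neighborhoods, assignment,
        cutoff=gnn_cutoff, backend=backend,
        annotations=sim.truth.annotation_table(),
        min_size=min_size, min_coverage=min_coverage,
    )
    return SyntheticRun(
        records=records, sim=sim, ssn_graph=graph, assignment=assignment,
        neighborhoods=neighborhoods, gnn=gnn,
    )
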