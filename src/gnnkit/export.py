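"""Serialization: Cytoscape XGMML, GraphML, and plain TSV tables.

All writers iterate in sorted order and format floats with ``repr`` (the
shortest round-trip representation), so output is byte-identical across
runs on the same input. E-values are written as decimal-exponent strings
rather than binary-typed floats so that 1e-300-scale values survive any
consumer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
from lxml import etree

from .genomes import GeneFeature, Neighborhood
from .gnn import GnnCluster, MapBackResult
from .seqio import SequenceRecord, write_fasta  # re-exported: the FASTA writer
from .ssn import SINGLETON, ClusterAssignment

__all__ = [
    "write_fasta",
    "write_xgmml",
    "read_xgmml",
    "write_graphml",
    "write_tables",
    "write_cluster_table",
    "read_cluster_table",
    "write_neighborhood_table",
    "read_neighborhood_table",
    "write_mapback_table",
]

XGMML_NS = "http://www.cs.rpi.edu/XGMML"


def _fmt(value) -> str:
    return repr(value) if isinstance(value, float) else str(value)


def _att(parent, name: str, value) -> None:
    if isinstance(value, (list, tuple)):
        att = etree.SubElement(parent, "att", name=name, type="list")
        for item in value:
            _att(att, name, item)
        return
    if isinstance(value, bool):
        kind, text = "string", str(value)
    elif isinstance(value, int):
        kind, text = "integer", str(value)
    elif isinstance(value, float):
        # e-values and friends: decimal string keeps tiny exponents intact
        kind, text = "string", repr(value)
    else:
        kind, text = "string", str(value)
    etree.SubElement(parent, "att", name=name, type=kind, value=text)


def write_xgmml(graph: nx.Graph, path: str | Path, name: str = "network") -> None:
    """Write a similarity graph as Cytoscape-compatible XGMML.

    Nodes are emitted sorted by id, edges by (id_a, id_b); all node and
    edge attributes are carried as typed ``att`` elements, lists included.
    """
    root = etree.Element("graph", label=name, directed="0", xmlns=XGMML_NS)
    nodes = sorted(graph.nodes)
    index = {node: str(i) for i, node in enumerate(nodes)}
    for node in nodes:
        el = etree.SubElement(root, "node", id=index[node], label=str(node))
        for key in sorted(graph.nodes[node]):
            _att(el, key, graph.nodes[node][key])
    for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges):
        el = etree.SubElement(
            root, "edge", source=index[u], target=index[v], label=f"{u},{v}"
        )
        for key in sorted(graph.edges[u, v]):
            _att(el, key, graph.edges[u, v][key])
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _parse_att(el) -> tuple[str, object]:
    kind = el.get("type", "string")
    if kind == "list":
        return el.get("name"), [ _parse_att(c)[1] for c in el if c.tag.endswith("att") ]
    value = el.get("value", "")
    if kind == "integer":
        return el.get("name"), int(value)
    if kind == "real":
        return el.get("name"), float(value)
    name = el.get("name")
    # numeric attributes serialized as strings for precision come back as floats
    if name in ("evalue", "bit_score", "pct_identity"):
        try:
            return name, float(value)
        except ValueError:
            pass
    return name, value


def read_xgmml(path: str | Path) -> nx.Graph:
    """Read a graph written by :func:`write_xgmml` (inverse on its output)."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XGMML in {path}: {exc}") from exc
    root = tree.getroot()
    ns = {"x": XGMML_NS}
    graph = nx.Graph(name=root.get("label", ""))
    by_index: dict[str, str] = {}
    for el in root.findall("x:node", ns):
        label = el.get("label")
        by_index[el.get("id")] = label
        attrs = dict(_parse_att(a) for a in el.findall("x:att", ns))
        graph.add_node(label, **attrs)
    for el in root.findall("x:edge", ns):
        u = by_index[el.get("source")]
        v = by_index[el.get("target")]
        attrs = dict(_parse_att(a) for a in el.findall("x:att", ns))
        graph.add_edge(u, v, **attrs)
    return graph


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write GraphML for non-Cytoscape consumers.

    GraphML has no list attribute type, so list attributes are flattened
    to ``;``-joined strings; floats become repr strings for precision.
    """
    out = nx.Graph(name=graph.name if hasattr(graph, "name") else "network")
    for node in sorted(graph.nodes):
        attrs = {
            k: ";".join(map(_fmt, v)) if isinstance(v, (list, tuple)) else
            (repr(v) if isinstance(v, float) else v)
            for k, v in sorted(graph.nodes[node].items())
        }
        out.add_node(node, **attrs)
    for u, v in sorted((min(u, v), max(u, v)) for u, v in graph.edges):
        attrs = {
            k: (repr(val) if isinstance(val, float) else val)
            for k, val in sorted(graph.edges[u, v].items())
        }
        out.add_edge(u, v, **attrs)
    nx.write_graphml(out, str(path))


def write_cluster_table(assignment: ClusterAssignment, path: str | Path) -> None:
    """SSN membership table: seq_id, cluster_number (0 = singleton), color, size."""
    with open(path, "w") as fh:
        fh.write("seq_id\tcluster_number\tcolor\tcluster_size\n")
        for seq_id in sorted(assignment.membership):
            num = assignment.membership[seq_id]
            color = assignment.cluster_colors.get(num, "")
            size = assignment.cluster_sizes.get(num, 1)
            fh.write(f"{seq_id}\t{num}\t{color}\t{size}\n")


def read_cluster_table(path: str | Path) -> ClusterAssignment:
    """Rebuild a numbered ClusterAssignment from :func:`write_cluster_table` output."""
    membership: dict[str, int] = {}
    colors: dict[int, str] = {}
    members: dict[int, set[str]] = {}
    singles: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("seq_id\t"):
            raise ValueError(f"{path} is not a cluster table")
        for line in fh:
            seq_id, num_s, color, _size = line.rstrip("\n").split("\t")
            num = int(num_s)
            membership[seq_id] = num
            if num == SINGLETON:
                singles.add(seq_id)
            else:
                colors[num] = color
                members.setdefault(num, set()).add(seq_id)
    ordered = [frozenset(members[n]) for n in sorted(members)]
    return ClusterAssignment(
        threshold=float("nan"),
        clusters=ordered,
        singletons=frozenset(singles),
        membership=membership,
        cluster_colors=colors,
        cluster_sizes={n: len(m) for n, m in members.items()},
        numbered=True,
    )


_NBH_COLUMNS = (
    "query_id\tquery_cluster\treplicon\toffset\tneighbor_protein_id"
    "\tlocus_tag\tproduct\tstrand\tstart\tend\tordinal"
)


def write_neighborhood_table(
    neighborhoods: Iterable[Neighborhood], path: str | Path
) -> None:
    """One row per (query, neighbor) collection event — the GNN provenance."""
    with open(path, "w") as fh:
        fh.write(_NBH_COLUMNS + "\n")
        for nbh in sorted(neighborhoods, key=lambda n: n.query_protein_id):
            for offset, feat in nbh.neighbors:
                fh.write(
                    "\t".join(
                        [
                            nbh.query_protein_id,
                            str(nbh.query_cluster if nbh.query_cluster is not None else ""),
                            nbh.replicon_id,
                            str(offset),
                            feat.protein_id,
                            feat.locus_tag,
                            feat.product,
                            feat.strand,
                            str(feat.start),
                            str(feat.end),
                            str(feat.ordinal),
                        ]
                    )
                    + "\n"
                )


def read_neighborhood_table(path: str | Path) -> list[Neighborhood]:
    """Inverse of :func:`write_neighborhood_table` (translations not carried:
    neighbor sequences travel in the companion FASTA)."""
    grouped: dict[tuple[str, str, Optional[int]], list[tuple[int, GeneFeature]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _NBH_COLUMNS:
            raise ValueError(f"{path} is not a neighborhood table")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            (qid, qcl, replicon, offset, pid, locus, product,
             strand, start, end, ordinal) = cols
            feat = GeneFeature(
                protein_id=pid,
                locus_tag=locus,
                replicon_id=replicon,
                ordinal=int(ordinal),
                strand=strand,
                start=int(start),
                end=int(end),
                product=product,
            )
            key = (qid, replicon, int(qcl) if qcl else None)
            grouped.setdefault(key, []).append((int(offset), feat))
    out = []
    for (qid, replicon, qcl), pairs in sorted(grouped.items()):
        pairs.sort(key=lambda p: p[0])
        out.append(
            Neighborhood(
                query_protein_id=qid,
                replicon_id=replicon,
                neighbors=pairs,
                query_cluster=qcl,
            )
        )
    return out


def write_mapback_table(result: MapBackResult, path: str | Path) -> None:
    """SSN node attribute table marking the queries a GNN cluster maps to."""
    with open(path, "w") as fh:
        fh.write("seq_id\tssn_cluster\tgnn_cluster\n")
        for cluster in sorted(result.queries_by_ssn_cluster):
            for qid in sorted(result.queries_by_ssn_cluster[cluster]):
                fh.write(f"{qid}\t{cluster}\t{result.gnn_cluster_number}\n")


def write_tables(
    path_prefix: str | Path,
    assignment: Optional[ClusterAssignment] = None,
    gnn_clusters: Optional[Sequence[GnnCluster]] = None,
    gnn_graph: Optional[nx.Graph] = None,
) -> list[Path]:
    """Write the standard TSV outputs under a common path prefix.

    Produces (as applicable): ``<prefix>clusters.tsv`` (SSN membership),
    ``<prefix>gnn_clusters.tsv`` (one summary row per GNN cluster),
    ``<prefix>gnn_composition.tsv`` (long-format color composition), and
    ``<prefix>gnn_nodes.tsv`` (per-node colors and provenance). Headers
    are always written, so empty inputs yield header-only files.
    """
    prefix = str(path_prefix)
    written: list[Path] = []
    if assignment is not None:
        p = Path(prefix + "clusters.tsv")
        write_cluster_table(assignment, p)
        written.append(p)
    if gnn_clusters is not None:
        p = Path(prefix + "gnn_clusters.tsv")
        with open(p, "w") as fh:
            fh.write("gnn_cluster\tsize\tlabel\tflag\tcolor\tquery_colors\n")
            for cl in gnn_clusters:
                cols = ";".join(str(c) for c in sorted(cl.colors))
                fh.write(f"{cl.number}\t{cl.size}\t{cl.label}\t{cl.flag}\t{cl.color}\t{cols}\n")
        written.append(p)
        p = Path(prefix + "gnn_composition.tsv")
        with open(p, "w") as fh:
            fh.write(
                "gnn_cluster\tcolor\tnode_count\tdistinct_query_count\tquery_coverage\n"
            )
            for cl in gnn_clusters:
                for color in sorted(cl.composition):
                    row = cl.composition[color]
                    fh.write(
                        f"{cl.number}\t{color}\t{row.node_count}"
                        f"\t{row.distinct_query_count}\t{repr(row.query_coverage)}\n"
                    )
        written.append(p)
    if gnn_graph is not None:
        p = Path(prefix + "gnn_nodes.tsv")
        with open(p, "w") as fh:
            fh.write("protein_id\tgnn_cluster\tcolors\tcollected_by\tannotation\n")
            for node in sorted(gnn_graph.nodes):
                data = gnn_graph.nodes[node]
                colors = ";".join(str(c) for c in data.get("colors", []))
                queries = ";".join(sorted(set(data.get("collected_by", []))))
                fh.write(
                    f"{node}\t{data.get('gnn_cluster', 0)}\t{colors}"
                    f"\t{queries}\t{data.get('annotation', 'unannotated')}\n"
                )
        written.append(p)
    return written
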