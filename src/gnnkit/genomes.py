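"""Genome annotation parsing and gene-neighborhood extraction.

Gene context is defined purely by gene order: CDS features on a replicon are
ranked by start coordinate into 0-based ordinals, and the neighborhood of a
query is the window of CDS with ordinals within +/-N of the query's, on the
query's replicon only. Strand is recorded but never reorders anything, and
windows are truncated at replicon (contig) ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneFeature:
    """One protein-coding gene on a replicon.

    Coordinates are 1-based inclusive (GenBank/GFF3 native); the ordinal is
    the gene's 0-based rank along the replicon in start-coordinate order.
    """

    protein_id: str
    locus_tag: str
    replicon_id: str
    ordinal: int
    strand: str
    start: int
    end: int
    product: str = ""
    translation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.protein_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.protein_id}: strand must be + or -")


@dataclass
class Neighborhood:
    """The ordered +/-N gene window around one query gene.

    ``neighbors`` holds (offset, feature) pairs with offsets in
    [-N, N] \\ {0}, strictly increasing; the query itself (offset 0) is
    never included.
    """

    query_protein_id: str
    replicon_id: str
    neighbors: list[tuple[int, GeneFeature]]
    query_cluster: Optional[int] = None
    query_color: Optional[str] = None

    def __post_init__(self) -> None:
        offsets = [off for off, _ in self.neighbors]
        if 0 in offsets:
            raise ValueError("offset 0 (the query) must not appear among neighbors")
        if offsets != sorted(offsets):
            raise ValueError("neighbor offsets must be strictly increasing")


def _sorted_with_ordinals(features: list[GeneFeature]) -> list[GeneFeature]:
    """Sort by (replicon, start, end, protein_id) and assign per-replicon ordinals."""
    features = sorted(features, key=lambda f: (f.replicon_id, f.start, f.end, f.protein_id))
    out: list[GeneFeature] = []
    counters: dict[str, int] = {}
    for feat in features:
        ordinal = counters.get(feat.replicon_id, 0)
        counters[feat.replicon_id] = ordinal + 1
        out.append(replace(feat, ordinal=ordinal))
    return out


def _dedup_protein_ids(features: list[GeneFeature]) -> list[GeneFeature]:
    seen: dict[str, int] = {}
    out = []
    for feat in features:
        if feat.protein_id in seen:
            new_id = f"{feat.protein_id}__{feat.replicon_id}"
            logger.warning("protein_id collision: %s renamed to %s", feat.protein_id, new_id)
            feat = replace(feat, protein_id=new_id)
        seen[feat.protein_id] = 1
        out.append(feat)
    return out


def read_genome(
    path: str | Path,
    format: str = "genbank",
    protein_fasta: str | Path | None = None,
) -> list[GeneFeature]:
    """Parse CDS features from GenBank or GFF3 into an ordered gene table.

    For GFF3, protein sequences must be supplied in a companion protein
    FASTA keyed by protein id; a CDS without a resolvable sequence is an
    error. CDS lacking both a protein_id and a locus_tag are skipped with
    a warning. Pseudogenes/non-CDS features never enter the gene count.
    """
    path = Path(path)
    if format == "genbank":
        features = _read_genbank(path)
    elif format in ("gff3", "gff"):
        if protein_fasta is None:
            raise ValueError("GFF3 input requires a companion protein FASTA")
        features = _read_gff3(path, Path(protein_fasta))
    else:
        raise ValueError(f"unknown genome format {format!r}")
    return _sorted_with_ordinals(_dedup_protein_ids(features))


def _read_genbank(path: Path) -> list[GeneFeature]:
    features: list[GeneFeature] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            if "pseudo" in quals or "pseudogene" in quals:
                continue
            protein_id = quals.get("protein_id", [None])[0]
            locus_tag = quals.get("locus_tag", [None])[0]
            if protein_id is None and locus_tag is None:
                logger.warning(
                    "skipping CDS at %s:%s with neither protein_id nor locus_tag",
                    rec.id, feat.location,
                )
                continue
            features.append(
                GeneFeature(
                    protein_id=protein_id or locus_tag,
                    locus_tag=locus_tag or protein_id,
                    replicon_id=rec.id,
                    ordinal=-1,
                    strand="+" if feat.location.strand != -1 else "-",
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    product=quals.get("product", [""])[0],
                    translation=quals.get("translation", [""])[0],
                )
            )
    return features


def _read_gff3(path: Path, protein_fasta: Path) -> list[GeneFeature]:
    import gffutils

    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta), "fasta")}
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for feat in db.features_of_type("CDS"):
        protein_id = (
            feat.attributes.get("protein_id", [None])[0]
            or feat.attributes.get("ID", [None])[0]
        )
        locus_tag = feat.attributes.get("locus_tag", [None])[0]
        if protein_id is None and locus_tag is None:
            logger.warning("skipping CDS at %s:%d with no identifier", feat.seqid, feat.start)
            continue
        pid = protein_id or locus_tag
        if pid not in proteins:
            raise ValueError(
                f"CDS {pid!r} has no sequence in companion protein FASTA {protein_fasta}"
            )
        features.append(
            GeneFeature(
                protein_id=pid,
                locus_tag=locus_tag or pid,
                replicon_id=feat.seqid,
                ordinal=-1,
                strand=feat.strand if feat.strand in "+-" else "+",
                start=feat.start,
                end=feat.end,
                product=feat.attributes.get("product", [""])[0],
                translation=proteins[pid],
            )
        )
    return features


def extract_neighborhood(
    features: list[GeneFeature],
    query_protein_id: str,
    window: int = 10,
    query_cluster: Optional[int] = None,
    query_color: Optional[str] = None,
) -> Neighborhood:
    """Collect the +/-window gene neighborhood of one query protein.

    Neighbors are the CDS whose ordinal lies within the window on the
    query's replicon, excluding the query itself; the window truncates at
    replicon ends. Offsets are ordinal differences, so the result depends
    only on gene order, never on strand or intergenic distance.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    query = next((f for f in features if f.protein_id == query_protein_id), None)
    if query is None:
        replicons = sorted({f.replicon_id for f in features})
        raise KeyError(
            f"query {query_protein_id!r} not found in genome(s): {', '.join(replicons)}"
        )
    neighbors = [
        (f.ordinal - query.ordinal, f)
        for f in features
        if f.replicon_id == query.replicon_id
        and f.protein_id != query.protein_id
        and abs(f.ordinal - query.ordinal) <= window
    ]
    neighbors.sort(key=lambda pair: pair[0])
    return Neighborhood(
        query_protein_id=query_protein_id,
        replicon_id=query.replicon_id,
        neighbors=neighbors,
        query_cluster=query_cluster,
        query_color=query_color,
    )
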