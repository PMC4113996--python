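"""Sequence and annotation I/O.

Protein collections are read from FASTA, validated against the 20-letter
amino-acid alphabet (plus ``X`` for unknown residues), and collapsed to
unique-sequence representatives before network construction: two proteins
with byte-identical residue strings become a single node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Residues accepted in input sequences. ``X`` is the standard unknown
#: placeholder; it scores zero against everything in the internal aligner.
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = AMINO_ACIDS | {"X"}

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with its accession and free-text description."""

    seq_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id!r} has no residues")

    @property
    def length(self) -> int:
        return len(self.residues)


class AnnotationTable(dict):
    """Mapping of seq_id to a family label; missing ids are 'unannotated'."""

    def label(self, seq_id: str) -> str:
        return self.get(seq_id, UNANNOTATED)


def _validate_residues(seq_id: str, residues: str, path: Path) -> str:
    residues = residues.upper()
    # trailing stop codons are a translation artifact, not sequence content
    residues = residues.rstrip("*")
    bad = set(residues) - ALLOWED_RESIDUES
    if bad:
        char = sorted(bad)[0]
        lineno = _find_char_line(path, seq_id, char)
        raise ValueError(
            f"invalid residue {char!r} in sequence {seq_id!r}"
            f" ({path}, line {lineno})"
        )
    if not residues:
        raise ValueError(f"sequence {seq_id!r} is empty after '*' stripping")
    return residues


def _find_char_line(path: Path, seq_id: str, char: str) -> int:
    """Locate the offending character for the error message."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == seq_id if line[1:].strip() else False
                continue
            if in_record and char in line.upper().rstrip("\n").rstrip("*"):
                return lineno
    return -1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into validated records, order preserved.

    The seq_id is the first whitespace-delimited token of the header.
    Duplicate ids, empty files, and residues outside the amino-acid
    alphabet (other than ``X`` and a trailing ``*``) are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id {seq_id!r} in {path}")
        seen.add(seq_id)
        residues = _validate_residues(seq_id, str(rec.seq), path)
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(seq_id=seq_id, residues=residues, description=desc))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA, deterministically in input order."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.seq_id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def deduplicate(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Collapse byte-identical sequences into unique-sequence nodes.

    Returns the unique records (represented by the lexicographically
    smallest seq_id of each identity group, in first-seen order) and a map
    from every input id to its representative.
    """
    groups: dict[str, list[SequenceRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.residues not in groups:
            groups[rec.residues] = []
            order.append(rec.residues)
        groups[rec.residues].append(rec)

    unique: list[SequenceRecord] = []
    rep_map: dict[str, str] = {}
    for residues in order:
        members = groups[residues]
        rep = min(members, key=lambda r: r.seq_id)
        unique.append(rep)
        for member in members:
            rep_map[member.seq_id] = rep.seq_id
    return unique, rep_map


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a 2-column TSV of (seq_id, label).

    A first line starting with ``#`` or reading ``seq_id<TAB>label`` is
    treated as a header. Later rows overwrite earlier ones with a warning.
    An empty file yields an empty (valid) table.
    """
    path = Path(path)
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if lineno == 1 and (line.startswith("#") or line.lower() == "seq_id\tlabel"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(
                    f"malformed annotation row at {path}:{lineno}: "
                    f"expected 2 tab-separated columns, got {len(cols)}"
                )
            seq_id, label = cols
            if seq_id in table and table[seq_id] != label:
                logger.warning(
                    "annotation for %s overwritten: %r -> %r (line %d)",
                    seq_id, table[seq_id], label, lineno,
                )
            table[seq_id] = label
    return table
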