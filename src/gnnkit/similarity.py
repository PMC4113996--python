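"""Pairwise protein similarities: the substrate of both the SSN and the GNN.

Edges between unique sequences can come from three routes that all yield the
same :class:`PairwiseHit` records:

* :func:`parse_blast_tabular` — ingest a precomputed all-by-all BLAST run
  (tabular ``-outfmt 6``);
* :func:`run_blast` — drive ``makeblastdb``/``blastp`` locally and parse the
  result (the fast route for superfamily-scale inputs);
* :func:`all_by_all` — an exact internal route: Smith–Waterman local
  alignment with affine gaps and Karlin–Altschul E-values. Quadratic and
  unaccelerated by design; intended for desk-scale inputs and as the exact
  reference in tests.

Directional hits are reduced to one undirected :class:`SimilarityEdge` per
protein pair by :func:`merge_reciprocal` (best E-value over both directions).
"""

from __future__ import annotations

import csv
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Optional

import biotite.sequence as _bseq
import biotite.sequence.align as _balign

from .seqio import SequenceRecord, write_fasta

LN2 = math.log(2.0)
LOG10_2 = math.log10(2.0)


@dataclass
class ScoringModel:
    """Scoring and Karlin–Altschul statistical parameters.

    Defaults correspond to gapped BLOSUM62 with BLAST's standard 11/1 affine
    gap costs (lambda = 0.267 nats, K = 0.041). ``db_residues`` is the
    effective database size n: for an all-by-all run, the summed length of
    all unique sequences.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    db_residues: int = 1

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.db_residues < 1:
            raise ValueError("db_residues must be >= 1")


@dataclass(frozen=True)
class PairwiseHit:
    """One directional pairwise similarity (one BLAST hit, or one internal
    alignment reported in a single orientation)."""

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    pct_identity: float
    aln_length: int
    raw_score: Optional[int] = None


@dataclass(frozen=True)
class SimilarityEdge:
    """Best undirected similarity between a protein pair; id_a < id_b."""

    id_a: str
    id_b: str
    evalue: float
    bit_score: float
    pct_identity: float

    def __post_init__(self) -> None:
        if not self.id_a < self.id_b:
            raise ValueError("edge endpoints must satisfy id_a < id_b")


_MATRIX_CACHE: dict[str, _balign.SubstitutionMatrix] = {}


def _substitution_matrix(name: str) -> _balign.SubstitutionMatrix:
    """BLOSUM62 with the X row/column zeroed (unknown residues are neutral)."""
    if name not in _MATRIX_CACHE:
        if name.upper() != "BLOSUM62":
            base = _balign.SubstitutionMatrix(
                _bseq.ProteinSequence.alphabet, _bseq.ProteinSequence.alphabet, name.upper()
            )
        else:
            base = _balign.SubstitutionMatrix.std_protein_matrix()
        scores = base.score_matrix().copy()
        alph = base.get_alphabet1()
        x = alph.encode("X")
        scores[x, :] = 0
        scores[:, x] = 0
        _MATRIX_CACHE[name] = _balign.SubstitutionMatrix(alph, alph, scores)
    return _MATRIX_CACHE[name]


def local_align(
    a: SequenceRecord, b: SequenceRecord, scoring: ScoringModel | None = None
) -> tuple[int, float, int]:
    """Optimal Smith–Waterman local alignment with affine gaps.

    Returns ``(raw_score, pct_identity, aln_length)``. Percent identity is
    identical aligned positions over the alignment length, with gapped
    columns counted in the length but never as identities. A sequence pair
    with no positive-scoring local alignment returns ``(0, 0.0, 0)``.

    A gap of length g costs ``gap_open + g * gap_extend`` (BLAST's affine
    convention), mapped onto the aligner's (first-position, extension)
    penalty pair.
    """
    scoring = scoring or ScoringModel()
    matrix = _substitution_matrix(scoring.matrix_name)
    seq_a = _bseq.ProteinSequence(a.residues)
    seq_b = _bseq.ProteinSequence(b.residues)
    alns = _balign.align_optimal(
        seq_a,
        seq_b,
        matrix,
        gap_penalty=(-(scoring.gap_open + scoring.gap_extend), -scoring.gap_extend),
        local=True,
        max_number=1,
    )
    if not alns or alns[0].score <= 0 or len(alns[0]) == 0:
        return 0, 0.0, 0
    aln = alns[0]
    identity = _balign.get_sequence_identity(aln, mode="all")
    return int(aln.score), 100.0 * identity, len(aln)


def evalue_of(
    raw_score: int, query_length: int, scoring: ScoringModel
) -> tuple[float, float]:
    """Karlin–Altschul statistics for a raw alignment score.

    bit = (lambda * S - ln K) / ln 2 and E = m * n * 2**(-bit), with m the
    query length and n the database residue count. Computed in log space so
    that extreme scores underflow cleanly to E = 0.0 rather than raising.
    """
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    bit = (scoring.lam * raw_score - math.log(scoring.K)) / LN2
    log10_e = math.log10(query_length) + math.log10(scoring.db_residues) - bit * LOG10_2
    evalue = 10.0 ** log10_e if log10_e > -320 else 0.0
    return bit, evalue


def all_by_all(
    records: list[SequenceRecord],
    scoring: ScoringModel | None = None,
    max_evalue: float = 10.0,
) -> list[PairwiseHit]:
    """Exact all-by-all similarities over deduplicated records.

    Every unordered pair is aligned exactly once; the aligner is symmetric,
    so each retained pair is emitted in a single orientation. Self-hits are
    excluded. The database size n is the total residue count of the input.
    """
    scoring = scoring or ScoringModel()
    scoring = ScoringModel(
        matrix_name=scoring.matrix_name,
        gap_open=scoring.gap_open,
        gap_extend=scoring.gap_extend,
        lam=scoring.lam,
        K=scoring.K,
        db_residues=sum(r.length for r in records),
    )
    hits: list[PairwiseHit] = []
    for a, b in combinations(records, 2):
        if b.seq_id < a.seq_id:
            a, b = b, a  # canonical orientation: results independent of input order
        raw, pident, aln_len = local_align(a, b, scoring)
        if aln_len == 0:
            continue
        # the best direction of a reciprocal search is the one with the
        # smaller query (E is linear in m), so report that one directly
        bit, evalue = evalue_of(raw, min(a.length, b.length), scoring)
        if evalue <= max_evalue:
            hits.append(
                PairwiseHit(
                    query_id=a.seq_id,
                    subject_id=b.seq_id,
                    bit_score=bit,
                    evalue=evalue,
                    pct_identity=pident,
                    aln_length=aln_len,
                    raw_score=raw,
                )
            )
    return hits


def parse_blast_tabular(path: str | Path) -> list[PairwiseHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Self-hits (qseqid == sseqid) are dropped;
    an e-value printed as ``0.0`` is kept as exactly 0 (it passes every
    threshold).
    """
    path = Path(path)
    hits: list[PairwiseHit] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 12:
                raise ValueError(
                    f"expected 12 columns at {path}:{lineno}, got {len(row)}"
                )
            try:
                pident = float(row[2])
                aln_length = int(row[3])
                evalue = float(row[10])
                bit = float(row[11])
            except ValueError as exc:
                raise ValueError(f"unparseable numeric field at {path}:{lineno}: {exc}")
            if row[0] == row[1]:
                continue
            hits.append(
                PairwiseHit(
                    query_id=row[0],
                    subject_id=row[1],
                    bit_score=bit,
                    evalue=evalue,
                    pct_identity=pident,
                    aln_length=aln_length,
                )
            )
    return hits


def run_blast(
    records: list[SequenceRecord],
    max_evalue: float = 10.0,
    threads: int = 1,
) -> list[PairwiseHit]:
    """All-by-all blastp over the records, returning parsed hits.

    Requires the NCBI BLAST+ ``makeblastdb`` and ``blastp`` executables on
    PATH. Used for superfamily-scale inputs where the exact internal
    aligner would be needlessly slow; thresholding and merging downstream
    are identical to the internal route.
    """
    if shutil.which("blastp") is None or shutil.which("makeblastdb") is None:
        raise RuntimeError("BLAST+ executables (blastp/makeblastdb) not found on PATH")
    with tempfile.TemporaryDirectory(prefix="gnnkit_blast_") as tmp:
        tmp_path = Path(tmp)
        fasta = tmp_path / "seqs.faa"
        write_fasta(records, fasta)
        db = tmp_path / "db"
        out = tmp_path / "hits.tsv"
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot", "-out", str(db)],
            check=True,
            capture_output=True,
        )
        subprocess.run(
            [
                "blastp",
                "-query", str(fasta),
                "-db", str(db),
                "-outfmt", "6",
                "-evalue", f"{max_evalue:g}",
                "-num_threads", str(threads),
                "-max_target_seqs", str(max(len(records), 10)),
                "-out", str(out),
            ],
            check=True,
            capture_output=True,
        )
        return parse_blast_tabular(out)


def merge_reciprocal(hits: Iterable[PairwiseHit]) -> list[SimilarityEdge]:
    """Reduce directional hits to one undirected edge per protein pair.

    For each unordered pair, the hit with the minimum e-value over both
    directions wins; ties go to the higher bit score, then to the
    id_a -> id_b direction. Output is sorted by (id_a, id_b).
    """
    best: dict[tuple[str, str], PairwiseHit] = {}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        key = (min(hit.query_id, hit.subject_id), max(hit.query_id, hit.subject_id))
        incumbent = best.get(key)
        if incumbent is None or _beats(hit, incumbent, key):
            best[key] = hit
    edges = [
        SimilarityEdge(
            id_a=key[0],
            id_b=key[1],
            evalue=hit.evalue,
            bit_score=hit.bit_score,
            pct_identity=hit.pct_identity,
        )
        for key, hit in best.items()
    ]
    edges.sort(key=lambda e: (e.id_a, e.id_b))
    return edges


def _beats(challenger: PairwiseHit, incumbent: PairwiseHit, key: tuple[str, str]) -> bool:
    if challenger.evalue != incumbent.evalue:
        return challenger.evalue < incumbent.evalue
    if challenger.bit_score != incumbent.bit_score:
        return challenger.bit_score > incumbent.bit_score
    # forward orientation (query == id_a) wins a full tie
    return challenger.query_id == key[0] and incumbent.query_id != key[0]
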