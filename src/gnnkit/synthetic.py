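"""Synthetic superfamilies and genomes with planted neighborhood structure.

The generator emulates the setting the networks are built for: a divergent
protein superfamily of F families (all descended from one root, so that
between-family similarity is weak but present), plus P unrelated "pathway
partner" families. Each query family member gets its own replicon, with the
partner genes of its family planted at fixed offsets inside the +/-10
window, the remaining window slots filled by noise genes — either members
of low-frequency "scatter" families that recur across random replicons
(genes that happen to be genome-proximal by chance across many species) or
fresh one-off random proteins.

Site substitutions are biased by BLOSUM62 target frequencies rather than
drawn uniformly, so simulated percent identities map onto realistic
alignment scores and E-values. Everything is driven by one seeded RNG:
the same config and seed reproduce byte-identical FASTA/GenBank output.
Protein and replicon identifiers are random digits, so no id encodes
family membership (no label leakage into the pipeline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import biotite.sequence.align as _balign

from .genomes import GeneFeature
from .seqio import AnnotationTable, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: BLOSUM62 background (marginal) amino-acid frequencies, order as AA20.
_BG = np.array([
    0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
    0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
])
_BG = _BG / _BG.sum()

#: Ungapped BLOSUM62 Karlin-Altschul lambda (half-bit matrix), in nats.
_LAMBDA_UNGAPPED = 0.3176


def _conditional_matrix() -> np.ndarray:
    """P(b | a) implied by BLOSUM62: p(a,b) ~ q_a q_b exp(lambda * s_ab)."""
    base = _balign.SubstitutionMatrix.std_protein_matrix()
    alph = base.get_alphabet1()
    idx = [alph.encode(a) for a in AA20]
    scores = base.score_matrix()[np.ix_(idx, idx)].astype(float)
    joint = _BG[:, None] * _BG[None, :] * np.exp(_LAMBDA_UNGAPPED * scores)
    cond = joint / joint.sum(axis=1, keepdims=True)
    return cond


_COND = _conditional_matrix()
_COND_CDF = np.cumsum(_COND, axis=1)
_BG_CDF = np.cumsum(_BG)


def random_protein(length: int, rng: np.random.Generator) -> str:
    """A protein drawn i.i.d. from BLOSUM62 background frequencies."""
    draws = np.searchsorted(_BG_CDF, rng.random(length))
    return "".join(AA20[i] for i in draws)


def mutate(residues: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability p, drawing the replacement from
    the BLOSUM62-conditional distribution (which may redraw the original
    residue — substitution is a resampling, not a forced change)."""
    encoded = np.fromiter((AA20.index(c) for c in residues), dtype=np.intp)
    mask = rng.random(len(encoded)) < p
    if mask.any():
        u = rng.random(int(mask.sum()))
        rows = _COND_CDF[encoded[mask]]
        encoded[mask] = np.array(
            [np.searchsorted(rows[i], u[i]) for i in range(len(u))], dtype=np.intp
        )
    return "".join(AA20[i] for i in encoded)


def expected_identity(residues: str, p: float) -> float:
    """Analytic expected identity between a sequence and one mutated copy:
    1 - p * (1 - mean over sites of P(a | a))."""
    same = np.array([_COND[AA20.index(c), AA20.index(c)] for c in residues])
    return 1.0 - p * float((1.0 - same).mean())


class _IdAllocator:
    """Random, collision-free numeric ids — no family information leaks."""

    def __init__(self, rng: np.random.Generator, prefix: str = "S"):
        self._rng = rng
        self._prefix = prefix
        self._used: set[int] = set()

    def next(self) -> str:
        while True:
            n = int(self._rng.integers(0, 10**9))
            if n not in self._used:
                self._used.add(n)
                return f"{self._prefix}{n:09d}"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic superfamily and genomes.

    Defaults: 8 query families of 20 members each, 300-residue proteins,
    per-site substitution probability 0.3 within a family and 0.8 between
    family ancestors (≈52% within-family and near-background between-family
    pairwise identity); 4 partner families planted at fixed small offsets
    for fixed query-family subsets; 11-gene replicons (query centered, the
    window truncates at the contig ends); 5 scatter noise families filling
    free window slots with probability 0.1 each, the rest one-off random
    genes.
    """

    n_families: int = 8
    members_per_family: int = 20
    length: int = 300
    n_partner_families: int = 4
    partner_map: Optional[dict[int, frozenset[int]]] = None
    p_within: float = 0.3
    p_between: float = 0.8
    replicon_halfwidth: int = 5
    n_scatter_families: int = 5
    scatter_prob: float = 0.1
    adjacent_pair: Optional[tuple[int, int]] = None
    seed: int = 0
    #: offsets used, in order, for a family's sorted partner list
    offset_cycle: tuple[int, ...] = (1, 2, -2, 3, -3, 4, -4)

    def __post_init__(self) -> None:
        if not (0 <= self.p_within < self.p_between <= 1):
            raise ValueError("need 0 <= p_within < p_between <= 1")
        for n in (self.n_families, self.members_per_family, self.length,
                  self.replicon_halfwidth):
            if n < 1:
                raise ValueError("all counts must be >= 1")
        if any(o == 0 or abs(o) > 10 for o in self.offset_cycle):
            raise ValueError("partner offsets must be in [-10, 10] and nonzero")
        if self.partner_map is None:
            self.partner_map = self._default_partner_map()
        for f, partners in self.partner_map.items():
            if not 0 <= f < self.n_families:
                raise ValueError(f"partner_map references unknown family {f}")
            if any(not 0 <= p < self.n_partner_families for p in partners):
                raise ValueError(f"partner_map for family {f} references unknown partner")
            if len(partners) > len(self.offset_cycle):
                raise ValueError("more partners than available offsets")
        if self.adjacent_pair is not None:
            f, g = self.adjacent_pair
            if f == g or not all(0 <= x < self.n_families for x in (f, g)):
                raise ValueError("adjacent_pair must name two distinct families")
            # the paired query occupies offset +1 of the host query
            for fam in (f,):
                n_partners = len(self.partner_map.get(fam, ()))
                offsets = set(self.offset_cycle[:n_partners])
                if 1 in offsets:
                    raise ValueError(
                        "offset collision: family partners occupy +1, which the "
                        "adjacent query needs"
                    )

    def _default_partner_map(self) -> dict[int, frozenset[int]]:
        if self.n_partner_families == 0:
            return {}
        # spread partners over families: some single-color, some multi-color
        assignments = {
            0: {0}, 1: {0, 1}, 2: {1}, 3: {2}, 4: {2, 3}, 5: {3}, 6: {0}, 7: {1, 2},
        }
        out: dict[int, frozenset[int]] = {}
        for f in range(self.n_families):
            partners = {p % self.n_partner_families for p in assignments.get(f % 8, {0})}
            out[f] = frozenset(partners)
        return out


@dataclass
class GroundTruth:
    """What was planted: families, partner wiring, and replicon layouts."""

    query_family: dict[str, int] = field(default_factory=dict)
    partner_map: dict[int, frozenset[int]] = field(default_factory=dict)
    partner_ancestors: dict[int, str] = field(default_factory=dict)
    scatter_ancestors: dict[int, str] = field(default_factory=dict)
    #: protein id -> (role, family index or None); roles: query, partner,
    #: scatter, background
    role: dict[str, tuple[str, Optional[int]]] = field(default_factory=dict)
    replicon_of_query: dict[str, str] = field(default_factory=dict)
    #: query id -> {offset -> partner index} as planted
    planted: dict[str, dict[int, int]] = field(default_factory=dict)

    def annotation_table(self) -> AnnotationTable:
        table = AnnotationTable()
        for pid, (role, idx) in self.role.items():
            table[pid] = role if idx is None else f"{role}_family_{idx}"
        return table

    def family_members(self, family: int) -> list[str]:
        return sorted(q for q, f in self.query_family.items() if f == family)


def evolve_family(
    ancestor: str,
    n_members: int,
    p_within: float,
    rng: np.random.Generator,
    ids: Optional[Sequence[str]] = None,
) -> list[SequenceRecord]:
    """Independently mutate the ancestor into n_members descendants."""
    records = []
    for i in range(n_members):
        seq = mutate(ancestor, p_within, rng)
        seq_id = ids[i] if ids is not None else f"M{i:04d}"
        records.append(SequenceRecord(seq_id=seq_id, residues=seq))
    return records


def simulate_superfamily(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[SequenceRecord], GroundTruth, np.random.Generator, _IdAllocator]:
    """Generate the query superfamily plus partner/scatter family ancestors.

    Query family ancestors descend from one shared root mutated at
    p_between, so families are homologous but deeply divergent; partner and
    scatter ancestors are independent random proteins, unalignable to the
    queries. Returns the RNG and id allocator so genome simulation can
    continue the same deterministic stream.
    """
    rng = rng or np.random.default_rng(config.seed)
    alloc = _IdAllocator(rng)
    truth = GroundTruth(partner_map=dict(config.partner_map))

    root = random_protein(config.length, rng)
    records: list[SequenceRecord] = []
    for f in range(config.n_families):
        ancestor = mutate(root, config.p_between, rng)
        ids = [alloc.next() for _ in range(config.members_per_family)]
        members = evolve_family(ancestor, config.members_per_family,
                                config.p_within, rng, ids)
        for rec in members:
            truth.query_family[rec.seq_id] = f
            truth.role[rec.seq_id] = ("query", f)
        records.extend(members)
    for p in range(config.n_partner_families):
        truth.partner_ancestors[p] = random_protein(config.length, rng)
    for s in range(config.n_scatter_families):
        truth.scatter_ancestors[s] = random_protein(config.length, rng)
    return records, truth, rng, alloc


@dataclass
class GenomeSimulation:
    """Simulated replicons as an ordered gene table plus emitters."""

    features: list[GeneFeature]
    truth: GroundTruth
    config: SimulationConfig

    def replicon_features(self, replicon_id: str) -> list[GeneFeature]:
        return [f for f in self.features if f.replicon_id == replicon_id]

    def write_genbank(self, path: str | Path) -> None:
        """Emit all replicons as one multi-record GenBank flat file with
        coordinate-consistent back-translated CDS and translations."""
        from Bio.Seq import Seq
        from Bio.SeqFeature import FeatureLocation, SeqFeature
        from Bio.SeqRecord import SeqRecord as BioRecord
        from Bio import SeqIO

        codon = {  # one fixed codon per residue: deterministic back-translation
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
            "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
            "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAA", "R": "CGT",
            "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "X": "NNN",
            "Y": "TAT",
        }
        by_replicon: dict[str, list[GeneFeature]] = {}
        for feat in self.features:
            by_replicon.setdefault(feat.replicon_id, []).append(feat)
        bio_records = []
        for replicon_id in sorted(by_replicon):
            feats = sorted(by_replicon[replicon_id], key=lambda f: f.start)
            length = max(f.end for f in feats) + 50
            dna = bytearray(b"A" * length)
            bio_feats = []
            for feat in feats:
                cds = "".join(codon[c] for c in feat.translation) + "TAA"
                dna[feat.start - 1 : feat.start - 1 + len(cds)] = cds.encode()
                bio_feats.append(
                    SeqFeature(
                        FeatureLocation(feat.start - 1, feat.end,
                                        strand=1 if feat.strand == "+" else -1),
                        type="CDS",
                        qualifiers={
                            "protein_id": [feat.protein_id],
                            "locus_tag": [feat.locus_tag],
                            "product": [feat.product],
                            "transl_table": ["11"],
                            "translation": [feat.translation],
                        },
                    )
                )
            rec = BioRecord(
                Seq(bytes(dna).decode()),
                id=replicon_id,
                name=replicon_id[:16],
                description="synthetic replicon",
                annotations={"molecule_type": "DNA", "topology": "linear"},
            )
            rec.features = bio_feats
            bio_records.append(rec)
        SeqIO.write(bio_records, str(path), "genbank")


def simulate_genomes(
    records: list[SequenceRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    alloc: Optional[_IdAllocator] = None,
) -> GenomeSimulation:
    """Place every query member on its own replicon with planted partners.

    Layout per replicon (2R+1 genes, R = replicon_halfwidth): the query at
    ordinal R; its family's partner genes — freshly evolved members of the
    partner ancestors at p_within — at the configured offsets; each
    remaining slot holds a scatter-family member with probability
    scatter_prob, else a one-off random background gene. With
    ``adjacent_pair=(f, g)``, member i of family g is placed at offset +1
    of member i of family f instead of getting its own replicon.
    """
    alloc = alloc or _IdAllocator(rng)
    cfg = config
    R = cfg.replicon_halfwidth
    by_family: dict[int, list[SequenceRecord]] = {}
    rec_by_id = {r.seq_id: r for r in records}
    for rec in records:
        fam = truth.query_family[rec.seq_id]
        by_family.setdefault(fam, []).append(rec)

    paired_guest: dict[str, str] = {}
    skip_own_replicon: set[str] = set()
    if cfg.adjacent_pair is not None:
        f, g = cfg.adjacent_pair
        hosts, guests = by_family[f], by_family[g]
        if len(hosts) != len(guests):
            raise ValueError("adjacent_pair families must have equal size")
        for host, guest in zip(hosts, guests):
            paired_guest[host.seq_id] = guest.seq_id
            skip_own_replicon.add(guest.seq_id)

    features: list[GeneFeature] = []
    for rec in records:
        if rec.seq_id in skip_own_replicon:
            continue
        fam = truth.query_family[rec.seq_id]
        replicon_id = f"rep{alloc.next()[1:]}"
        truth.replicon_of_query[rec.seq_id] = replicon_id
        slots: dict[int, tuple[str, str, tuple[str, Optional[int]]]] = {}
        # (ordinal -> (protein_id, residues, role))
        slots[R] = (rec.seq_id, rec.residues, ("query", fam))

        partners = sorted(cfg.partner_map.get(fam, ()))
        planted: dict[int, int] = {}
        for p, offset in zip(partners, cfg.offset_cycle):
            ordinal = R + offset
            if ordinal in slots or not 0 <= ordinal <= 2 * R:
                raise ValueError(f"offset collision planting partner {p} at {offset:+d}")
            member = mutate(truth.partner_ancestors[p], cfg.p_within, rng)
            pid = alloc.next()
            slots[ordinal] = (pid, member, ("partner", p))
            planted[offset] = p
        truth.planted[rec.seq_id] = planted

        guest_id = paired_guest.get(rec.seq_id)
        if guest_id is not None:
            if R + 1 in slots:
                raise ValueError("offset collision: +1 occupied, cannot place paired query")
            guest = rec_by_id[guest_id]
            gfam = truth.query_family[guest_id]
            slots[R + 1] = (guest_id, guest.residues, ("query", gfam))
            truth.replicon_of_query[guest_id] = replicon_id

        for ordinal in range(2 * R + 1):
            if ordinal in slots:
                continue
            if cfg.n_scatter_families and rng.random() < cfg.scatter_prob:
                s = int(rng.integers(0, cfg.n_scatter_families))
                member = mutate(truth.scatter_ancestors[s], cfg.p_within, rng)
                slots[ordinal] = (alloc.next(), member, ("scatter", s))
            else:
                slots[ordinal] = (alloc.next(), random_protein(cfg.length, rng),
                                  ("background", None))

        for ordinal in range(2 * R + 1):
            pid, residues, role = slots[ordinal]
            truth.role.setdefault(pid, role)
            start = 1 + ordinal * (3 * cfg.length + 100)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                GeneFeature(
                    protein_id=pid,
                    locus_tag=f"{replicon_id}_{ordinal:03d}",
                    replicon_id=replicon_id,
                    ordinal=ordinal,
                    strand=strand,
                    start=start,
                    end=start + 3 * len(residues) + 2,
                    product="hypothetical protein",
                    translation=residues,
                )
            )
    return GenomeSimulation(features=features, truth=truth, config=cfg)


def simulate(config: SimulationConfig) -> tuple[list[SequenceRecord], GenomeSimulation]:
    """Run both simulation stages under one seeded RNG stream."""
    records, truth, rng, alloc = simulate_superfamily(config)
    sim = simulate_genomes(records, truth, config, rng, alloc)
    return records, sim


def expected_partner_colors(
    truth: GroundTruth, membership: dict[str, int]
) -> dict[int, frozenset[int]]:
    """The planted color set of each partner family, expressed in SSN
    cluster numbers: the clusters of the query families it was planted with.
    Family -> cluster is resolved by majority vote over members."""
    from collections import Counter

    fam_cluster: dict[int, int] = {}
    families = {f for fs in (truth.query_family.values(),) for f in fs}
    for fam in sorted(families):
        votes = Counter(membership[q] for q in truth.family_members(fam))
        fam_cluster[fam] = votes.most_common(1)[0][0]
    out: dict[int, set[int]] = {}
    for fam, partners in truth.partner_map.items():
        for p in partners:
            out.setdefault(p, set()).add(fam_cluster[fam])
    return {p: frozenset(cs) for p, cs in out.items()}
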