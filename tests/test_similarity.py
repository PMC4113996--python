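import math
import random

import pytest

from gnnkit import (
    ScoringModel,
    all_by_all,
    evalue_of,
    local_align,
    merge_reciprocal,
    parse_blast_tabular,
)
from gnnkit.seqio import SequenceRecord
from gnnkit.similarity import PairwiseHit

from oracles import group_min_evalue, sw_score_oracle


def rec(seq_id, residues):
    return SequenceRecord(seq_id, residues)


class TestLocalAlign:
    def test_self_alignment_scores_blosum62_diagonal(self):
        # M=5, K=5, V=4, L=4, W=11 on the BLOSUM62 diagonal -> 29
        raw, pident, aln_len = local_align(rec("a", "MKVLW"), rec("b", "MKVLW"))
        assert (raw, pident, aln_len) == (29, 100.0, 5)

    def test_all_negative_pairs_have_no_local_alignment(self):
        raw, pident, aln_len = local_align(rec("a", "AAAA"), rec("b", "WWWW"))
        assert (raw, pident, aln_len) == (0, 0.0, 0)

    def test_matches_exhaustive_dp_oracle_on_random_pairs(self):
        rng = random.Random(7)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            a = "".join(rng.choice(aas) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(aas) for _ in range(rng.randint(1, 12)))
            raw, _, _ = local_align(rec("a", a), rec("b", b))
            assert raw == sw_score_oracle(a, b), (a, b)


class TestEvalueOf:
    def test_zero_bits_gives_search_space_size(self):
        scoring = ScoringModel(db_residues=10**6)
        s_zero = math.log(scoring.K) / scoring.lam  # bit score exactly 0
        bit, evalue = evalue_of(s_zero, 300, scoring)
        assert bit == pytest.approx(0.0, abs=1e-12)
        assert evalue == pytest.approx(300 * 10**6)

    def test_frozen_regression_value(self):
        # computed once with an independent calculator for
        # lambda=0.267, K=0.041, S=200, m=300, n=1e6
        bit, evalue = evalue_of(200, 300, ScoringModel(db_residues=10**6))
        assert bit == pytest.approx(81.64814746351466, rel=1e-12)
        assert evalue == pytest.approx(7.917348791530573e-17, rel=1e-10)

    def test_linear_in_database_size(self):
        small = ScoringModel(db_residues=10**6)
        double = ScoringModel(db_residues=2 * 10**6)
        _, e1 = evalue_of(150, 250, small)
        _, e2 = evalue_of(150, 250, double)
        assert e2 == pytest.approx(2 * e1)

    def test_strictly_decreasing_in_score(self):
        scoring = ScoringModel(db_residues=10**5)
        evalues = [evalue_of(s, 200, scoring)[1] for s in range(10, 400, 7)]
        assert all(a > b for a, b in zip(evalues, evalues[1:]))

    def test_extreme_scores_underflow_to_zero(self):
        _, evalue = evalue_of(10_000, 300, ScoringModel(db_residues=10**6))
        assert evalue == 0.0


class TestAllByAll:
    def test_identical_pair_gives_one_full_identity_hit(self):
        hits = all_by_all([rec("A", "MKVLWCH" * 10), rec("B", "MKVLWCH" * 10)],
                          max_evalue=10.0)
        assert len(hits) == 1
        assert hits[0].pct_identity == 100.0
        assert {hits[0].query_id, hits[0].subject_id} == {"A", "B"}

    def test_unrelated_sequences_rarely_hit_at_stringent_cutoff(self):
        total_pairs = 0
        total_hits = 0
        for seed in range(10):
            rng = random.Random(seed)
            records = [
                rec(f"S{i}", "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                                     for _ in range(100)))
                for i in range(8)
            ]
            hits = all_by_all(records, max_evalue=1e-20)
            total_hits += len(hits)
            total_pairs += 28
        assert total_hits <= 0.01 * total_pairs

    def test_consistent_with_pairwise_oracle(self):
        records = [rec("A", "MKVLWCHDE" * 5), rec("B", "MKVLWCHDE" * 5),
                   rec("C", "MKILWCHDD" * 5)]
        hits = all_by_all(records, max_evalue=10.0)
        n = sum(r.length for r in records)
        scoring = ScoringModel(db_residues=n)
        for h in hits:
            a = next(r for r in records if r.seq_id == h.query_id)
            b = next(r for r in records if r.seq_id == h.subject_id)
            assert h.raw_score == sw_score_oracle(a.residues, b.residues)
            assert h.bit_score == pytest.approx(
                evalue_of(h.raw_score, a.length, scoring)[0])

    def test_edges_invariant_under_input_permutation(self):
        rng = random.Random(1)
        records = [rec(f"S{i}", "MKVLWCHDE" * 4) for i in range(3)] + [
            rec(f"T{i}", "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY")
                                 for _ in range(40))) for i in range(3)
        ]
        edges_fwd = merge_reciprocal(all_by_all(records, max_evalue=10.0))
        shuffled = records[::-1]
        edges_rev = merge_reciprocal(all_by_all(shuffled, max_evalue=10.0))
        assert edges_fwd == edges_rev


BLAST_ROW = "A\tB\t97.5\t200\t5\t0\t1\t200\t1\t200\t1e-120\t430\n"


class TestParseBlastTabular:
    def test_row_parsing(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(BLAST_ROW)
        (hit,) = parse_blast_tabular(path)
        assert hit == PairwiseHit(
            query_id="A", subject_id="B", bit_score=430.0, evalue=1e-120,
            pct_identity=97.5, aln_length=200,
        )

    def test_self_rows_dropped(self, tmp_path):
        path = tmp_path / "hits.tsv"
        rows = [BLAST_ROW] * 4
        rows += [BLAST_ROW.replace("A\tB", "X\tX")] * 2
        rows += [BLAST_ROW.replace("A\tB", "C\tD")] * 4
        path.write_text("".join(rows))
        assert len(parse_blast_tabular(path)) == 8

    def test_zero_evalue_kept_as_zero(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(BLAST_ROW.replace("1e-120", "0.0"))
        assert parse_blast_tabular(path)[0].evalue == 0.0

    def test_wrong_column_count_reports_line(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(BLAST_ROW + "A\tB\tbroken\n")
        with pytest.raises(ValueError, match=":2"):
            parse_blast_tabular(path)

    def test_unparseable_numeric_is_an_error(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(BLAST_ROW.replace("97.5", "NA?"))
        with pytest.raises(ValueError, match="unparseable"):
            parse_blast_tabular(path)


def hit(q, s, evalue, bit=100.0):
    return PairwiseHit(query_id=q, subject_id=s, bit_score=bit, evalue=evalue,
                       pct_identity=50.0, aln_length=100)


class TestMergeReciprocal:
    def test_minimum_evalue_wins(self):
        edges = merge_reciprocal([hit("A", "B", 1e-60), hit("B", "A", 1e-58)])
        assert len(edges) == 1
        assert edges[0].evalue == 1e-60
        assert (edges[0].id_a, edges[0].id_b) == ("A", "B")

    def test_single_direction_hit_is_retained(self):
        edges = merge_reciprocal([hit("B", "A", 1e-30)])
        assert len(edges) == 1 and edges[0].evalue == 1e-30

    def test_tie_prefers_higher_bit_score(self):
        edges = merge_reciprocal([hit("A", "B", 1e-50, bit=100),
                                  hit("B", "A", 1e-50, bit=200)])
        assert edges[0].bit_score == 200

    def test_matches_group_by_min_oracle_on_random_multiset(self):
        rng = random.Random(13)
        ids = [f"N{i}" for i in range(8)]
        hits = []
        for _ in range(200):
            q, s = rng.sample(ids, 2)
            hits.append(hit(q, s, 10.0 ** (-rng.randint(1, 80)),
                            bit=rng.randint(20, 500)))
        edges = merge_reciprocal(hits)
        oracle = group_min_evalue(hits)
        assert len(edges) == len(oracle)
        for edge in edges:
            best = oracle[frozenset((edge.id_a, edge.id_b))]
            assert edge.evalue == best.evalue
            assert edge.bit_score == best.bit_score
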