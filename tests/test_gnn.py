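import pytest

from gnnkit import (
    BACKGROUND,
    SIGNAL,
    SINGLETON,
    classify_clusters,
    collect_neighbors,
    composition,
    expected_partner_colors,
    map_back,
)
from gnnkit.genomes import GeneFeature, Neighborhood
from gnnkit.gnn import CompositionRow, GnnCluster
from gnnkit.ssn import ClusterAssignment


def feature(pid, replicon="repA", ordinal=0, translation="MKVLWCH"):
    return GeneFeature(
        protein_id=pid, locus_tag=pid, replicon_id=replicon, ordinal=ordinal,
        strand="+", start=1 + 500 * ordinal, end=500 * ordinal + 24,
        translation=translation,
    )


def assignment_of(memberships: dict[str, int]) -> ClusterAssignment:
    clusters: dict[int, set] = {}
    for node, num in memberships.items():
        if num != SINGLETON:
            clusters.setdefault(num, set()).add(node)
    ordered = [frozenset(clusters[n]) for n in sorted(clusters)]
    return ClusterAssignment(
        threshold=1e-20,
        clusters=ordered,
        singletons=frozenset(n for n, c in memberships.items() if c == SINGLETON),
        membership=dict(memberships),
        cluster_colors={n: f"color{n}" for n in clusters},
        cluster_sizes={n: len(m) for n, m in clusters.items()},
        numbered=True,
    )


def nbh(query, neighbor_pids, replicon="repA"):
    neighbors = [(i + 1, feature(p, replicon, ordinal=i + 1))
                 for i, p in enumerate(neighbor_pids)]
    return Neighborhood(query_protein_id=query, replicon_id=replicon,
                        neighbors=neighbors)


class TestCollectNeighbors:
    def test_single_query_collects_single_colored_records(self):
        qa = assignment_of({"Q1": 1, "Q2": 1})
        records, colors = collect_neighbors([nbh("Q1", ["N1", "N2", "N3", "N4"])], qa)
        assert len(records) == 4
        assert all(colors[r.seq_id] == {(1, "Q1")} for r in records)

    def test_shared_neighbor_holds_both_colors(self):
        qa = assignment_of({"Q1": 1, "Q3": 3})
        nbhs = [nbh("Q1", ["Nshared"], "repA"), nbh("Q3", ["Nshared"], "repB")]
        records, colors = collect_neighbors(nbhs, qa)
        assert len(records) == 1  # deduplicated by protein id
        assert {c for c, _q in colors["Nshared"]} == {1, 3}

    def test_unknown_query_is_an_error(self):
        qa = assignment_of({"Q1": 1})
        with pytest.raises(KeyError, match="Q9"):
            collect_neighbors([nbh("Q9", ["N1"])], qa)

    def test_singleton_queries_use_reserved_color(self):
        qa = assignment_of({"Qs": SINGLETON})
        _, colors = collect_neighbors([nbh("Qs", ["N1"])], qa)
        assert colors["N1"] == {(SINGLETON, "Qs")}

    def test_adjacent_query_family_members_collect_each_other(self, adjacent_run):
        colors = adjacent_run.gnn.colors
        truth = adjacent_run.sim.truth
        queries = set(truth.query_family)
        collected = {pid for pid in colors if pid in queries}
        # every query member was collected by its partner query ...
        assert collected == queries
        for pid in collected:
            collecting_queries = {q for _c, q in colors[pid]}
            # ... and never by itself
            assert pid not in collecting_queries
            assert len(collecting_queries) == 1

    def test_query_family_forms_own_gnn_cluster(self, adjacent_run):
        truth = adjacent_run.sim.truth
        fam0 = frozenset(truth.family_members(0))
        fam1 = frozenset(truth.family_members(1))
        member_sets = {c.members for c in adjacent_run.gnn.clusters}
        assert fam0 in member_sets and fam1 in member_sets


class TestComposition:
    def test_counts_and_coverage_arithmetic(self):
        qa = assignment_of({f"Q{i}": 3 for i in range(10)})
        colors = {f"N{i}": {(3, f"Q{i}")} for i in range(8)}
        rows = composition([f"N{i}" for i in range(8)], colors, qa)
        assert set(rows) == {3}
        assert rows[3].node_count == 8
        assert rows[3].distinct_query_count == 8
        assert rows[3].query_coverage == pytest.approx(0.8)

    def test_multicolor_nodes_count_once_per_color(self):
        qa = assignment_of({"Qa": 1, "Qb": 2})
        colors = {"N1": {(1, "Qa"), (2, "Qb")}}
        rows = composition(["N1"], colors, qa)
        assert rows[1].node_count == 1 and rows[2].node_count == 1

    def test_matches_independent_tally_on_pipeline_run(self, small_run):
        qa = small_run.assignment
        colors = small_run.gnn.colors
        for cluster in small_run.gnn.clusters:
            # independent recount straight from the neighborhood lists
            node_count: dict[int, set] = {}
            queries: dict[int, set] = {}
            for nbh_ in small_run.neighborhoods:
                c = qa.membership[nbh_.query_protein_id]
                for _off, feat in nbh_.neighbors:
                    if feat.protein_id in cluster.members:
                        node_count.setdefault(c, set()).add(feat.protein_id)
                        queries.setdefault(c, set()).add(nbh_.query_protein_id)
            assert set(cluster.composition) == set(node_count)
            for c, row in cluster.composition.items():
                assert row.node_count == len(node_count[c])
                assert row.distinct_query_count == len(queries[c])
                assert row.query_coverage == pytest.approx(
                    len(queries[c]) / qa.cluster_sizes[c])


def make_cluster(number, size, coverages):
    comp = {
        color: CompositionRow(color=color, node_count=size,
                              distinct_query_count=1, query_coverage=cov)
        for color, cov in coverages.items()
    }
    return GnnCluster(number=number, members=frozenset(f"M{number}_{i}" for i in range(size)),
                      composition=comp)


class TestClassifyClusters:
    def test_small_multicolor_cluster_is_background(self):
        cluster = make_cluster(1, 2, {1: 0.05, 2: 0.05})
        classify_clusters([cluster])
        assert cluster.flag == BACKGROUND

    def test_large_covered_cluster_is_signal(self):
        cluster = make_cluster(1, 40, {3: 0.9})
        classify_clusters([cluster])
        assert cluster.flag == SIGNAL

    def test_singleton_color_never_confers_signal(self):
        cluster = make_cluster(1, 10, {SINGLETON: 1.0})
        classify_clusters([cluster])
        assert cluster.flag == BACKGROUND

    def test_thresholds_are_configurable(self):
        cluster = make_cluster(1, 2, {1: 0.4})
        classify_clusters([cluster], min_size=2, min_coverage=0.3)
        assert cluster.flag == SIGNAL

    def test_planted_partners_signal_on_pipeline_run(self, small_run):
        truth = small_run.sim.truth
        for cluster in small_run.gnn.clusters:
            roles = {truth.role[m][0] for m in cluster.members}
            if roles == {"partner"}:
                assert cluster.flag == SIGNAL


class TestMapBack:
    def test_single_query_cluster(self):
        qa = assignment_of({"Q1": 1})
        colors = {"N1": {(1, "Q1")}, "N2": {(1, "Q1")}}
        cluster = GnnCluster(number=1, members=frozenset({"N1", "N2"}))
        result = map_back(cluster, None, colors, qa)
        assert result.queries_by_ssn_cluster == {1: frozenset({"Q1"})}

    def test_unknown_cluster_number_is_an_error(self):
        qa = assignment_of({"Q1": 1})
        with pytest.raises(KeyError):
            map_back(99, [], {}, qa)

    def test_planted_truth_recovered(self, small_run):
        truth = small_run.sim.truth
        qa = small_run.assignment
        for cluster in small_run.gnn.clusters:
            roles = {truth.role[m] for m in cluster.members}
            if {r for r, _i in roles} != {"partner"}:
                continue
            (_, partner_idx), = roles
            result = map_back(cluster, None, small_run.gnn.colors, qa)
            expected = {
                q for q, fam in truth.query_family.items()
                if partner_idx in truth.partner_map[fam]
            }
            assert result.query_ids == frozenset(expected)

    def test_colors_agree_with_composition(self, small_run):
        for cluster in small_run.gnn.clusters:
            result = map_back(cluster, None, small_run.gnn.colors,
                              small_run.assignment)
            assert result.colors == cluster.colors


class TestConservation:
    def test_colorbag_events_equal_collection_events(self, small_run):
        events = sum(len(n.neighbors) for n in small_run.neighborhoods)
        bag_total = sum(len(v) for v in small_run.gnn.colors.values())
        assert bag_total == events

    def test_no_query_appears_in_its_own_neighborhood(self, small_run):
        for nbh_ in small_run.neighborhoods:
            assert nbh_.query_protein_id not in {
                f.protein_id for _off, f in nbh_.neighbors
            }
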