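"""Shortest-path distances, drug distances, and the effect radius."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cocktailnet as ck
from cocktailnet import UNREACHABLE
from cocktailnet.effect_radius import radius_distribution, write_radius_table


def floyd_warshall_oracle(graph):
    """Independent min-plus matrix oracle for unweighted all-pairs distances."""
    nodes = sorted(graph.nodes())
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in graph.edges():
        dist[index[u], index[v]] = 1.0
        dist[index[v], index[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    return nodes, dist


def _drug(did, targets):
    return ck.DrugRecord(did, set(targets), {"A01AA01"})


class TestDistanceIndex:
    def test_path_graph_distances(self):
        net = nx.path_graph(["g1", "g2", "g3"])
        index = ck.DistanceIndex(net)
        assert ck.shortest_path_distance(index, "g1", "g3") == 2
        assert ck.shortest_path_distance(index, "g1", "g2") == 1

    def test_identity_distance_is_zero_even_off_network(self):
        index = ck.DistanceIndex(nx.Graph())
        assert index.distance("ghost", "ghost") == 0

    def test_absent_gene_unreachable(self):
        net = nx.path_graph(["g1", "g2"])
        index = ck.DistanceIndex(net)
        assert index.distance("g1", "ghost") == UNREACHABLE

    def test_cross_component_unreachable(self):
        net = nx.Graph([("a", "b"), ("c", "d")])
        assert ck.DistanceIndex(net).distance("a", "d") == UNREACHABLE

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        net = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(2**31)))
        net = nx.relabel_nodes(net, lambda i: f"g{i}")
        index = ck.DistanceIndex(net)
        nodes, dist = floyd_warshall_oracle(net)
        for i, a in enumerate(nodes):
            for j, b in enumerate(nodes):
                expected = dist[i, j] if math.isfinite(dist[i, j]) else UNREACHABLE
                assert index.distance(a, b) == expected


class TestDrugDistance:
    def test_single_target_pair(self):
        net = nx.path_graph(["g1", "g2", "g3"])
        index = ck.DistanceIndex(net)
        assert ck.drug_distance(index, _drug("i", {"g1"}), _drug("j", {"g3"})) == 2

    def test_shared_target_gives_zero(self):
        index = ck.DistanceIndex(nx.Graph())
        assert ck.drug_distance(index, _drug("i", {"g1"}), _drug("j", {"g1", "g9"})) == 0

    def test_min_over_pairs_matches_enumeration(self):
        net = nx.gnp_random_graph(10, 0.25, seed=4)
        net = nx.relabel_nodes(net, lambda i: f"g{i}")
        index = ck.DistanceIndex(net)
        a, b = _drug("i", {"g1", "g9"}), _drug("j", {"g3", "g4"})
        expected = min(
            index.distance(ti, tj) for ti in a.targets for tj in b.targets
        )
        assert ck.drug_distance(index, a, b) == expected
        # symmetry and the upper bound by any single pair
        assert ck.drug_distance(index, b, a) == expected
        for ti in a.targets:
            for tj in b.targets:
                assert ck.drug_distance(index, a, b) <= index.distance(ti, tj)

    def test_empty_targets_hard_error(self):
        index = ck.DistanceIndex(nx.Graph())
        with pytest.raises(ValueError):
            ck.drug_distance(index, ck.DrugRecord("i", set(), {"A"}), _drug("j", {"g"}))

    def test_adding_edge_never_increases_distance(self):
        rng = np.random.default_rng(12)
        base = nx.gnp_random_graph(15, 0.12, seed=7)
        base = nx.relabel_nodes(base, lambda i: f"g{i}")
        a, b = _drug("i", {"g1", "g5"}), _drug("j", {"g8", "g13"})
        before = ck.drug_distance(ck.DistanceIndex(base), a, b)
        for _ in range(10):
            u, v = rng.choice([f"g{k}" for k in range(15)], 2, replace=False)
            grown = base.copy()
            grown.add_edge(u, v)
            after = ck.drug_distance(ck.DistanceIndex(grown), a, b)
            assert after <= before


class TestEffectRadius:
    def _lookup(self, *drugs):
        return {d.drug_id: d for d in drugs}

    def test_two_drug_combo_single_pair_mean(self):
        net = nx.path_graph(["g1", "g2", "g3"])
        index = ck.DistanceIndex(net)
        combo = ck.CombinationRecord("c", frozenset({"i", "j"}))
        res = ck.effect_radius(
            index, combo, self._lookup(_drug("i", {"g1"}), _drug("j", {"g3"}))
        )
        assert res.radius == 2 and res.n_pairs_used == 1 and res.n_pairs_unreachable == 0

    def test_unreachable_pairs_excluded_from_mean(self):
        """Pairwise distances {1, 3, UNREACHABLE} -> R = 2 over the 2 used pairs."""
        # component a-b-m-c gives d(a,b)=1 and d(a,c)=3; target x is isolated,
        # so the d2-d3 pair (b vs x) is unreachable.
        net = nx.Graph([("a", "b"), ("b", "m"), ("m", "c"), ("x", "y")])
        index = ck.DistanceIndex(net)
        drugs = self._lookup(
            ck.DrugRecord("d1", {"a"}, {"A"}),
            ck.DrugRecord("d2", {"b"}, {"A"}),
            ck.DrugRecord("d3", {"x"}, {"A"}),
        )
        combo = ck.CombinationRecord("c", frozenset({"d1", "d2", "d3"}))
        assert ck.drug_distance(index, drugs["d1"], drugs["d2"]) == 1
        assert ck.drug_distance(index, drugs["d1"], drugs["d3"]) == UNREACHABLE
        # rebuild d1 with targets {a, c}: d1-d2 = 1, d1-d3 stays unreachable
        drugs["d1"].targets = {"c"}
        assert ck.drug_distance(index, drugs["d1"], drugs["d2"]) == 2
        drugs["d1"].targets = {"a"}
        drugs["d3"].targets = {"c"}  # now d1-d3 = 3, d2-d3 = 2
        res = ck.effect_radius(index, combo, drugs)
        assert res.radius == pytest.approx(2.0)  # mean of {1, 3, 2}
        assert res.n_pairs_used == 3 and res.n_pairs_unreachable == 0
        drugs["d3"].targets = {"x"}  # d1-d3 and d2-d3 both unreachable
        res = ck.effect_radius(index, combo, drugs)
        assert res.radius == pytest.approx(1.0)
        assert res.n_pairs_used == 1 and res.n_pairs_unreachable == 2

    def test_all_sharing_one_target_gives_zero(self):
        index = ck.DistanceIndex(nx.Graph())
        drugs = self._lookup(
            _drug("d1", {"g"}), _drug("d2", {"g"}), _drug("d3", {"g"})
        )
        combo = ck.CombinationRecord("c", frozenset({"d1", "d2", "d3"}))
        assert ck.effect_radius(index, combo, drugs).radius == 0

    def test_all_unreachable_is_undefined(self):
        net = nx.Graph([("a", "b")])
        index = ck.DistanceIndex(net)
        drugs = self._lookup(_drug("d1", {"a"}), _drug("d2", {"zz"}))
        res = ck.effect_radius(
            index, ck.CombinationRecord("c", frozenset({"d1", "d2"})), drugs
        )
        assert res.radius is None and not res.defined


class TestDistributionAndStrata:
    def _results(self, radii):
        return [
            ck.RadiusResult(f"c{i}", r, 1 if r is not None else 0, 0)
            for i, r in enumerate(radii)
        ]

    def test_split_at_three(self):
        hist = radius_distribution(self._results([1, 2, 2, 5]), [3])
        assert hist == {"<=3": 0.75, ">3": 0.25}

    def test_single_result_degenerate(self):
        hist = radius_distribution(self._results([2]), [3])
        assert hist == {"<=3": 1.0, ">3": 0.0}

    def test_proportions_sum_to_one(self):
        hist = radius_distribution(self._results([0, 1, 2, 3, 4, 7]), [1, 3, 5])
        assert sum(hist.values()) == pytest.approx(1.0)

    def test_all_undefined_is_error(self):
        with pytest.raises(ValueError):
            radius_distribution(self._results([None, None]), [3])

    def test_stratum_boundary_inclusive(self):
        small, large = ck.stratify_by_radius(self._results([3, 3.0001]), 3)
        assert small == {"c0"} and large == {"c1"}

    def test_all_equal_threshold_in_left_stratum(self):
        small, large = ck.stratify_by_radius(self._results([3, 3, 3]), 3)
        assert len(small) == 3 and not large

    def test_partition_counts(self):
        small, large = ck.stratify_by_radius(self._results([0, 1, 2, 4, 5]), 3)
        assert (len(small), len(large)) == (3, 2)

    def test_radius_table_written(self, tmp_path):
        write_radius_table(self._results([1.5, None]), tmp_path / "r.tsv")
        text = (tmp_path / "r.tsv").read_text()
        assert "NA" in text and "1.5" in text
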