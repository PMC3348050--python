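"""Rank-sum test correctness and the descriptive category tallies."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import cocktailnet as ck
from cocktailnet import PathwayPairRelation as R
from cocktailnet.stats_compare import write_comparisons, write_tally


def brute_force_rank_sum(x, y, alternative):
    """Independent oracle: enumerate every assignment of pooled values to the
    first group and compare the resulting rank sums directly."""
    pooled = list(x) + list(y)
    ranks = scipy.stats.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    n_le = n_ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        total += 1
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    p_le, p_ge = n_le / total, n_ge / total
    if alternative == "real_less":
        return p_le
    if alternative == "real_greater":
        return p_ge
    return min(1.0, 2 * min(p_le, p_ge))


class TestRankSumExact:
    def test_textbook_example(self):
        """x={1,2} vs y={3,4}: the most extreme of C(4,2)=6 splits, doubled."""
        res = ck.rank_sum_test([1, 2], [3, 4], "two_sided")
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"
        assert ck.rank_sum_test([1, 2], [3, 4], "real_less").p_value == pytest.approx(1 / 6)

    def test_identical_samples_two_sided_p_one(self):
        res = ck.rank_sum_test([1.0, 2.0, 3.0], [1.5, 2.5, 3.5], "two_sided")
        assert res.p_value >= 0.5
        res = ck.rank_sum_test([5.0, 5.0], [5.0, 5.0], "two_sided")
        assert res.p_value == 1.0 and res.method == "degenerate"

    def test_degenerate_warns(self, caplog):
        ck.rank_sum_test([2.0, 2.0], [2.0], "two_sided")
        assert any("degenerate" in rec.message for rec in caplog.records)

    @pytest.mark.parametrize("alternative", ["two_sided", "real_less", "real_greater"])
    def test_matches_brute_force_enumeration(self, alternative):
        rng = np.random.default_rng(7)
        for n, m in [(1, 2), (2, 2), (3, 2), (3, 3), (4, 4), (2, 6)]:
            values = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = values[:n], values[n:]
            ours = ck.rank_sum_test(x, y, alternative).p_value
            assert ours == pytest.approx(brute_force_rank_sum(x, y, alternative))

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(11)
        for n, m in [(3, 4), (5, 5), (4, 6)]:
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            ours = ck.rank_sum_test(x, y, "two_sided").p_value
            ref = scipy.stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert ours == pytest.approx(float(ref))

    def test_one_sided_antisymmetry_under_swap(self):
        x, y = [1.0, 4.0, 5.0], [2.0, 3.0, 6.0]
        p_less = ck.rank_sum_test(x, y, "real_less").p_value
        p_greater = ck.rank_sum_test(y, x, "real_greater").p_value
        assert p_less == pytest.approx(p_greater)

    @given(
        x=st.lists(st.integers(0, 50), min_size=2, max_size=5),
        y=st.lists(st.integers(51, 100), min_size=2, max_size=5),
        shift=st.integers(-5, 5),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariances(self, x, y, shift):
        x = [float(v) for v in x]
        y = [float(v) + 0.5 for v in y]
        two = ck.rank_sum_test(x, y, "two_sided").p_value
        less = ck.rank_sum_test(x, y, "real_less").p_value
        greater = ck.rank_sum_test(x, y, "real_greater").p_value
        # the two-sided p doubles the smaller tail (capped at 1)
        assert two >= min(less, greater) - 1e-12
        assert two <= 2 * min(less, greater) + 1e-12
        shifted = ck.rank_sum_test(
            [v + shift for v in x], [v + shift for v in y], "two_sided"
        ).p_value
        assert shifted == pytest.approx(two)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ck.rank_sum_test([], [1.0], "two_sided")


class TestRankSumAsymptotic:
    def test_large_samples_use_asymptotic_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, size=40).astype(float)
        y = rng.integers(0, 5, size=40).astype(float)
        res = ck.rank_sum_test(x, y, "two_sided")
        assert res.method == "asymptotic"
        ref = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", use_continuity=True, method="asymptotic"
        ).pvalue
        assert res.p_value == pytest.approx(float(ref))

    def test_separated_samples_small_p(self):
        res = ck.rank_sum_test(
            np.arange(30.0), np.arange(100.0, 130.0), "real_less"
        )
        assert res.p_value < 1e-8


class TestComparisons:
    def _radius(self, cid, r):
        return ck.RadiusResult(cid, r, 1 if r is not None else 0, int(r is None))

    def test_compare_radius_pools_and_excludes_undefined(self):
        real = [self._radius("a", 1.0), self._radius("b", None)]
        null = [[self._radius("n1", 2.0)], [self._radius("n2", 3.0), self._radius("n3", None)]]
        res = ck.compare_radius(real, null, "real_less", "pooled")
        assert len(res.real_values) == 1 and len(res.null_values) == 2
        assert res.pooling == "pooled"

    def test_replicate_mean_pooling(self):
        real = [self._radius("a", 1.0)]
        null = [
            [self._radius("x", 2.0), self._radius("y", 4.0)],
            [self._radius("z", 6.0)],
        ]
        res = ck.compare_radius(real, null, "real_less", "replicate_mean")
        assert sorted(res.null_values) == [3.0, 6.0]

    def test_identical_distributions_give_large_p(self):
        vals = [float(v) for v in range(8)]
        real = [self._radius(f"r{i}", v) for i, v in enumerate(vals)]
        null = [[self._radius(f"n{i}", v) for i, v in enumerate(vals)]]
        res = ck.compare_radius(real, null, "two_sided")
        assert res.p_value > 0.5

    def test_compare_pathway_proportion_degenerate(self):
        prof = lambda cid, k: ck.PathwayProfile(cid, {R.INTERACTING: k, R.PARALLEL: 10 - k})
        real = [prof("a", 0), prof("b", 0)]
        null = [[prof("n", 0)]]
        res = ck.compare_pathway_proportion(real, null, R.INTERACTING)
        assert res.p_value == 1.0

    def test_compare_pathway_proportion_detects_shift(self):
        prof = lambda cid, k: ck.PathwayProfile(cid, {R.INTERACTING: k, R.PARALLEL: 10 - k})
        real = [prof(f"r{i}", 8) for i in range(6)]
        null = [[prof(f"n{i}", 2) for i in range(6)]]
        res = ck.compare_pathway_proportion(real, null, R.INTERACTING, "real_greater")
        assert res.p_value < 0.01


class TestTallies:
    def _world(self):
        drugs = {
            "d1": ck.DrugRecord("d1", {"g1"}, {"C01AA05"}),
            "d2": ck.DrugRecord("d2", {"g2", "g3"}, {"N05AH02"}),
            "d3": ck.DrugRecord("d3", {"g1"}, {"C07AB02", "L01XX01"}),
        }
        combos = {
            "c1": ck.CombinationRecord("c1", frozenset({"d1", "d2"}), "synergistic", "approved"),
            "c2": ck.CombinationRecord("c2", frozenset({"d1", "d3"}), "synergistic", "clinical"),
            "c3": ck.CombinationRecord("c3", frozenset({"d2", "d3"}), "additive", "approved"),
        }
        return drugs, combos

    def test_atc_level1_incidence_counting(self):
        drugs, combos = self._world()
        tally = ck.tally_categories({"c1"}, drugs, combos, "atc_level1")
        assert tally.counts == {"C": 1, "N": 1}

    def test_multi_class_drug_counts_in_both_classes(self):
        drugs, combos = self._world()
        tally = ck.tally_categories({"c2"}, drugs, combos, "atc_level1")
        # d1 -> C; d3 -> C and L
        assert tally.counts == {"C": 2, "L": 1}

    def test_drug_counts_once_per_combination_membership(self):
        drugs, combos = self._world()
        tally = ck.tally_categories({"c1", "c2"}, drugs, combos, "atc_level1")
        assert tally.counts["C"] == 3  # d1 twice (two combos) + d3 once

    def test_combo_type_proportions(self):
        drugs, combos = self._world()
        tally = ck.tally_categories(set(combos), drugs, combos, "combo_type")
        assert tally.counts == {"synergistic": 2, "additive": 1}
        assert tally.proportions["synergistic"] == pytest.approx(2 / 3)

    def test_target_function_uses_annotation_with_fallback(self):
        drugs, combos = self._world()
        tally = ck.tally_categories(
            {"c1"}, drugs, combos, "target_function", annotation={"g1": "GPCR"}
        )
        assert tally.counts == {"GPCR": 1, "unclassified": 2}
        with pytest.raises(ValueError):
            ck.tally_categories({"c1"}, drugs, combos, "target_function")

    def test_proportions_sum_to_one_and_order_invariant(self):
        drugs, combos = self._world()
        t1 = ck.tally_categories(["c1", "c2", "c3"], drugs, combos, "combo_type")
        t2 = ck.tally_categories(["c3", "c1", "c2"], drugs, combos, "combo_type")
        assert t1.counts == t2.counts
        assert sum(t1.proportions.values()) == pytest.approx(1.0)

    def test_serialization(self, tmp_path):
        drugs, combos = self._world()
        tally = ck.tally_categories({"c1"}, drugs, combos, "atc_level1")
        write_tally(tally, tmp_path / "t.tsv")
        assert "label\tcount\tproportion" in (tmp_path / "t.tsv").read_text()
        res = ck.rank_sum_test([1.0, 2.0], [3.0, 4.0])
        write_comparisons({"demo": res}, tmp_path / "c.json")
        assert "p_value" in (tmp_path / "c.json").read_text()
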