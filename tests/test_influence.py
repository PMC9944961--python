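"""Influence descriptives: tie partition, ego categories, thresholds, test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from normnet.data import TwoWaveNetwork
from normnet.influence import (
    EGO_CATEGORIES,
    baseline_threshold_table,
    categorize_ego,
    friend_change_profile,
    partition_ties,
    transition_intervention_chisq,
)


def assignments_frame(rows):
    return pd.DataFrame(
        rows, columns=["school", "student", "side_t0", "side_t1"]
    ).assign(
        transition_category=lambda d: [
            categorize_ego(a, b) for a, b in zip(d["side_t0"], d["side_t1"])
        ]
    )


class TestPartition:
    def test_identical_waves_all_persisting(self):
        net = TwoWaveNetwork(("a", "b", "c"), {("a", "b")}, {("a", "b")})
        p = partition_ties(net)
        assert p.persisting == {("a", "b")} and not p.new and not p.dropped

    def test_disjoint_waves_no_persisting(self):
        net = TwoWaveNetwork(("a", "b", "c"), {("a", "b")}, {("b", "c")})
        p = partition_ties(net)
        assert not p.persisting and p.new == {("b", "c")} and p.dropped == {("a", "b")}

    def test_hand_tally_and_partition_property(self):
        t0 = {("a", "b"), ("a", "c"), ("b", "c"), ("c", "a")}
        t1 = {("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")}
        net = TwoWaveNetwork(("a", "b", "c", "d"), t0, t1)
        p = partition_ties(net)
        assert (len(p.persisting), len(p.new), len(p.dropped)) == (2, 2, 2)
        sets = [p.persisting, p.new, p.dropped]
        for s1, s2 in itertools.combinations(sets, 2):
            assert not (s1 & s2)
        assert p.persisting | p.new | p.dropped == t0 | t1


class TestCategorize:
    def test_exhaustive_four_outputs(self):
        outputs = {
            categorize_ego(a, b)
            for a in ("favorable", "against") for b in ("favorable", "against")
        }
        assert outputs == set(EGO_CATEGORIES)

    @pytest.mark.parametrize(
        "s0, s1, expected",
        [
            ("against", "against", "maintain-against"),
            ("favorable", "against", "change-to-against"),
            ("against", "favorable", "change-to-favorable"),
            ("favorable", "favorable", "maintain-favorable"),
        ],
    )
    def test_mapping(self, s0, s1, expected):
        assert categorize_ego(s0, s1) == expected

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            categorize_ego("against", "maybe")


class TestFriendChangeProfile:
    def test_homogeneous_population(self):
        rows = [("s", x, "against", "against") for x in "abcd"]
        a = assignments_frame(rows)
        net = TwoWaveNetwork(
            tuple("abcd"), {("a", "b"), ("c", "d")}, {("a", "b"), ("b", "c")},
            school="s",
        )
        prof = friend_change_profile(a, [net])
        ma = prof[prof["friend_category"] == "maintain-against"]
        assert (ma["proportion"] == 1.0).all()

    def test_hand_built_example(self):
        # 5 students, 8 distinct ties; among maintain-against egos only 'a'
        # has persisting out-ties: b (maintain-against), c (change-to-favorable)
        rows = [
            ("s", "a", "against", "against"),
            ("s", "b", "against", "against"),
            ("s", "c", "against", "favorable"),
            ("s", "d", "favorable", "favorable"),
            ("s", "e", "favorable", "against"),
        ]
        a = assignments_frame(rows)
        t0 = {("a", "b"), ("a", "c"), ("d", "e"), ("b", "c"), ("e", "a")}
        t1 = {("a", "b"), ("a", "c"), ("d", "e"), ("c", "d"), ("e", "b")}
        net = TwoWaveNetwork(tuple("abcde"), t0, t1, school="s")
        prof = friend_change_profile(a, [net])
        row = prof[
            (prof["ego_category"] == "maintain-against")
            & (prof["tie_class"] == "persisting")
            & (prof["friend_category"] == "maintain-against")
        ]
        # ego a's persisting friends: b and c -> 1/2 maintain-against
        assert row["proportion"].iloc[0] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, true_assignments, small_tables):
        _, networks = small_tables
        prof = friend_change_profile(true_assignments, networks)
        sums = prof.groupby(["ego_category", "tie_class", "setting", "intervention"])[
            "proportion"
        ].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestThreshold:
    def test_simple_share(self):
        rows = [
            ("s", "a", "against", "against"),
            ("s", "b", "favorable", "favorable"),
            ("s", "c", "against", "against"),
            ("s", "d", "against", "against"),
            ("s", "e", "against", "against"),
        ]
        a = assignments_frame(rows)
        t0 = {("a", "b"), ("a", "c"), ("a", "d"), ("a", "e")}
        net = TwoWaveNetwork(tuple("abcde"), t0, t0, school="s")
        table = baseline_threshold_table(a, [net]).set_index("ego_category")
        assert table.loc["maintain-against", "mean_favorable_share"] == pytest.approx(
            0.25
        )

    def test_all_against_population(self):
        rows = [("s", x, "against", "against") for x in "abc"]
        a = assignments_frame(rows)
        net = TwoWaveNetwork(tuple("abc"), {("a", "b"), ("b", "c")}, set(), school="s")
        table = baseline_threshold_table(a, [net])
        shares = table["mean_favorable_share"].dropna()
        assert (shares == 0.0).all()

    def test_planted_influence_ordering(self, true_assignments, small_tables):
        # favorable-side ego categories see more favorable baseline friends
        _, networks = small_tables
        table = baseline_threshold_table(true_assignments, networks).set_index(
            "ego_category"
        )["mean_favorable_share"]
        assert table["maintain-favorable"] > table["maintain-against"]
        assert table["change-to-favorable"] > table["maintain-against"]


class TestChiSquare:
    def _frame(self, counts):
        # counts: {(changed, arm): n} among at-risk egos
        rows = []
        i = 0
        for (changed, arm), n in counts.items():
            for _ in range(n):
                rows.append(
                    {
                        "school": arm, "student": f"x{i}",
                        "side_t0": "favorable",
                        "side_t1": "against" if changed else "favorable",
                    }
                )
                i += 1
        a = pd.DataFrame(rows)
        attrs = a[["school", "student"]].assign(intervention=a["school"])
        return a, attrs

    def test_perfect_independence_zero(self):
        a, attrs = self._frame(
            {(True, "p"): 10, (False, "p"): 10, (True, "t"): 10, (False, "t"): 10}
        )
        stat, dof, p, _ = transition_intervention_chisq(a, attrs)
        assert stat == pytest.approx(0.0) and dof == 1 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        a, attrs = self._frame(
            {(True, "p"): 30, (False, "p"): 10, (True, "t"): 10, (False, "t"): 30}
        )
        stat, dof, p, _ = transition_intervention_chisq(a, attrs)
        # n(ad - bc)^2 / (row and column products) = 80*(900-100)^2/40^4
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_no_at_risk_rejected(self):
        a = pd.DataFrame(
            [{"school": "p", "student": "a", "side_t0": "against",
              "side_t1": "against"}]
        )
        attrs = a[["school", "student"]].assign(intervention="p")
        with pytest.raises(ValueError, match="at-risk"):
            transition_intervention_chisq(a, attrs)
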