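"""STERGM: pair construction, change statistics, MPLE, simulator."""

import itertools

import numpy as np
import pytest
import statsmodels.api as sm

from normnet.data import TwoWaveNetwork
from normnet.stergm import (
    StergmSpec,
    build_pair,
    change_statistic,
    change_stats_matrix,
    mple_fit,
    network_statistics,
    simulate_stergm,
)
from normnet.synthetic import _sample_dyads


def random_adj(n, p, seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    return a


class TestBuildPair:
    def test_static_network(self):
        net = TwoWaveNetwork(("a", "b", "c"), {("a", "b")}, {("a", "b")})
        pair = build_pair(net)
        assert np.array_equal(pair.y_plus, pair.y_prev)
        assert np.array_equal(pair.y_minus, pair.y_prev)

    def test_full_turnover(self):
        net = TwoWaveNetwork(("a", "b", "c"), {("a", "b")}, {("b", "c")})
        pair = build_pair(net)
        assert pair.y_plus.sum() == 2 and pair.y_minus.sum() == 0

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        nodes = tuple(range(10))
        for r in range(5):
            t0 = {
                (i, j) for i in nodes for j in nodes
                if i != j and rng.random() < 0.2
            }
            t1 = {
                (i, j) for i in nodes for j in nodes
                if i != j and rng.random() < 0.2
            }
            net = TwoWaveNetwork(nodes, t0, t1)
            pair = build_pair(net)
            np.testing.assert_array_equal(
                pair.y_next(), net.adjacency("followup")
            )

    def test_nesting_invariant(self):
        for r in range(10):
            a0 = random_adj(8, 0.3, r)
            a1 = random_adj(8, 0.3, 100 + r)
            net = TwoWaveNetwork(
                tuple(range(8)),
                {tuple(e) for e in np.argwhere(a0)},
                {tuple(e) for e in np.argwhere(a1)},
            )
            pair = build_pair(net)
            assert np.all(pair.y_minus <= pair.y_prev)
            assert np.all(pair.y_prev <= pair.y_plus)


class TestChangeStatistics:
    def test_mutual_zero_when_reverse_absent(self):
        a = np.zeros((3, 3), dtype=np.int8)
        assert change_statistic("mutual", (0, 1), a) == 0.0

    def test_same_side_match(self):
        a = np.zeros((3, 3), dtype=np.int8)
        side = np.array(["against", "against", "favorable"])
        assert change_statistic("same_side", (0, 1), a, side) == 1.0
        assert change_statistic("same_side", (0, 2), a, side) == 0.0

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            change_statistic("triangles", (0, 1), np.zeros((3, 3)))

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            change_statistic("edges", (1, 1), np.zeros((3, 3)))

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exhaustive_against_full_recount(self, n):
        # every statistic, every dyad, several graphs: change statistic
        # equals the brute-force before/after recount
        side = np.array(["a", "b"] * n)[:n]
        for seed in range(3):
            a = random_adj(n, 0.35, seed)
            mats = change_stats_matrix(a, list(("edges", "mutual", "transitive", "same_side")), side)
            for stat in ("edges", "mutual", "transitive", "same_side"):
                for i, j in itertools.permutations(range(n), 2):
                    on, off = a.copy(), a.copy()
                    on[i, j], off[i, j] = 1, 0
                    brute = (
                        network_statistics(on, [stat], side)[stat]
                        - network_statistics(off, [stat], side)[stat]
                    )
                    assert mats[stat][i, j] == brute, (stat, i, j)


class TestMPLE:
    def test_edges_only_closed_form(self):
        a0 = random_adj(20, 0.2, 1)
        a1 = random_adj(20, 0.2, 2)
        net = TwoWaveNetwork(
            tuple(range(20)),
            {tuple(e) for e in np.argwhere(a0)},
            {tuple(e) for e in np.argwhere(a1)},
        )
        pair = build_pair(net)
        spec = StergmSpec(formation=("edges",), dissolution=("edges",))
        fit = mple_fit(pair, spec)
        eligible = (pair.y_prev == 0) & ~np.eye(20, dtype=bool)
        frac = pair.y_plus[eligible].mean()
        expected = np.log(frac / (1 - frac))
        assert fit.formation["coef"][0] == pytest.approx(expected, abs=1e-6)

    def test_dyad_independent_matches_exact_mle(self):
        # edges + same_side is dyad-independent: MPLE == MLE; cross-check
        # against an independent logistic implementation
        rng = np.random.default_rng(3)
        n = 40
        side = rng.choice(["x", "y"], n)
        a0 = random_adj(n, 0.15, 4)
        a1 = random_adj(n, 0.15, 5)
        net = TwoWaveNetwork(
            tuple(range(n)),
            {tuple(e) for e in np.argwhere(a0)},
            {tuple(e) for e in np.argwhere(a1)},
        )
        pair = build_pair(net)
        spec = StergmSpec(formation=("edges", "same_side"), dissolution=("edges", "same_side"))
        fit = mple_fit(pair, spec, side_t0=side, side_t1=side)
        eligible = (pair.y_prev == 0) & ~np.eye(n, dtype=bool)
        same = (side[:, None] == side[None, :]).astype(float)
        x = np.column_stack([np.ones(eligible.sum()), same[eligible]])
        y = pair.y_plus[eligible]
        ref = sm.Logit(y, x).fit(disp=0)
        assert np.abs(fit.formation["coef"].to_numpy() - ref.params).max() < 1e-6

    def test_simulate_then_estimate_recovery(self):
        spec = StergmSpec(formation=("edges", "mutual"), dissolution=("edges", "mutual"))
        tp, tm = np.array([-3.5, 2.0]), np.array([1.0, 0.7])
        errs = []
        for r in range(8):
            rng = np.random.default_rng(200 + r)
            y0 = _sample_dyads(rng, 50, -2.5, 0.0, 1.5, np.zeros(50, int))
            pair = simulate_stergm(y0, spec, tp, tm, n_sweeps=20, seed=r, return_pair=True)
            fit = mple_fit(pair, spec)
            errs.append(
                np.r_[fit.formation["coef"] - tp, fit.dissolution["coef"] - tm]
            )
        assert np.abs(np.nanmean(errs, axis=0)).max() < 0.3


class TestSimulator:
    def test_frozen_dynamics(self):
        a0 = random_adj(15, 0.2, 6)
        spec = StergmSpec(formation=("edges",), dissolution=("edges",))
        y1 = simulate_stergm(a0, spec, np.array([-20.0]), np.array([20.0]),
                             n_sweeps=5, seed=0)
        np.testing.assert_array_equal(y1, a0)

    def test_edges_only_formation_rate(self):
        a0 = np.zeros((40, 40), dtype=np.int8)
        theta = -1.0
        spec = StergmSpec(formation=("edges",), dissolution=("edges",))
        rates = []
        for s in range(5):
            pair = simulate_stergm(
                a0, spec, np.array([theta]), np.array([5.0]),
                n_sweeps=5, seed=s, return_pair=True,
            )
            rates.append(pair.y_plus.mean() * 40 * 40 / (40 * 39))
        p = 1 / (1 + np.exp(-theta))
        se = np.sqrt(p * (1 - p) / (40 * 39 * 5))
        assert abs(np.mean(rates) - p) < 3 * se + 1e-3

    def test_invalid_sweeps(self):
        with pytest.raises(ValueError):
            simulate_stergm(
                np.zeros((3, 3), dtype=np.int8), StergmSpec(("edges",), ("edges",)),
                np.array([0.0]), np.array([0.0]), n_sweeps=0,
            )

    def test_formation_distribution_matches_enumeration(self):
        # 5-node network, small formation space: the sampled distribution of
        # formation networks matches exhaustive enumeration of the
        # exponential-family probabilities
        n = 5
        a0 = np.ones((n, n), dtype=np.int8)
        np.fill_diagonal(a0, 0)
        free = [(0, 1), (1, 0), (2, 3), (3, 2), (4, 0)]
        for d in free:
            a0[d] = 0
        spec = StergmSpec(formation=("edges", "mutual"), dissolution=("edges",))
        theta = np.array([-0.5, 1.0])

        def state_prob():
            weights = {}
            for bits in itertools.product([0, 1], repeat=len(free)):
                a = a0.copy()
                for d, b in zip(free, bits):
                    a[d] = b
                g = network_statistics(a, ["edges", "mutual"])
                weights[bits] = np.exp(theta @ np.array([g["edges"], g["mutual"]]))
            z = sum(weights.values())
            return {k: v / z for k, v in weights.items()}

        exact = state_prob()
        counts = {k: 0 for k in exact}
        n_draws = 4000
        for s in range(n_draws):
            pair = simulate_stergm(
                a0, spec, theta, np.array([20.0]), n_sweeps=8, seed=s,
                return_pair=True,
            )
            bits = tuple(int(pair.y_plus[d]) for d in free)
            counts[bits] += 1
        tv = 0.5 * sum(
            abs(counts[k] / n_draws - exact[k]) for k in exact
        )
        assert tv < 0.05


class TestFitAllSchools:
    @staticmethod
    def _run(seed=1, n_schools=6, **cfgkw):
        import pandas as pd

        import normnet as nn
        from normnet.data import side_of_group
        from normnet.influence import categorize_ego
        from normnet.stergm import fit_all_schools

        config = nn.CohortConfig(
            n_schools=n_schools, school_size_range=(90, 120), seed=seed, **cfgkw
        )
        study = nn.generate_study(config)
        rows = []
        for tbl, net in study:
            base = tbl[tbl["wave"] == "baseline"].set_index("student")
            follow = tbl[tbl["wave"] == "followup"].set_index("student")
            for stu in net.roster:
                s0 = side_of_group(base.loc[stu, "true_group"])
                s1 = side_of_group(follow.loc[stu, "true_group"])
                rows.append(
                    {"school": net.school, "student": stu,
                     "side_t0": s0, "side_t1": s1,
                     "transition_category": categorize_ego(s0, s1)}
                )
        return fit_all_schools(
            [n for _, n in study], pd.DataFrame(rows), StergmSpec()
        )

    def test_null_homophily_mostly_nonsignificant(self):
        table = self._run(homophily_strength=0.0)
        same = table[table["term"] == "same_side"]
        # 6 schools x 2 phases; at the 5% level few should reject under null
        assert (same["p_value"] > 0.05).sum() >= len(same) - 2

    def test_strong_reciprocity_detected_everywhere(self):
        table = self._run(formation_reciprocity=2.5, dissolution_reciprocity=2.5)
        mut = table[table["term"] == "mutual"]
        assert ((mut["coef"] > 0) & (mut["p_value"] < 0.05)).all()

    def test_report_shape(self):
        table = self._run(n_schools=3)
        assert set(table["phase"]) == {"formation", "dissolution"}
        assert len(table) == 3 * 2 * 4  # schools x phases x statistics
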