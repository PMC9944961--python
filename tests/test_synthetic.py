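"""Planted-effect and invariant checks of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

import normnet as nn
from normnet.data import FAVORABLE_GROUPS, WAVES
from normnet.netchange import jaccard_change


def _config(**kw):
    base = dict(n_schools=2, school_size_range=(60, 80), seed=0)
    base.update(kw)
    return nn.CohortConfig(**base)


class TestConfigValidation:
    def test_rejects_small_schools(self):
        with pytest.raises(ValueError, match="school_size_range"):
            _config(school_size_range=(10, 50))

    def test_rejects_bad_prevalence(self):
        with pytest.raises(ValueError, match="prevalence"):
            _config(group_prevalence=(0.5, 0.4, 0.2))

    def test_rejects_bad_persistence(self):
        with pytest.raises(ValueError, match="persistence"):
            _config(tie_persistence=1.2)


class TestGenerateSchool:
    def test_out_degree_never_exceeds_cap(self):
        config = _config(max_nominations=5, target_in_degree=6.0)
        _, net = nn.generate_school(config, 0)
        for wave in WAVES:
            out = pd.Series([e for e, _ in net.ties(wave)]).value_counts()
            assert out.max() <= 5

    def test_full_persistence_gives_jaccard_one(self):
        _, net = nn.generate_school(_config(tie_persistence=1.0), 0)
        assert jaccard_change(net).jaccard == 1.0

    def test_in_degree_calibration(self):
        # generator's own calibration: realized mean in-degree near target
        realized = []
        for seed in range(20):
            config = nn.CohortConfig(
                n_schools=1, school_size_range=(100, 100),
                target_in_degree=6.5, seed=seed,
            )
            _, net = nn.generate_school(config, 0)
            realized.append(len(net.ties_t0) / len(net.roster))
        assert abs(np.mean(realized) - 6.5) < 0.5

    def test_null_homophily_no_same_group_excess(self):
        # with no planted homophily the same-group tie odds ratio is ~1
        lors = []
        for seed in range(30):
            config = nn.CohortConfig(
                n_schools=1, school_size_range=(70, 70),
                homophily_strength=0.0, influence_strength=0.0, seed=seed,
            )
            table, net = nn.generate_school(config, 0)
            base = table[table["wave"] == "baseline"].set_index("student")
            g = base["true_group"]
            same_tie = diff_tie = 0
            for e, a in net.ties_t0:
                if g[e] == g[a]:
                    same_tie += 1
                else:
                    diff_tie += 1
            n = len(net.roster)
            gm = g[list(net.roster)].to_numpy()
            same_pairs = (gm[:, None] == gm[None, :]).sum() - n
            diff_pairs = n * (n - 1) - same_pairs
            lors.append(
                np.log((same_tie + 0.5) / (same_pairs + 0.5))
                - np.log((diff_tie + 0.5) / (diff_pairs + 0.5))
            )
        assert abs(np.mean(lors)) < 2 * np.std(lors) / np.sqrt(len(lors)) + 0.05

    def test_homophily_monotone(self):
        def mean_lor(h):
            vals = []
            for seed in range(30):
                config = nn.CohortConfig(
                    n_schools=1, school_size_range=(60, 60),
                    homophily_strength=h, seed=seed,
                )
                table, net = nn.generate_school(config, 0)
                g = table[table["wave"] == "baseline"].set_index("student")[
                    "true_group"
                ]
                same = sum(g[e] == g[a] for e, a in net.ties_t0)
                diff = len(net.ties_t0) - same
                gm = g[list(net.roster)].to_numpy()
                n = len(gm)
                sp = (gm[:, None] == gm[None, :]).sum() - n
                dp = n * (n - 1) - sp
                vals.append(np.log((same + 0.5) * dp / ((diff + 0.5) * sp)))
            return np.mean(vals)

        grid = [mean_lor(h) for h in (0.0, 0.5, 1.0)]
        assert grid[0] < grid[1] < grid[2]
        assert np.exp(grid[1]) > 1.0  # odds ratio above 1 with planted homophily

    def test_jaccard_monotone_in_persistence(self):
        js = []
        for rho in (0.2, 0.5, 0.8):
            vals = []
            for seed in range(10):
                config = nn.CohortConfig(
                    n_schools=1, school_size_range=(80, 80),
                    tie_persistence=rho, seed=seed,
                )
                _, net = nn.generate_school(config, 0)
                vals.append(jaccard_change(net).jaccard)
            js.append(np.mean(vals))
        assert js[0] < js[1] < js[2]

    def test_prevalence_converges(self):
        config = nn.CohortConfig(
            n_schools=1, school_size_range=(500, 500), seed=3
        )
        # single large-school check against the configured prevalence
        counts = np.zeros(3)
        for seed in range(4):  # 4 x 500 students = n=2000
            c = nn.CohortConfig(
                n_schools=1, school_size_range=(500, 500), seed=seed
            )
            table, _ = nn.generate_school(c, 0)
            base = table[table["wave"] == "baseline"]
            counts += np.bincount(base["true_group"], minlength=4)[1:]
        freq = counts / counts.sum()
        assert np.abs(freq - np.array(config.group_prevalence)).max() < 0.02


class TestGenerateStudy:
    def test_deterministic(self):
        a = nn.generate_study(_config())
        b = nn.generate_study(_config())
        for (ta, na), (tb, nb) in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)
            assert na.ties_t0 == nb.ties_t0 and na.ties_t1 == nb.ties_t1

    def test_balanced_arms(self):
        config = nn.CohortConfig(n_schools=12, school_size_range=(30, 40), seed=1)
        study = nn.generate_study(config)
        arms = {}
        for table, _ in study:
            setting = table["setting"].iloc[0]
            interv = table["intervention"].iloc[0]
            arms[(setting, interv)] = arms.get((setting, interv), 0) + 1
        assert all(v == 3 for v in arms.values()) and len(arms) == 4

    def test_sizes_in_range(self, small_study):
        config, study = small_study
        lo, hi = config.school_size_range
        for _, net in study:
            assert lo <= len(net.roster) <= hi


class TestInjectMissingness:
    def test_rate_zero_identity(self, small_tables):
        table, _ = small_tables
        out = nn.inject_missingness(table, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, table)

    def test_rejects_rate_one(self, small_tables):
        with pytest.raises(ValueError):
            nn.inject_missingness(small_tables[0], 1.0, seed=1)

    def test_deterministic(self, small_tables):
        table, _ = small_tables
        a = nn.inject_missingness(table, 0.3, seed=7)
        b = nn.inject_missingness(table, 0.3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_binomial_complete_case_count(self):
        # rate 0.28 leaves ~72% complete, within 2 binomial s.e.
        config = nn.CohortConfig(
            n_schools=3, school_size_range=(460, 480), seed=5
        )
        table = pd.concat(
            [t for t, _ in nn.generate_study(config)], ignore_index=True
        )
        n = table.groupby(["school", "student"]).ngroups
        out = nn.inject_missingness(table, 0.28, seed=2)
        scores = nn.build_norm_scores(out)
        complete = scores[scores["complete"]].groupby(["school", "student"]).ngroups
        se = np.sqrt(n * 0.28 * 0.72)
        assert abs(complete - 0.72 * n) < 2 * se
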