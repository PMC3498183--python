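"""Nonparametric statistics against enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from meggraph.stats import (
    StatsConfig,
    cognitive_z,
    fdr_correct,
    kendall_tau,
    kruskal_wallis,
    mann_whitney,
    run_group_analysis,
)

# ---------------------------------------------------------------- oracles


def rankdata_avg(x):
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def kw_oracle(groups):
    """Kruskal-Wallis H by direct rank computation with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = rankdata_avg(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        r = ranks[idx : idx + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        idx += len(g)
    h *= 12 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def mwu_oracle(x, y):
    """U = min(U_x, U_y) by brute-force pair counting with half-ties."""
    ux = sum(1.0 * (a > b) + 0.5 * (a == b) for a in x for b in y)
    return min(ux, len(x) * len(y) - ux)


def bh_oracle(p, alpha):
    """Benjamini-Hochberg step-up reject set by direct threshold scan."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, pi in enumerate(p[order], start=1):
        if pi <= i * alpha / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def tau_b_oracle(x, y):
    """Kendall tau-b by O(n^2) concordant/discordant pair counting."""
    n = len(x)
    c = d = tx = ty = 0
    for i, j in combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            c += 1
        else:
            d += 1
    denom = np.sqrt((c + d + tx) * (c + d + ty))
    return (c - d) / denom if denom > 0 else np.nan


# ------------------------------------------------------------------ tests


class TestKruskalWallis:
    def test_three_clean_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert 0 < p < 0.05

    def test_identical_groups_degenerate(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_group_order_irrelevant(self, rng):
        groups = [rng.normal(size=5), rng.normal(size=7), rng.normal(size=6)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis(groups[::-1])
        assert h1 == pytest.approx(h2)

    def test_matches_rank_oracle_with_ties(self, rng):
        for _ in range(20):
            groups = [
                rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
                for _ in range(3)
            ]
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kw_oracle(groups), abs=1e-10)

    def test_rejects_single_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples(self):
        u, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == pytest.approx(16 / 2)
        assert p == pytest.approx(1.0)

    def test_interleaved(self):
        u, _ = mann_whitney([1, 3, 5], [2, 4, 6])
        assert u == 3.0

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 20, size=rng.integers(2, 15)).astype(float)
            y = rng.integers(0, 20, size=rng.integers(2, 15)).astype(float)
            u, _ = mann_whitney(x, y)
            assert u == pytest.approx(mwu_oracle(x, y))


class TestFdr:
    def test_linear_grid_all_rejected(self):
        p_adj, reject = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), 0.05)
        assert reject.all()

    def test_single_p_unchanged(self):
        p_adj, _ = fdr_correct(np.array([0.03]))
        assert p_adj[0] == pytest.approx(0.03)

    def test_one_small_among_large(self):
        _, reject = fdr_correct(np.array([0.001, 0.9, 0.9, 0.9, 0.9]), 0.05)
        assert reject.tolist() == [True, False, False, False, False]

    def test_adjusted_p_monotone_in_raw_order(self, rng):
        p = rng.uniform(size=20)
        p_adj, _ = fdr_correct(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)

    def test_matches_step_up_oracle(self, rng):
        for _ in range(50):
            p = np.round(rng.uniform(size=rng.integers(1, 15)), 3)
            _, reject = fdr_correct(p, 0.05)
            assert np.array_equal(reject, bh_oracle(p, 0.05))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.5, 1.2]))


class TestKendallTau:
    def test_perfect_concordance(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])
        assert tau == pytest.approx(1.0)

    def test_perfect_discordance(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_single_swap(self):
        tau, _ = kendall_tau([1, 2, 3, 4], [1, 3, 2, 4])
        assert tau == pytest.approx(2 / 3)

    def test_zero_variance_flagged_nan(self):
        tau, p = kendall_tau([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(tau) and np.isnan(p)

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 50))
            x = rng.integers(0, 10, size=n).astype(float)
            y = rng.integers(0, 10, size=n).astype(float)
            tau, _ = kendall_tau(x, y)
            oracle = tau_b_oracle(x, y)
            if np.isnan(oracle):
                assert np.isnan(tau)
            else:
                assert tau == pytest.approx(oracle, abs=1e-12)


class TestCognitiveZ:
    CONTROL_MEAN = {"attention": [50.0, 30.0], "memory": [10.0]}
    CONTROL_SD = {"attention": [10.0, 5.0], "memory": [2.0]}

    def test_at_control_mean_all_zero(self):
        domains, overall = cognitive_z(
            {"attention": [50.0, 30.0], "memory": [10.0]},
            self.CONTROL_MEAN,
            self.CONTROL_SD,
        )
        assert domains == {"attention": 0.0, "memory": 0.0}
        assert overall == 0.0

    def test_one_sd_below_on_one_of_two_subtests(self):
        domains, _ = cognitive_z(
            {"attention": [40.0, 30.0], "memory": [10.0]},
            self.CONTROL_MEAN,
            self.CONTROL_SD,
        )
        assert domains["attention"] == pytest.approx(-0.5)

    def test_domain_average(self):
        domains, overall = cognitive_z(
            {"a": [-1.1], "b": [-1.2], "c": [0.0]},
            {"a": [0.0], "b": [0.0], "c": [0.0]},
            {"a": [1.0], "b": [1.0], "c": [1.0]},
        )
        assert overall == pytest.approx(-0.7667, abs=1e-4)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cognitive_z({"a": [1.0]}, {"a": [0.0]}, {"a": [0.0]})


# ------------------------------------------- the full analysis procedure


def null_metrics_table(rng, groups=(("A", 10), ("B", 10), ("C", 10), ("D", 10))):
    rows = []
    for label, n in groups:
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{label}{i}",
                    "group": label,
                    "band": "theta",
                    "pli": rng.normal(),
                    "cw_ratio": rng.normal(),
                    "lw_ratio": rng.normal(),
                    "S": rng.normal(),
                    "Q": rng.normal(),
                    "Pw": rng.normal(),
                    "zbar": rng.normal(),
                    "seizure_freq": rng.uniform(0, 10),
                    "cognition": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestRunGroupAnalysis:
    def test_single_group_rejected(self, rng):
        df = null_metrics_table(rng, groups=(("A", 8),))
        with pytest.raises(ValueError, match="2 groups"):
            run_group_analysis(df)

    def test_missing_metric_column_named(self, rng):
        df = null_metrics_table(rng).drop(columns=["Pw"])
        with pytest.raises(KeyError, match="Pw"):
            run_group_analysis(df)

    def test_posthoc_only_for_fdr_significant(self, rng):
        df = null_metrics_table(rng)
        # plant a huge effect on S in group A
        df.loc[df["group"] == "A", "S"] += 10.0
        ga = run_group_analysis(df)
        for rep in ga.reports:
            if rep.in_family and not rep.significant:
                assert rep.posthoc == []
        s_rep = next(r for r in ga.reports if r.metric == "S")
        assert s_rep.significant
        assert len(s_rep.posthoc) == 6  # all pairs of 4 groups

    def test_planted_effect_power_and_group_identification(self, rng):
        """A strong planted group shift on S is flagged after FDR and the
        post-hoc tests single out the planted group in >= 80% of runs."""
        hits = 0
        runs = 50
        for _ in range(runs):
            df = null_metrics_table(
                rng, groups=(("LGG", 13), ("HGG", 12), ("NGL", 10), ("CTL", 36))
            )
            df.loc[df["group"] == "LGG", "S"] -= 2.0
            ga = run_group_analysis(df)
            s_rep = next(r for r in ga.reports if r.metric == "S")
            if s_rep.significant:
                lgg_ps = [p for (pair, u, p) in s_rep.posthoc if "LGG" in pair]
                if lgg_ps and max(lgg_ps) < 0.05:
                    hits += 1
        assert hits >= 0.8 * runs

    def test_rank_statistics_invariant_under_monotone_transform(self, rng):
        df = null_metrics_table(rng)
        ga1 = run_group_analysis(df)
        df2 = df.copy()
        for col in ("pli", "cw_ratio", "lw_ratio", "S", "Q", "Pw", "zbar"):
            df2[col] = np.exp(3.0 * df2[col])  # strictly increasing
        ga2 = run_group_analysis(df2)
        for r1, r2 in zip(ga1.reports, ga2.reports):
            assert r1.kw_statistic == pytest.approx(r2.kw_statistic)
            assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_correlations_reported_per_group(self, rng):
        df = null_metrics_table(rng)
        ga = run_group_analysis(
            df, StatsConfig(covariate_pairs=(("S", "seizure_freq"),))
        )
        assert set(ga.correlations["group"]) == {"A", "B", "C", "D"}
        assert (ga.correlations["n"] == 10).all()


@given(st.integers(0, 2**31 - 1))
def test_fdr_reject_iff_adjusted_p_below_alpha(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=8)
    p_adj, reject = fdr_correct(p, 0.05)
    assert np.array_equal(reject, p_adj <= 0.05)
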