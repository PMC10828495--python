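"""The multi-arm comparison layer: Holm-Sidak, ANOVA, Fisher r x c, t-tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ucmp.stats import (
    fisher_exact_rxc,
    holm_sidak_adjust,
    one_way_anova_posthoc,
    rm_two_way_anova,
    summarize_table,
    unpaired_t,
)
from ucmp.synth import CohortEffectSpec, gen_cohort


def step_down_oracle(pvals):
    """Literal Holm-Sidak definition, independent of the implementation."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        val = 1.0 - (1.0 - pvals[idx]) ** (m - rank)
        running = max(running, val)
        adj[idx] = min(running, 1.0)
    return adj


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_pair(self):
        adj = holm_sidak_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)  # 0.0199
        assert adj[1] == pytest.approx(0.04)

    def test_all_ones(self):
        assert holm_sidak_adjust([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=200)
    def test_matches_literal_definition(self, pvals):
        adj = holm_sidak_adjust(pvals)
        assert adj == pytest.approx(step_down_oracle(pvals), abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=100)
    def test_invariants(self, pvals):
        adj = holm_sidak_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in sorted order

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            holm_sidak_adjust([0.5, 1.5])


def brute_force_f(groups):
    """One-way ANOVA F from explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestOneWay:
    def test_identical_arms(self):
        res = one_way_anova_posthoc({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.f_statistic == 0.0
        assert res.p_omnibus == 1.0
        assert res.comparisons[0].p_adjusted == 1.0

    def test_f_matches_brute_force_oracle(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, size=8) for i in range(4)}
        res = one_way_anova_posthoc(groups)
        assert res.f_statistic == pytest.approx(
            brute_force_f(list(groups.values())), abs=1e-10)

    def test_textbook_three_groups(self):
        groups = {"a": [6, 8, 4, 5, 3, 4], "b": [8, 12, 9, 11, 6, 8],
                  "c": [13, 9, 11, 8, 7, 12]}
        res = one_way_anova_posthoc(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(float(f), abs=1e-10)
        assert res.p_omnibus == pytest.approx(float(p), abs=1e-12)

    def test_family_structure(self):
        groups = {n: [1.0, 2.0, 3.0] for n in ("Sham", "CKD", "D1", "D2")}
        assert len(one_way_anova_posthoc(groups).comparisons) == 6
        vs = one_way_anova_posthoc(groups, family="vs-control", control="Sham")
        assert len(vs.comparisons) == 3
        assert all("Sham" in c.name for c in vs.comparisons)

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova_posthoc({"a": [1.0], "b": [1, 2]})

    def test_null_familywise_error_near_nominal(self):
        # 4 arms, n=8, no effect: P(any Holm-Sidak-adjusted p < .05) ~ .05
        rng = np.random.default_rng(2024)
        reps = 1000
        hits = 0
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(size=8) for i in range(4)}
            res = one_way_anova_posthoc(groups)
            hits += any(c.significant for c in res.comparisons)
        fwer = hits / reps
        assert abs(fwer - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)


def _two_tp_cohort(effect=0.0, n=7, seed=0, arms=("Sham", "CKD", "D1", "D2")):
    rng = np.random.default_rng(seed)
    rows = []
    for arm in arms:
        for j in range(n):
            a = rng.normal()
            rows.append((f"{arm}{j}", arm, "week5", a + rng.normal()))
            rows.append((f"{arm}{j}", arm, "endpoint", a + effect + rng.normal()))
    return pd.DataFrame(rows, columns=["animal", "arm", "timepoint", "value"])


class TestRMTwoWay:
    def test_matches_pingouin_oracle(self):
        df = _two_tp_cohort(effect=0.8, seed=3)
        res = rm_two_way_anova(df)
        aov = pg.mixed_anova(data=df, dv="value", within="timepoint",
                             subject="animal", between="arm").set_index("Source")
        assert res.effect_p("time") == pytest.approx(aov.loc["timepoint", "p_unc"])
        assert res.effect_p("group") == pytest.approx(aov.loc["arm", "p_unc"])

    def test_time_effect_power_at_large_d(self):
        # Cohen's d = 2 time effect, n = 7/arm: detected in >= 95% of runs
        detected = 0
        runs = 60
        for seed in range(runs):
            df = _two_tp_cohort(effect=2 * math.sqrt(2), n=7, seed=seed)
            res = rm_two_way_anova(df)
            detected += res.effect_p("time") < 0.05
        assert detected / runs >= 0.95

    def test_null_interaction_p_uniform(self):
        reps = 300
        ps = []
        for seed in range(reps):
            df = _two_tp_cohort(effect=0.0, n=6, seed=10_000 + seed,
                                arms=("a", "b", "c"))
            ps.append(rm_two_way_anova(df).effect_p("interaction"))
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_incomplete_animal_excluded_with_warning(self):
        df = _two_tp_cohort(seed=5)
        df = df.drop(df[(df["animal"] == "Sham0") & (df["timepoint"] == "endpoint")].index)
        with pytest.warns(UserWarning, match="missing a timepoint"):
            res = rm_two_way_anova(df)
        assert res.n_excluded_animals == 1

    def test_duplicated_timepoint_rows_error(self):
        df = _two_tp_cohort(seed=5)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            rm_two_way_anova(dup)

    def test_arm_below_two_error(self):
        # n=2 per arm; making one Sham animal incomplete leaves the arm at n=1
        df = _two_tp_cohort(n=2, seed=1)
        df = df.drop(df[(df["animal"] == "Sham0") & (df["timepoint"] == "endpoint")].index)
        with pytest.raises(ValueError, match="below n=2"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rm_two_way_anova(df)

    def test_within_arm_contrasts_adjusted(self):
        df = _two_tp_cohort(effect=1.5, seed=9)
        res = rm_two_way_anova(df)
        assert len(res.contrasts) == 4
        for c in res.contrasts:
            assert c.p_adjusted >= c.p_raw - 1e-15


class TestFisher:
    def test_diagonal_5_5(self):
        res = fisher_exact_rxc([[5, 0], [0, 5]])
        assert res.p == pytest.approx(2 / math.comb(10, 5), abs=1e-12)

    def test_2x2_matches_scipy(self, rng):
        for _ in range(20):
            table = rng.integers(0, 12, size=(2, 2))
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                continue
            _, p_scipy = sps.fisher_exact(table)
            assert fisher_exact_rxc(table).p == pytest.approx(p_scipy, abs=1e-9)

    def test_2x2_hypergeometric_closed_form(self):
        table = np.array([[3, 7], [6, 2]])
        # sum hypergeometric pmf over tables at least as extreme (prob order)
        n1, n2 = table.sum(axis=1)
        k = table[:, 0].sum()
        rv = sps.hypergeom(n1 + n2, n1, k)
        p_obs = rv.pmf(table[0, 0])
        p_closed = sum(rv.pmf(x) for x in range(max(0, k - n2), min(k, n1) + 1)
                       if rv.pmf(x) <= p_obs * (1 + 1e-9))
        assert fisher_exact_rxc(table).p == pytest.approx(p_closed, abs=1e-12)

    def test_zero_row_dropped(self):
        base = fisher_exact_rxc([[4, 1], [2, 5]]).p
        padded = fisher_exact_rxc([[4, 1], [0, 0], [2, 5]]).p
        assert padded == pytest.approx(base, abs=1e-12)

    def test_probabilities_sum_to_one_on_margin_space(self):
        # enumerate via p of an impossible "extreme" observation: setting the
        # threshold above every table probability must give p = 1
        res = fisher_exact_rxc([[2, 1, 1], [1, 2, 1]])
        assert 0 < res.p <= 1.0
        # a table equal to expectation is among the most probable ones
        assert fisher_exact_rxc([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_rxc_against_r_convention(self):
        # 3x3 with a clear association: exact p must be well below 0.05 and
        # the Monte-Carlo route must agree within its own error
        table = [[8, 1, 0], [1, 7, 1], [0, 2, 8]]
        exact = fisher_exact_rxc(table)
        mc = fisher_exact_rxc(table, method="monte-carlo", n_permutations=20000,
                              rng=np.random.default_rng(0))
        assert exact.method == "exact"
        assert exact.p < 0.001
        assert abs(mc.p - exact.p) < 4 * (mc.se or 1)

    def test_enumeration_budget(self):
        big = (np.ones((5, 6), dtype=int) * 8)
        with pytest.raises(ValueError, match="monte-carlo"):
            fisher_exact_rxc(big, max_tables=1000, method="exact")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[1, -1], [2, 3]])


class TestUnpairedT:
    def test_identical_samples(self):
        res = unpaired_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(1.0)

    def test_matches_closed_form(self):
        a, b = [6.0, 8.0, 4.0, 5.0], [8.0, 12.0, 9.0, 11.0]
        res = unpaired_t(a, b)
        na, nb = len(a), len(b)
        sp2 = (((np.array(a) - np.mean(a)) ** 2).sum()
               + ((np.array(b) - np.mean(b)) ** 2).sum()) / (na + nb - 2)
        t_oracle = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t_oracle, abs=1e-12)
        assert res.p_raw == pytest.approx(2 * sps.t.sf(abs(t_oracle), na + nb - 2),
                                          abs=1e-12)

    def test_swap_flips_sign(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        r1, r2 = unpaired_t(a, b), unpaired_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_raw == pytest.approx(r2.p_raw)

    def test_zero_variance_convention(self):
        res = unpaired_t([2.0, 2.0], [2.0, 2.0])
        assert (res.statistic, res.p_raw) == (0.0, 1.0)
        assert res.flag == "zero-variance"

    def test_welch_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.5, size=6)
        b = rng.normal(1, 4.0, size=20)
        student = unpaired_t(a, b, welch=False)
        welch = unpaired_t(a, b, welch=True)
        assert welch.df < student.df


class TestSummarize:
    def test_single_cell(self):
        df = pd.DataFrame({"arm": ["Sham"] * 2, "timepoint": ["week5"] * 2,
                           "parameter": ["LVEDV"] * 2, "value": [8.0, 12.0]})
        out = summarize_table(df)
        row = out.iloc[0]
        assert (row["mean"], row["sem"], row["n"]) == (10.0, pytest.approx(2.0), 2)

    def test_dropout_arm_reports_n7(self):
        spec = CohortEffectSpec(
            means={"LVEDV": {arm: {"week5": (194.0, 30.0), "endpoint": (255.0, 40.0)}
                             for arm in ("Sham", "CKD", "CKD+D1", "CKD+D2")}},
            n_per_group=8, dropout=(("CKD+D2", 1),), seed=0)
        out = summarize_table(gen_cohort(spec))
        ns = out.set_index(["arm", "timepoint"])["n"]
        assert ns[("CKD+D2", "week5")] == 7
        assert ns[("Sham", "week5")] == 8
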