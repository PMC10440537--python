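"""Cohort statistics against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from prtms.group_stats import (
    fisher_exact_2x2,
    one_sample_t,
    paired_t,
    rm_anova,
    sign_test_binned,
    summarize_cohort,
    t_from_summary,
    threshold_exceedance,
)
from prtms.psychometrics import ScoreSeries


def _series(sid, totals):
    return ScoreSeries(subject_id=sid, instrument="PCL5", totals=totals)


class TestSummarize:
    def test_hand_computed_fixture(self):
        cohort = [
            _series("a", {0: 50, 4: 30}),
            _series("b", {0: 60, 4: 40}),
            _series("c", {0: 40, 4: 35}),
            _series("d", {0: 55, 4: 45}),
            _series("e", {0: 45}),  # missing week 4
        ]
        table = summarize_cohort(cohort, [0, 4])
        raw0 = table[(table.week == 0) & (table.data_type == "RAW")].iloc[0]
        assert raw0["n"] == 5
        assert raw0["mean"] == pytest.approx((50 + 60 + 40 + 55 + 45) / 5)
        assert raw0["median"] == 50
        cfb4 = table[(table.week == 4) & (table.data_type == "CFB")].iloc[0]
        assert cfb4["n"] == 4
        assert cfb4["mean"] == pytest.approx((-20 - 20 - 5 - 10) / 4)
        assert cfb4["min"] == -20 and cfb4["max"] == -5

    def test_single_subject_degenerate(self):
        table = summarize_cohort([_series("a", {0: 50})], [0])
        row = table.iloc[0]
        assert row["mean"] == row["median"] == row["min"] == row["max"] == 50
        assert row["sd"] == 0.0
        assert "sd_undefined" in row["flags"]

    def test_empty_timepoint_omitted(self):
        table = summarize_cohort([_series("a", {0: 50})], [0, 4])
        assert (4, "RAW") in table.attrs["dropped"]


class TestTTests:
    def test_cohort_scale_summary_t(self):
        # mean -20.6, sd 16.64, n 195: |t| = 20.6 / (16.64/sqrt(195))
        res = t_from_summary(-20.6, 16.64, 195)
        oracle = -20.6 / (16.64 / math.sqrt(195))
        assert res.statistic == pytest.approx(oracle, abs=1e-12)
        assert res.statistic == pytest.approx(-17.29, abs=0.01)
        assert res.p < 1e-4
        assert res.df == 194

    def test_one_sample_matches_summary_form(self):
        rng = np.random.default_rng(1)
        v = rng.normal(-3, 4, size=40)
        a = one_sample_t(v)
        b = t_from_summary(v.mean(), v.std(ddof=1), v.size)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance|degenerate"):
            one_sample_t([0.0, 0.0, 0.0])

    def test_paired_reduces_to_differences(self):
        pre = [10.0, 12.0, 9.0, 15.0, 11.0, 13.0]
        post = [7.0, 10.0, 8.0, 12.0, 10.0, 9.0]
        res = paired_t(pre, post)
        ref = one_sample_t(np.subtract(post, pre))
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.p)

    def test_paired_identical_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            paired_t([1.0, 2.0], [1.0])

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_p_scale_invariant(self, c):
        v = np.array([-4.0, -2.0, -5.0, -1.0, -3.0, 0.5])
        assert one_sample_t(v).p == pytest.approx(one_sample_t(c * v).p,
                                                  rel=1e-9)


def _binom_two_sided(k, n):
    """Brute-force exact two-sided binomial p at p0 = 1/2."""
    pmf = [math.comb(n, i) * 0.5 ** n for i in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] + 1e-12))


class TestSignTest:
    def test_five_leads_all_falling(self):
        pre = [10.6, 10.7, 10.8, 10.9, 11.0]
        post = [9.6, 9.7, 9.8, 9.9, 10.0]
        res = sign_test_binned(pre, post)
        assert res.p == pytest.approx(2 * 0.5 ** 5)  # 0.0625

    def test_symmetric_changes_give_p_one(self):
        pre = [9.0, 9.0, 11.0, 11.0]
        post = [10.0, 10.0, 10.0, 10.0]
        assert sign_test_binned(pre, post).p == pytest.approx(1.0)

    def test_all_ties_flagged(self):
        pre = post = [10.0, 10.1, 10.2]
        res = sign_test_binned(pre, post)
        assert res.p == 1.0
        assert "all_ties" in res.flags

    def test_within_bin_moves_are_ties(self):
        res = sign_test_binned([10.0], [10.4])  # same 0.5 Hz bin [10, 10.5)
        assert "all_ties" in res.flags

    def test_matches_exact_enumeration_for_all_small_n(self):
        # exhaustive: every (n <= 20, k) against the brute-force binomial tail
        for n in range(1, 21):
            for k in range(n + 1):
                pre = [10.6] * n
                post = [11.6] * k + [9.6] * (n - k)
                res = sign_test_binned(pre, post)
                assert res.p == pytest.approx(_binom_two_sided(k, n),
                                              abs=1e-12), (n, k)


class TestRMAnova:
    def test_identical_trajectories_null(self):
        y = np.tile([10.0, 9.0, 8.0], (6, 1))
        res = rm_anova(y, ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.9

    def test_three_by_three_fixture_vs_brute_force(self):
        y = np.array([
            [10.0, 9.0, 8.0],
            [11.0, 9.5, 8.5],
            [10.5, 10.4, 10.6],
            [10.8, 10.9, 10.7],
        ])
        groups = ["resp", "resp", "non", "non"]
        res = rm_anova(y, groups)

        # brute-force SS decomposition, independently recomputed
        grand = y.mean()
        k = y.shape[1]
        ss_group = 0.0
        for g in ("resp", "non"):
            rows = y[[i for i, x in enumerate(groups) if x == g]]
            ss_group += rows.shape[0] * k * (rows.mean() - grand) ** 2
        subj_means = y.mean(axis=1)
        ss_bs = k * ((subj_means - grand) ** 2).sum()
        ss_sw = ss_bs - ss_group
        f_oracle = (ss_group / 1) / (ss_sw / 2)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-8)

    def test_sum_of_squares_conserved(self):
        rng = np.random.default_rng(3)
        y = rng.normal(10, 2, size=(12, 5))
        groups = ["a"] * 7 + ["b"] * 5
        res = rm_anova(y, groups)
        ss = res.extras["ss"]
        total = (ss["group"] + ss["subjects_within_groups"] + ss["week"]
                 + ss["interaction"] + ss["error"])
        assert total == pytest.approx(ss["total"], abs=1e-10 * max(1, ss["total"]))

    def test_agrees_with_pingouin_mixed_anova(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(7)
        n, k = 10, 4
        y = rng.normal(10, 1, size=(n, k))
        y[:6] += np.linspace(0, -2, k)  # group trend
        groups = ["resp"] * 6 + ["non"] * 4
        res = rm_anova(y, groups)

        df = pd.DataFrame({
            "y": y.ravel(),
            "week": np.tile(np.arange(k), n),
            "subject": np.repeat(np.arange(n), k),
            "group": np.repeat(groups, k),
        })
        ref = pg.mixed_anova(df, dv="y", within="week", subject="subject",
                             between="group")
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        f_ref = float(ref.loc[ref.Source == "group", "F"].iloc[0])
        p_ref = float(ref.loc[ref.Source == "group", pcol].iloc[0])
        assert res.statistic == pytest.approx(f_ref, rel=1e-6)
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_small_group_rejected(self):
        y = np.ones((3, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            rm_anova(y, ["a", "a", "b"])


class TestExceedanceAndFisher:
    def test_counting(self):
        out = threshold_exceedance([12, 7, 3])
        assert out[5.0] == pytest.approx(2 / 3)
        assert out[10.0] == pytest.approx(1 / 3)

    def test_all_zero_drops(self):
        out = threshold_exceedance([0, 0, 0])
        assert out[5.0] == 0.0 and out[10.0] == 0.0

    def test_fisher_diagonal_table(self):
        # exact hypergeometric enumeration oracle for [[10,0],[0,10]]:
        # p = 2 / C(20,10)
        oracle = 2.0 / math.comb(20, 10)
        res = fisher_exact_2x2([[10, 0], [0, 10]])
        assert res.p == pytest.approx(oracle, rel=1e-9)
        assert res.p == pytest.approx(1.083e-5, rel=1e-3)

    @pytest.mark.parametrize("table", [[[5, 5], [5, 5]], [[1, 1], [1, 1]]])
    def test_fisher_no_association(self, table):
        assert fisher_exact_2x2(table).p == pytest.approx(1.0)

    def test_fisher_matches_enumeration(self):
        # independent oracle: enumerate the hypergeometric distribution
        a, b, c, d = 7, 3, 2, 9
        n, r1, c1 = a + b + c + d, a + b, a + c
        def pmf(x):
            return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                    / math.comb(n, c1))
        p_obs = pmf(a)
        oracle = sum(pmf(x) for x in range(max(0, c1 - (n - r1)),
                                           min(r1, c1) + 1)
                     if pmf(x) <= p_obs * (1 + 1e-9))
        assert fisher_exact_2x2([[a, b], [c, d]]).p == pytest.approx(
            oracle, rel=1e-9)

    def test_zero_margin_flagged(self):
        res = fisher_exact_2x2([[0, 0], [3, 4]])
        assert res.p == 1.0
        assert "zero_margin" in res.flags
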