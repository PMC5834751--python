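"""Tests for the statistical analysis battery, each checked against an
independent route: hand-computed values, brute-force enumeration, or a
second estimator."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from goalshape.analysis import (
    DegenerateTestError,
    crosstab_chi2,
    fit_weekend_trend,
    goal_summary,
    prepost_table,
    response_rates,
    two_sample_proportion_test,
    weekend_records_from_log,
    wilcoxon_signed_rank,
)
from goalshape.events import Day, MessageEvent, ResponseEvent, Template
from goalshape.screening import score_frame
from test_screening import make_record


def prompt(pid, week, day, template, seq=0, payload=None):
    return MessageEvent(pid, week, day, "17:00", template, payload or {}, seq)


def reply(msg, value, in_window=True):
    return ResponseEvent(
        msg.participant_id, msg.event_id, msg.week_index, msg.day, value,
        received_within_window=in_window,
    )


class TestResponseRates:
    def test_window_rule(self):
        """4 prompts, 2 answered in window, 1 late -> rate 0.5."""
        msgs = [prompt("P0", w, Day.THU, Template.PLAN) for w in (1, 2, 3, 4)]
        events = msgs + [
            reply(msgs[0], True),
            reply(msgs[1], False),
            reply(msgs[2], True, in_window=False),
        ]
        table = response_rates(events, by=("slot_type",))
        row = table.iloc[0]
        assert (row["prompts"], row["responses"], row["rate"]) == (4, 2, 0.5)

    def test_full_compliance_is_rate_one(self):
        msgs = [prompt("P0", 1, Day.SUN, Template.MAX_DRINKS)]
        table = response_rates(msgs + [reply(msgs[0], 3)])
        assert (table["rate"] == 1.0).all()

    def test_duplicate_replies_counted_once(self):
        msg = prompt("P0", 1, Day.THU, Template.PLAN)
        table = response_rates([msg, reply(msg, True), reply(msg, True)])
        assert table["responses"].sum() == 1

    def test_empty_log_gives_empty_table(self):
        assert response_rates([]).empty

    def test_blocks_partition_weeks(self):
        msgs = [prompt("P0", w, Day.THU, Template.PLAN) for w in (-2, 1, 4, 5)]
        table = response_rates(msgs, by=("block",))
        assert sorted(table["block"]) == [0, 1, 2]


class TestGoalSummary:
    def goal_week(self, pid, week, limit, reported, commit=True,
                  confidences=(), above=False):
        g = prompt(pid, week, Day.THU, Template.GOAL_COMMIT, seq=1,
                   payload={"limit": limit, "above_binge": above})
        m = prompt(pid, week, Day.SUN, Template.MAX_DRINKS)
        events = [g, reply(g, commit), m]
        if reported is not None:
            events.append(reply(m, reported))
        for i, c in enumerate(confidences):
            cp = prompt(pid, week, Day.FRI if i == 0 else Day.SAT,
                        Template.CONFIDENCE, seq=3 + i)
            events += [cp, reply(cp, c)]
        return events

    def test_success_two_of_three(self):
        events = (
            self.goal_week("P0", 1, 7, 5)
            + self.goal_week("P0", 2, 7, 7)
            + self.goal_week("P0", 3, 7, 9)
        )
        metrics = goal_summary(events)
        assert (metrics.success.numerator, metrics.success.denominator) == (2, 3)
        assert metrics.commitment.rate == 1.0

    def test_zero_commitments_leaves_success_undefined(self):
        events = self.goal_week("P0", 1, 7, 5, commit=False)
        metrics = goal_summary(events)
        assert metrics.success.denominator == 0
        assert metrics.success.rate is None

    def test_unanswered_sunday_not_evaluated(self):
        events = self.goal_week("P0", 1, 7, None)
        assert goal_summary(events).success.denominator == 0

    def test_confidence_split_uses_weekend_minimum(self):
        events = (
            self.goal_week("P0", 1, 7, 5, confidences=(5, 3))  # min 3 -> low
            + self.goal_week("P0", 2, 7, 9, confidences=(4, 4))  # high
            + self.goal_week("P0", 3, 7, 5)  # no confidence -> excluded
        )
        metrics = goal_summary(events)
        low = metrics.success_by_confidence["low"]
        high = metrics.success_by_confidence["high"]
        assert (low.numerator, low.denominator) == (1, 1)
        assert (high.numerator, high.denominator) == (0, 1)

    def test_above_binge_share_by_week(self):
        events = (
            self.goal_week("P0", 1, 9, 5, above=True)
            + self.goal_week("P1", 1, 4, 5, above=False)
            + self.goal_week("P0", 2, 4, 5, above=False)
        )
        ab = goal_summary(events).above_binge_by_week.set_index("week")
        assert ab.loc[1, "rate"] == 0.5
        assert ab.loc[2, "rate"] == 0.0


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, chi2, p",
        [
            ([[32, 10], [56, 1]], 11.91, 5.6e-4),
            ([[26, 8], [104, 8]], 7.18, 7.4e-3),
        ],
    )
    def test_printed_goal_success_tables(self, table, chi2, p):
        stat, pval = crosstab_chi2(table)
        assert stat == pytest.approx(chi2, abs=0.01)
        assert pval == pytest.approx(p, rel=0.02)

    def test_identical_proportions_give_zero(self):
        assert crosstab_chi2([[10, 10], [10, 10]]) == (0.0, 1.0)

    def test_zero_margin_is_explicitly_undefined(self):
        with pytest.raises(DegenerateTestError):
            crosstab_chi2([[0, 0], [5, 3]])
        with pytest.raises(DegenerateTestError):
            crosstab_chi2([[5, 0], [3, 0]])

    def test_matches_brute_force_expected_counts(self):
        """Pearson X^2 equals the direct sum of (O-E)^2/E over the table."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(1, 31, size=(2, 2)).astype(float)
            stat, _ = crosstab_chi2(t)
            n = t.sum()
            expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
            brute = ((t - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(brute, rel=1e-12)


class TestWilcoxon:
    def test_textbook_example(self):
        """All three differences negative: W+ = 0, exact p = 2/8."""
        w, p = wilcoxon_signed_rank([1, 2, 3], [2, 4, 6])
        assert (w, p) == (0.0, 0.25)

    def test_identical_vectors_undefined(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_swap_flips_statistic_keeps_p(self):
        pre, post = [3, 9, 1, 7, 5], [1, 2, 8, 2, 2]
        w1, p1 = wilcoxon_signed_rank(pre, post)
        w2, p2 = wilcoxon_signed_rank(post, pre)
        assert w1 + w2 == 15  # n(n+1)/2 with n=5
        assert p1 == pytest.approx(p2)

    def test_exact_p_matches_full_enumeration(self):
        """For n <= 8 (ties included), the exact p equals enumeration over
        all 2^n sign assignments of the midranks."""
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            pre = rng.integers(0, 6, size=n).astype(float)
            post = rng.integers(0, 6, size=n).astype(float)
            d = pre - post
            d = d[d != 0]
            if len(d) == 0:
                continue
            ranks = scipy.stats.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            total = ranks.sum()
            count = sum(
                1
                for signs in itertools.product([0, 1], repeat=len(d))
                if abs(sum(r for r, s in zip(ranks, signs) if s) - total / 2)
                >= abs(w_obs - total / 2) - 1e-12
            )
            w, p = wilcoxon_signed_rank(pre, post)
            assert w == pytest.approx(w_obs)
            assert p == pytest.approx(count / 2 ** len(d))

    def test_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(2)
        pre = rng.normal(size=12)
        post = pre + rng.normal(0.4, 1.0, size=12)
        _, p = wilcoxon_signed_rank(pre, post)
        ref = scipy.stats.wilcoxon(pre, post, mode="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(size=60)
        post = pre + rng.normal(0.3, 1.0, size=60)
        _, p = wilcoxon_signed_rank(pre, post)
        ref = scipy.stats.wilcoxon(pre, post, mode="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestProportionTest:
    def test_published_pooled_z_values(self):
        z, p = two_sample_proportion_test(14, 32, 9, 32)
        assert p == pytest.approx(0.19, abs=0.005)
        z, p = two_sample_proportion_test(4, 6, 2, 6)
        assert z == pytest.approx(1.1547, abs=1e-4)
        assert p == pytest.approx(0.248, abs=0.001)

    def test_equal_proportions(self):
        assert two_sample_proportion_test(5, 10, 5, 10) == (0.0, 1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sample_proportion_test(1, 0, 1, 5)
        with pytest.raises(ValueError):
            two_sample_proportion_test(6, 5, 1, 5)


class TestTrendFit:
    def flat_panel(self, n=10, weeks=4, value=5):
        rows = [
            {"participant_id": f"P{i}", "week": w + 1, "max_drinks": value}
            for i in range(n)
            for w in range(weeks)
        ]
        return pd.DataFrame(rows)

    def test_constant_counts_give_zero_slope(self):
        fit = fit_weekend_trend(self.flat_panel())
        assert abs(fit.loc[0, "slope"]) < 0.01
        assert fit.loc[0, "slope_lo"] <= fit.loc[0, "slope"] <= fit.loc[0, "slope_hi"]

    @pytest.mark.parametrize("method", ["random_intercept", "gee"])
    def test_trend_free_symmetric_panel(self, method):
        """Counts symmetric in week carry no trend: slope ~ 0, finite CI."""
        rows = [
            {"participant_id": f"P{i}", "week": w + 1, "max_drinks": v}
            for i in range(10)
            for w, v in enumerate((4, 6, 6, 4))
        ]
        fit = fit_weekend_trend(pd.DataFrame(rows), method=method)
        assert abs(fit.loc[0, "slope"]) < 0.01
        assert np.isfinite(fit.loc[0, "slope_lo"])
        assert fit.loc[0, "slope_lo"] <= fit.loc[0, "slope"] <= fit.loc[0, "slope_hi"]

    def test_small_stratum_skipped_with_warning(self):
        panel = self.flat_panel(n=2)
        with pytest.warns(UserWarning, match="fit skipped"):
            fit = fit_weekend_trend(panel)
        assert fit.empty

    def test_estimators_agree_on_slope(self, small_cohort):
        _, log, truth = small_cohort
        records = weekend_records_from_log(log)
        ri = fit_weekend_trend(records)
        gee = fit_weekend_trend(records, method="gee")
        assert not ri.empty and not gee.empty
        assert ri.loc[0, "slope"] == pytest.approx(gee.loc[0, "slope"], abs=0.05)

    def test_repeated_fits_identical(self, small_cohort):
        _, log, _ = small_cohort
        records = weekend_records_from_log(log)
        a = fit_weekend_trend(records)
        b = fit_weekend_trend(records)
        pd.testing.assert_frame_equal(a, b)


class TestPrepostTable:
    def test_wilcoxon_and_proportion_columns(self):
        base = [
            make_record(participant_id=f"S{i}",
                        ddq_typical=(0, 0, 0, 0, 6, 0, 0),
                        ddq_heavy=(0, 0, 0, 0, 8 + i, 0, 0),
                        byaacq_items=[True] * 10 + [False] * 14)
            for i in range(8)
        ]
        post = [
            make_record(participant_id=f"S{i}",
                        ddq_typical=(0, 0, 0, 0, 2, 0, 0),
                        ddq_heavy=(0, 0, 0, 0, 4, 0, 0),
                        byaacq_items=[True] * 3 + [False] * 21)
            for i in range(8)
        ]
        table = prepost_table(score_frame(base), score_frame(post))
        assert set(table["outcome"]) == {
            "max_weekend_drinks", "any_binge_typical_week",
            "negative_consequences",
        }
        binge = table[table["outcome"] == "any_binge_typical_week"].iloc[0]
        assert binge["baseline"] == "8 (100%)"
        assert binge["followup"] == "0 (0%)"
        drinks = table[table["outcome"] == "max_weekend_drinks"].iloc[0]
        assert drinks["p_value"] < 0.05

    def test_disjoint_ids_rejected(self):
        a = score_frame([make_record(participant_id="A")])
        b = score_frame([make_record(participant_id="B")])
        with pytest.raises(ValueError):
            prepost_table(a, b)
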