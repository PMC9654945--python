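"""Channel screening: summary ANOVA, Duncan letters, correlations, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from growthsense import (
    ChannelSummary,
    ReplicatePanel,
    anova_from_summary,
    discrimination_count,
    duncan_letters,
    enose_loadings,
    pearson_with_stars,
    rank_sensors,
    summarize_panel,
)


def _summary(means, sds, n=5, channel="X"):
    k = len(means)
    return ChannelSummary(
        channel=channel,
        times=np.arange(k, dtype=float),
        means=np.asarray(means, float),
        sds=np.asarray(sds, float),
        ns=np.full(k, n),
    )


class TestSummarize:
    def test_textbook_values(self):
        panel = ReplicatePanel.from_arrays([0.0], np.array([[1.0, 2.0, 3.0]]), "A")
        (s,) = summarize_panel(panel)
        assert s.means[0] == 2.0 and s.sds[0] == 1.0 and s.ns[0] == 3

    def test_zero_noise_gives_zero_sd(self):
        panel = ReplicatePanel.from_arrays(
            [0.0, 1.0], np.array([[2.0, 2.0], [3.0, 3.0]]), "A"
        )
        (s,) = summarize_panel(panel)
        assert np.all(s.sds == 0.0)

    def test_single_replicate_rejected(self):
        panel = ReplicatePanel.from_arrays([0.0, 1.0], np.array([[1.0], [2.0]]), "A")
        with pytest.raises(ValueError, match="fewer than 2 replicates"):
            summarize_panel(panel)

    def test_fixture_sd_matches_configured_noise(self, fixture1):
        cal = fixture1.calibrations["Sweetness"]
        mat = fixture1.sensors.values_matrix("Sweetness")
        sd0 = float(np.std(mat[0], ddof=1))
        # sample sd at n=20 stays within wide chi-square bounds of sigma
        assert 0.5 * cal.noise_sd < sd0 < 1.6 * cal.noise_sd


class TestAnova:
    def test_two_group_hand_example(self):
        """means 0 and 1, sd=1, n=2: SSB = 2(.25)+2(.25) = 1, MSW = 1, F = 1, df (1,2)."""
        res = anova_from_summary(_summary([0.0, 1.0], [1.0, 1.0], n=2))
        assert res.df_between == 1 and res.df_within == 2
        assert res.f_stat == pytest.approx(1.0, abs=1e-12)

    def test_equal_means_give_zero_f(self):
        res = anova_from_summary(_summary([2.0, 2.0, 2.0], [0.5, 0.4, 0.6]))
        assert res.f_stat == 0.0 and res.p_value == 1.0

    def test_degenerate_all_zero_sd(self):
        res = anova_from_summary(_summary([0.0, 1.0], [0.0, 0.0]))
        assert np.isinf(res.f_stat) and res.p_value == 0.0

    def test_matches_raw_replicate_anova(self):
        """Summary reconstruction is exact against scipy on raw replicates."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(3, 8)
            groups = [rng.normal(rng.normal(), 1.0, size=int(rng.integers(3, 12)))
                      for _ in range(k)]
            summary = ChannelSummary(
                channel="raw",
                times=np.arange(k, dtype=float),
                means=np.array([g.mean() for g in groups]),
                sds=np.array([g.std(ddof=1) for g in groups]),
                ns=np.array([len(g) for g in groups]),
            )
            res = anova_from_summary(summary)
            ref = stats.f_oneway(*groups)
            assert res.f_stat == pytest.approx(ref.statistic, abs=1e-10, rel=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_s7_highly_significant(self, enose_summary):
        s7 = ChannelSummary.from_frame(enose_summary, "S7")
        assert anova_from_summary(s7).p_value < 0.01


class TestDuncan:
    def test_forced_separation(self):
        s = _summary([10.0, 0.0], [0.1, 0.1])
        grouping = duncan_letters(s, anova_from_summary(s), 0.05)
        assert sorted(grouping.letters) == ["a", "b"]

    def test_three_groups_close_pair(self):
        """(10, 9.9, 1) with sd 0.1, n=5: critical 2-range q(.95,2,12)*sqrt(0.01/5)
        = 3.082*0.0447 = 0.138 > 0.1, so the top pair shares a letter."""
        s = _summary([10.0, 9.9, 1.0], [0.1, 0.1, 0.1])
        grouping = duncan_letters(s, anova_from_summary(s), 0.05)
        a, b, c = grouping.letters
        assert set(a) & set(b)
        assert not (set(c) & (set(a) | set(b)))

    def test_recomputed_s7_letter_count(self, enose_summary):
        """Reconstruction from the printed S7 means/SDs yields 11 subsets.

        (The published table letters 12 groups; the raw-data MSE behind
        them is not recoverable from the rounded summaries.)
        """
        s7 = ChannelSummary.from_frame(enose_summary, "S7")
        grouping = duncan_letters(s7, anova_from_summary(s7), 0.05)
        assert discrimination_count(grouping) == 11

    def test_letters_are_order_consistent(self, enose_summary):
        """Two times sharing a letter are never separated by a time between them."""
        s2 = ChannelSummary.from_frame(enose_summary, "S2")
        grouping = duncan_letters(s2, anova_from_summary(s2), 0.05)
        order = np.argsort(-s2.means, kind="stable")
        letters_sorted = [grouping.letters[i] for i in order]
        for letter in set("".join(letters_sorted)):
            positions = [i for i, ls in enumerate(letters_sorted) if letter in ls]
            assert positions == list(range(positions[0], positions[-1] + 1))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_never_separates_below_two_group_range(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 10))
        s = _summary(rng.normal(0, 1, k), rng.uniform(0.2, 1.0, k), n=8)
        anova = anova_from_summary(s)
        grouping = duncan_letters(s, anova, 0.05)
        r2 = stats.studentized_range.ppf(0.95, 2, anova.df_within) * np.sqrt(anova.mse / 8)
        for i in range(k):
            for j in range(k):
                if abs(s.means[i] - s.means[j]) < r2:
                    assert set(grouping.letters[i]) & set(grouping.letters[j])

    def test_count_invariant_to_letter_renaming(self):
        assert discrimination_count(("a", "ab", "b")) == 2
        assert discrimination_count(("z", "zy", "y")) == 2
        assert discrimination_count(("a", "a", "a")) == 1


class TestPrintedLetterColumns:
    @pytest.mark.parametrize(
        "channel,expected", [("S1", 7), ("S2", 9), ("S5", 10), ("S7", 12)]
    )
    def test_published_discrimination_counts(self, enose_summary, channel, expected):
        letters = enose_summary.loc[enose_summary.channel == channel, "letters"]
        assert discrimination_count(tuple(letters)) == expected


class TestPearson:
    def test_published_s7_s9_correlation(self, enose_summary):
        s7 = ChannelSummary.from_frame(enose_summary, "S7")
        s9 = ChannelSummary.from_frame(enose_summary, "S9")
        table = pearson_with_stars({"S7": s7.means, "S9": s9.means})
        assert table.r.loc["S7", "S9"] == pytest.approx(0.998, abs=0.002)
        assert table.stars.loc["S7", "S9"] == "**"

    def test_structure(self):
        rng = np.random.default_rng(2)
        table = pearson_with_stars(
            {"a": rng.normal(size=10), "b": rng.normal(size=10), "c": rng.normal(size=10)}
        )
        assert np.allclose(np.diag(table.r), 1.0)
        assert np.allclose(table.r.values, table.r.values.T)

    def test_hand_computed_pair(self):
        table = pearson_with_stars({"x": [1, 2, 3], "y": [2, 4, 5]})
        assert table.r.loc["x", "y"] == pytest.approx(0.98198, abs=1e-5)

    def test_zero_variance_named(self):
        with pytest.raises(ValueError, match="flat"):
            pearson_with_stars({"flat": [1.0, 1.0, 1.0], "y": [1, 2, 3]})


class TestLoadings:
    def test_dominant_variance_channel_leads_pc1(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=12)
        X = pd.DataFrame(
            {"big": 10 * base, "small1": rng.normal(size=12) * 0.1,
             "small2": rng.normal(size=12) * 0.1}
        )
        loadings, fractions = enose_loadings(X)
        assert loadings["PC1"].abs().idxmax() == "big"
        assert fractions[0] > 0.9

    def test_duplicated_channels_get_equal_loadings(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=10)
        X = pd.DataFrame({"a1": a, "a2": a, "b": rng.normal(size=10)})
        loadings, _ = enose_loadings(X)
        assert loadings.loc["a1", "PC1"] == pytest.approx(loadings.loc["a2", "PC1"], abs=1e-10)

    def test_s2_dominates_table_means(self, enose_summary):
        """S2 has by far the widest response range, so it must lead |PC1|."""
        means = enose_summary.pivot(index="time_h", columns="channel", values="mean")
        loadings, _ = enose_loadings(means)
        top2 = loadings["PC1"].abs().sort_values(ascending=False).index[:2]
        assert "S2" in top2


class TestRankSensors:
    def test_constructed_winner(self):
        counts = {"S1": 5, "S3": 9, "S5": 7}
        corrs = {"S1": -0.5, "S3": -0.95, "S5": 0.7}
        loads = {"S1": 0.2, "S3": 0.9, "S5": 0.4}
        assert rank_sensors(counts, corrs, loads)[0] == "S3"

    def test_count_ties_broken_by_correlation(self):
        counts = {"A": 5, "B": 5}
        assert rank_sensors(counts, {"A": -0.9, "B": 0.5}, {"A": 0.1, "B": 0.9})[0] == "A"

    def test_singleton(self):
        assert rank_sensors({"A": 1}, {"A": 0.0}, {"A": 0.0}) == ["A"]

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError):
            rank_sensors({"A": 1, "B": 2}, {"A": 0.5}, {"A": 0.1, "B": 0.2})
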