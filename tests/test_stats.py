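"""Group-level statistics: chi-square, rank comparisons, trends, runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tanlab.stats import (CorrectRun, chi2_2x2, find_correct_runs,
                          mot_binned_magnitudes, mot_trend, rank_compare,
                          region_contrast, sequence_trend)


class TestChi2:
    @pytest.mark.parametrize("resp1, n1, resp2, n2, printed", [
        (51, 114, 23, 86, 6.80),    # cue-responsive TANs across animals
        (14, 52, 27, 38, 17.23),    # Pavlovian cue responses across animals
        (32, 52, 20, 38, 0.71),     # Pavlovian reward responses across animals
        (29, 68, 22, 46, 0.298),    # region contrast, first animal
        (14, 52, 11, 34, 0.294),    # region contrast, second animal
    ])
    def test_reproduces_published_statistics(self, resp1, n1, resp2, n2, printed):
        res = chi2_2x2(resp1, n1 - resp1, resp2, n2 - resp2)
        assert res.chi2 == pytest.approx(printed, abs=0.02)
        assert res.df == 1

    def test_proportional_table_is_zero(self):
        assert chi2_2x2(10, 10, 20, 20).chi2 == 0.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(0, 0, 5, 5)

    @settings(derandomize=True, max_examples=60)
    @given(st.tuples(*[st.integers(1, 60)] * 4))
    def test_matches_expected_count_formula(self, counts):
        """Pearson formula sum (O-E)^2/E over the four cells (independent
        oracle for the determinant closed form)."""
        a, b, c, d = counts
        obs = np.array([[a, b], [c, d]], float)
        rows = obs.sum(1, keepdims=True)
        cols = obs.sum(0, keepdims=True)
        exp = rows @ cols / obs.sum()
        oracle = ((obs - exp) ** 2 / exp).sum()
        assert chi2_2x2(a, b, c, d).chi2 == pytest.approx(oracle, rel=1e-9)

    def test_yates_reduces_statistic(self):
        plain = chi2_2x2(51, 63, 23, 63).chi2
        corrected = chi2_2x2(51, 63, 23, 63, yates=True).chi2
        assert corrected < plain


class TestRankCompare:
    def test_paired_identical_is_null(self):
        x = np.arange(10.0)
        res = rank_compare(x, x, paired=True)
        assert res.z == 0.0 and res.p == 1.0

    def test_two_sided_p_symmetric_in_group_exchange(self):
        rng = np.random.default_rng(61)
        x, y = rng.normal(0, 1, 30), rng.normal(0.7, 1, 25)
        a, b = rank_compare(x, y), rank_compare(y, x)
        assert a.p == pytest.approx(b.p)
        assert a.z == pytest.approx(-b.z)

    def test_power_at_one_sd_shift(self):
        rng = np.random.default_rng(62)
        x = rng.normal(0, 1, 100)
        y = rng.normal(1, 1, 100)
        assert rank_compare(x, y).p < 0.001

    def test_paired_detects_consistent_shift(self):
        rng = np.random.default_rng(63)
        x = rng.normal(0, 1, 40)
        res = rank_compare(x, x + 0.8 + rng.normal(0, 0.3, 40), paired=True)
        assert res.p < 0.01 and res.paired

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_compare([1, 2], [1, 2, 3], paired=True)


class TestTrends:
    def test_monotone_relation_has_rho_one(self):
        mots = [1.0, 1.2, 1.5, 1.9, 2.4]
        mags = [-10, -8, -5, -3, -1]
        res = mot_trend(mags, mots)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.slope > 0

    def test_constant_magnitudes_flat(self):
        res = mot_trend([5.0] * 6, [1, 2, 3, 4, 5, 6])
        assert res.slope == 0.0 and res.spearman_rho == 0.0

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            mot_trend([1, 2, 3], [2, 2, 2])

    def test_slope_recovery_under_noise(self):
        rng = np.random.default_rng(64)
        bias = []
        for _ in range(20):
            mots = rng.uniform(1.3, 3.3, 500)
            mags = -40 + 12.0 * (mots - mots.mean()) + rng.normal(0, 25, 500)
            bias.append(mot_trend(mags, mots).slope - 12.0)
        assert abs(np.mean(bias)) < 0.2 * 12.0


class TestMotBins:
    def test_single_bin_when_all_close(self):
        df = mot_binned_magnitudes([-5, -6, -7], [1.55, 1.6, 1.9], bin_ms=500)
        assert len(df) == 1 and df.iloc[0]["n"] == 3

    def test_boundary_goes_to_upper_bin(self):
        df = mot_binned_magnitudes([-5.0], [1.5], bin_ms=500)
        assert df.iloc[0]["bin_start_s"] == pytest.approx(1.5)

    def test_bin_means_of_linear_relation_are_linear(self):
        mots = np.linspace(0.05, 2.95, 600)
        mags = -60 + 10 * mots
        df = mot_binned_magnitudes(mags, mots, bin_ms=500)
        centers = (df["bin_start_s"] + df["bin_end_s"]) / 2
        np.testing.assert_allclose(df["mean"], -60 + 10 * centers, atol=0.5)


class TestCorrectRuns:
    @staticmethod
    def runs_tuples(outcomes, min_len=5):
        return [(r.start_index, r.end_index)
                for r in find_correct_runs(outcomes, min_len=min_len)]

    def test_simple_run_at_start(self):
        assert self.runs_tuples("CCCCCE") == [(1, 5)]

    def test_length_four_is_too_short(self):
        assert self.runs_tuples("CCCC") == []

    def test_example_block_with_two_sequences(self):
        """A 45-trial block correct exactly on trials 7-14 and 25-34."""
        outcomes = ["E"] * 45
        for i in list(range(7, 15)) + list(range(25, 35)):
            outcomes[i - 1] = "C"
        assert self.runs_tuples(outcomes) == [(7, 14), (25, 34)]

    def test_run_lengths(self):
        runs = find_correct_runs("ECCCCCCCE")
        assert runs[0].length == 7

    def test_works_on_trial_events(self, small_session):
        runs = find_correct_runs(small_session.trials)
        for r in runs:
            for idx in r.positions():
                assert small_session.trials[idx - 1].outcome == "correct"


class TestSequenceTrend:
    def test_exact_line_single_run(self):
        run = CorrectRun(1, 5)
        tm = pd.DataFrame({"trial_index": [1, 2, 3, 4, 5],
                           "magnitude": [-10, -20, -30, -40, -50]})
        res = sequence_trend([run], tm)
        assert res.slope == pytest.approx(-10.0)
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_constant_magnitudes_flat(self):
        run = CorrectRun(1, 6)
        tm = pd.DataFrame({"trial_index": range(1, 7), "magnitude": [-5.0] * 6})
        res = sequence_trend([run], tm)
        assert res.slope == 0.0

    def test_no_runs_rejected(self):
        with pytest.raises(ValueError):
            sequence_trend([], pd.DataFrame({"trial_index": [], "magnitude": []}))


class TestRegionContrast:
    def _table(self, mags_assoc, mags_motor):
        rows = []
        for i, m in enumerate(mags_assoc):
            rows.append({"unit_id": f"a{i}", "region": "associative",
                         "interval": "long", "magnitude": m})
        for i, m in enumerate(mags_motor):
            rows.append({"unit_id": f"m{i}", "region": "motor",
                         "interval": "long", "magnitude": m})
        return pd.DataFrame(rows)

    def test_identical_populations_null(self):
        mags = list(np.linspace(-60, -10, 12))
        res = region_contrast(self._table(mags, mags), "long")
        assert res["magnitude"].p == 1.0

    def test_frequency_test_uses_published_counts(self):
        table = self._table(np.zeros(68), np.zeros(46))
        responsive = {f"a{i}": i < 29 for i in range(68)}
        responsive.update({f"m{i}": i < 22 for i in range(46)})
        res = region_contrast(table, "long", responsive=responsive)
        assert res["frequency"].chi2 == pytest.approx(0.298, abs=0.02)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="motor"):
            region_contrast(self._table([1.0, 2.0], []), "long")
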