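"""Sliding-window pause detection: counting, rank test, scan, windows."""

from itertools import combinations

import numpy as np
import pytest

from tanlab import simulate
from tanlab.detect import (QuantWindow, ScanConfig, aligned_counts,
                           derive_quant_window, preset_quant_window, scan,
                           stepwise_test)
from tanlab.simulate import BehaviorParams, ResponseSpec, UnitParams


class TestAlignedCounts:
    def test_spike_at_window_end_not_counted(self):
        counts = aligned_counts([10.3], [10.0], (100, 300))
        assert counts[0] == 0
        assert aligned_counts([10.2999], [10.0], (100, 300))[0] == 1

    def test_spike_at_window_start_counted(self):
        assert aligned_counts([10.1], [10.0], (100, 300))[0] == 1

    def test_silenced_window_counts_zero(self, trials_60, default_config):
        unit = UnitParams(baseline_rate=6.0,
                          responses=[ResponseSpec("cue_on", 100, 200, 0.0)],
                          seed=41)
        st = simulate.generate_spike_train(unit, trials_60, default_config)
        cues = np.array([t.t_cue_on for t in trials_60])
        assert aligned_counts(st.times, cues, (100, 300)).sum() == 0

    def test_additivity_over_adjacent_windows(self):
        rng = np.random.default_rng(42)
        spikes = np.sort(rng.uniform(0, 100, 2000))
        events = np.arange(5.0, 95.0, 6.0)
        left = aligned_counts(spikes, events, (0, 150))
        right = aligned_counts(spikes, events, (150, 400))
        union = aligned_counts(spikes, events, (0, 400))
        np.testing.assert_array_equal(left + right, union)

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError):
            aligned_counts([1.0], [], (0, 100))


class TestStepwiseTest:
    def test_identical_rates_not_significant(self):
        counts = np.arange(30) % 4
        res = stepwise_test(counts, counts, 500, 500)
        assert res.p == 1.0 and res.statistic == 0.0
        assert res.direction == "none"

    def test_maximal_separation_is_significant_decrease(self):
        res = stepwise_test(np.full(40, 3), np.zeros(40), 500, 100)
        assert res.significant and res.direction == "decrease"

    def test_scale_invariance_of_rank_statistic(self):
        rng = np.random.default_rng(7)
        c, t = rng.poisson(3, 50), rng.poisson(2, 50)
        a = stepwise_test(c, t, 500, 100)
        b = stepwise_test(c * 10, t * 10, 500, 100)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_p_matches_brute_force_enumeration_small_n(self):
        """Tie-free small samples: returned p equals the exact two-sided p
        from enumerating every group assignment."""
        rng = np.random.default_rng(8)
        for n1, n2 in [(3, 3), (4, 6), (5, 5), (8, 7)]:
            x = np.round(rng.normal(10.0, 1.0, size=n1), 6)
            y = np.round(rng.normal(10.8, 1.0, size=n2), 6)
            res = stepwise_test(y, x, 1000, 1000)  # control=y, test=x
            pooled = np.concatenate([x, y])
            obs_u = sum((xi > yj) for xi in x for yj in y)
            us = []
            for idx in combinations(range(n1 + n2), n1):
                grp = pooled[list(idx)]
                rest = np.delete(pooled, list(idx))
                us.append(sum((a > b) for a in grp for b in rest))
            us = np.array(us)
            lo = np.mean(us <= obs_u)
            hi = np.mean(us >= obs_u)
            p_exact = min(1.0, 2 * min(lo, hi))
            assert res.p == pytest.approx(p_exact, abs=1e-12)


class TestScan:
    def test_recovers_injected_pause_onset(self, paused_train):
        st, cues = paused_train
        res = scan(st.times, cues, ScanConfig())
        assert res.direction == "decrease"
        assert 70 <= res.pause_onset_ms <= 170
        assert res.pause_offset_ms >= res.pause_onset_ms + 100

    def test_short_run_is_not_a_pause(self, paused_train):
        """Requiring more consecutive steps than the pause can span yields no
        detection, while the default does detect it."""
        st, cues = paused_train
        wide = scan(st.times, cues, ScanConfig(min_run=40))
        assert wide.pause_onset_ms is None and wide.direction == "none"

    def test_min_run_rule_blocks_four_step_runs(self):
        """A synthetic significance pattern of only 4 consecutive steps must
        not be reported as a pause under min_run=5."""
        from tanlab import detect as d

        flags = np.zeros(91, bool)
        flags[10:14] = True
        assert d._first_run(flags, 5) is None
        flags[14] = True
        assert d._first_run(flags, 5) == (10, 14)

    def test_rebound_reported_as_increase(self, trials_60, default_config):
        unit = UnitParams(baseline_rate=6.0,
                          responses=[ResponseSpec("cue_on", 100, 250, 3.0)],
                          seed=43)
        st = simulate.generate_spike_train(unit, trials_60, default_config)
        cues = np.array([t.t_cue_on for t in trials_60])
        res = scan(st.times, cues, ScanConfig())
        assert res.direction == "increase"
        assert res.increase_onset_ms is not None

    def test_span_shorter_than_min_run_rejected(self):
        with pytest.raises(ValueError, match="min_run"):
            ScanConfig(scan_span_ms=(0, 130)).step_starts()

    def test_detection_power_monotone_in_depth_and_trials(self, default_config):
        """Deeper pauses and more trials never detect less often (3x3 grid)."""
        rates = {}
        for factor in (0.1, 0.5, 0.9):
            for n in (20, 60, 180):
                hits = 0
                for seed in range(8):
                    trials = simulate.generate_behavior(
                        default_config,
                        BehaviorParams(n_trials=n, seed=900 + seed,
                                       p_no_response=0.0))
                    unit = UnitParams(
                        baseline_rate=6.0,
                        responses=[ResponseSpec("cue_on", 120, 180, factor)],
                        seed=seed)
                    st = simulate.generate_spike_train(unit, trials,
                                                       default_config)
                    cues = np.array([t.t_cue_on for t in trials])
                    hits += scan(st.times, cues,
                                 ScanConfig()).pause_onset_ms is not None
                rates[(factor, n)] = hits / 8
        for n in (20, 60, 180):
            assert rates[(0.1, n)] >= rates[(0.5, n)] >= rates[(0.9, n)]
        for factor in (0.1, 0.5):
            assert rates[(factor, 180)] >= rates[(factor, 20)]


class TestQuantWindows:
    def test_mean_method(self):
        w = derive_quant_window([100, 140, 180], [300, 340, 380], "mean")
        assert (w.start_ms, w.end_ms) == (140, 340)
        assert w.provenance == "derived"

    def test_single_pause_window_is_that_pause(self):
        w = derive_quant_window([120], [300])
        assert (w.start_ms, w.end_ms) == (120, 300)

    def test_central_coverage_brackets_mean(self):
        on = np.linspace(80, 160, 21)
        off = np.linspace(280, 360, 21)
        w = derive_quant_window(on, off, "central_coverage", coverage=0.9)
        assert w.start_ms < on.mean() < off.mean() < w.end_ms

    def test_preset_window_bypasses_derivation(self):
        w = preset_quant_window("monkeyC", "cue_on", "short")
        assert (w.start_ms, w.end_ms) == (93.0, 309.0)
        assert w.provenance == "published"

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            derive_quant_window([], [])

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            QuantWindow(300, 100)
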