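"""Sliding-window pause detection.

A 100 ms test window is advanced in 10 ms steps from an alignment event
(cue onset, movement onset, target contact, or reward). At each step the
per-trial firing rates in the test window are compared against the per-trial
rates in the 500 ms immediately preceding cue onset (the control period) with
a Dunn-type rank test at p < 0.01. A *pause* is reported when at least five
consecutive steps show a significant decrease; its onset is the start of the
first such step and its offset the end of the last consecutive significant
step. Significant increases are tracked symmetrically for rebound reporting.

The control period is always pre-cue, also for movement- and reward-aligned
scans, so every scan is referenced to the same baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rank import mann_whitney
from .session import Session, ALIGN_EVENTS


@dataclass
class ScanConfig:
    align_event: str = "cue_on"
    window_ms: float = 100.0
    step_ms: float = 10.0
    control_ms: tuple[float, float] = (-500.0, 0.0)
    alpha: float = 0.01
    min_run: int = 5
    scan_span_ms: tuple[float, float] = (0.0, 1000.0)
    method: str = "auto"          # p-value method of the per-step rank test
    bonferroni: bool = False      # adjust per-step p across steps

    def __post_init__(self):
        if not (self.window_ms > 0 and self.step_ms > 0):
            raise ValueError("window_ms and step_ms must be positive")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.align_event not in ALIGN_EVENTS:
            raise ValueError(f"unknown align_event {self.align_event!r}")

    def step_starts(self) -> np.ndarray:
        lo, hi = self.scan_span_ms
        n = int(np.floor((hi - lo - self.window_ms) / self.step_ms)) + 1
        if n < self.min_run:
            raise ValueError(
                f"scan span {self.scan_span_ms} yields {max(n, 0)} steps, "
                f"fewer than min_run={self.min_run}")
        return lo + self.step_ms * np.arange(n)


def aligned_counts(spike_times, event_times, window_ms) -> np.ndarray:
    """Spike count per event in the half-open window
    ``[event + start_ms, event + end_ms)`` (milliseconds)."""
    ev = np.asarray(event_times, float)
    if ev.size == 0:
        raise ValueError("event list is empty")
    t = np.asarray(spike_times, float)
    lo = ev + window_ms[0] / 1000.0
    hi = ev + window_ms[1] / 1000.0
    return (np.searchsorted(t, hi, side="left")
            - np.searchsorted(t, lo, side="left")).astype(int)


def aligned_rate(spike_times, event_times, window_ms) -> float:
    """Mean firing rate (spikes/s) over all events in the aligned window."""
    dur_s = (window_ms[1] - window_ms[0]) / 1000.0
    counts = aligned_counts(spike_times, event_times, window_ms)
    return float(counts.mean() / dur_s)


@dataclass
class StepTest:
    statistic: float
    p: float
    significant: bool
    direction: str  # decrease | increase | none


def stepwise_test(control_counts, test_counts,
                  control_dur_ms: float = 500.0, test_dur_ms: float = 100.0,
                  alpha: float = 0.01, method: str = "auto") -> StepTest:
    """Compare per-trial test-window rates against control-period rates.

    Counts are converted to rates before ranking (the rank test is invariant
    to this common rescaling; the contract fixes rates for reporting).
    """
    c = np.asarray(control_counts, float) / (control_dur_ms / 1000.0)
    t = np.asarray(test_counts, float) / (test_dur_ms / 1000.0)
    z, p = mann_whitney(t, c, method=method)
    sig = p < alpha
    direction = "none"
    if sig:
        direction = "decrease" if z < 0 else "increase"
    return StepTest(statistic=z, p=p, significant=sig, direction=direction)


@dataclass
class SlidingWindowResult:
    step_starts: np.ndarray
    rates: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    sig_decrease: np.ndarray
    sig_increase: np.ndarray
    pause_onset_ms: Optional[float]
    pause_offset_ms: Optional[float]
    increase_onset_ms: Optional[float]
    increase_offset_ms: Optional[float]
    direction: str
    n_trials: int

    @property
    def has_pause(self) -> bool:
        return self.pause_onset_ms is not None


def _first_run(flags: np.ndarray, min_run: int) -> Optional[tuple[int, int]]:
    """(start, end) indices (inclusive) of the first maximal run of True flags
    with length >= min_run, else None."""
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                return i, j
            i = j + 1
        i += 1
    return None


def scan(spike_times, event_times, config: ScanConfig,
         control_event_times=None) -> SlidingWindowResult:
    """Run the sliding-window test over the scan span.

    ``control_event_times`` are the cue-onset times defining the pre-cue
    control period; they default to ``event_times`` (cue-aligned scan).
    """
    if control_event_times is None:
        control_event_times = event_times
    starts = config.step_starts()
    # Segment the control period into window-length sub-windows so control
    # and test counts share the same discrete support; ranking 500 ms counts
    # directly against 100 ms counts is biased toward spurious decreases.
    lo, hi = config.control_ms
    n_seg = max(int((hi - lo) // config.window_ms), 1)
    control = np.concatenate([
        aligned_counts(spike_times, control_event_times,
                       (lo + k * config.window_ms,
                        lo + (k + 1) * config.window_ms))
        for k in range(n_seg)])
    control_dur = config.window_ms

    n_steps = len(starts)
    rates = np.empty(n_steps)
    stats = np.empty(n_steps)
    ps = np.empty(n_steps)
    for i, s in enumerate(starts):
        counts = aligned_counts(spike_times, event_times,
                                (s, s + config.window_ms))
        rates[i] = counts.mean() / (config.window_ms / 1000.0)
        st = stepwise_test(control, counts, control_dur, config.window_ms,
                           alpha=config.alpha, method=config.method)
        stats[i] = st.statistic
        ps[i] = min(1.0, st.p * n_steps) if config.bonferroni else st.p
    sig = ps < config.alpha
    sig_dec = sig & (stats < 0)
    sig_inc = sig & (stats > 0)

    def bounds(flags):
        run = _first_run(flags, config.min_run)
        if run is None:
            return None, None
        i, j = run
        return float(starts[i]), float(starts[j] + config.window_ms)

    p_on, p_off = bounds(sig_dec)
    i_on, i_off = bounds(sig_inc)
    direction = "decrease" if p_on is not None else (
        "increase" if i_on is not None else "none")
    return SlidingWindowResult(
        step_starts=starts, rates=rates, statistics=stats, p_values=ps,
        sig_decrease=sig_dec, sig_increase=sig_inc,
        pause_onset_ms=p_on, pause_offset_ms=p_off,
        increase_onset_ms=i_on, increase_offset_ms=i_off,
        direction=direction, n_trials=len(np.asarray(event_times)))


@dataclass
class QuantWindow:
    """Fixed ms window after an alignment event for magnitude rating."""
    start_ms: float
    end_ms: float
    provenance: str = "derived"  # published | derived

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise ValueError("window start must precede end")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.start_ms, self.end_ms)


#: published fixed quantification windows (ms after event) per monkey x event
#: x interval, derived from average pause onset/offset times.
PRESET_QUANT_WINDOWS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("monkeyC", "cue_on", "short"): (93.0, 309.0),
    ("monkeyC", "cue_on", "long"): (93.0, 309.0),
    ("monkeyD", "cue_on", "short"): (127.0, 313.0),
    ("monkeyD", "cue_on", "long"): (211.0, 418.0),
    ("monkeyC", "reward", "short"): (139.0, 369.0),
    ("monkeyC", "reward", "long"): (139.0, 369.0),
    ("monkeyD", "reward", "short"): (194.0, 391.0),
    ("monkeyD", "reward", "long"): (194.0, 391.0),
}


def preset_quant_window(monkey: str, align_event: str, interval: str) -> QuantWindow:
    key = (monkey, align_event, interval)
    if key not in PRESET_QUANT_WINDOWS:
        raise KeyError(f"no preset quantification window for {key}")
    lo, hi = PRESET_QUANT_WINDOWS[key]
    return QuantWindow(lo, hi, provenance="published")


def derive_quant_window(onsets_ms: Sequence[float], offsets_ms: Sequence[float],
                        method: str = "mean",
                        coverage: float = 0.9) -> QuantWindow:
    """Pool detected pause onsets/offsets into one fixed window.

    ``mean`` takes the average onset and offset; ``central_coverage`` takes the
    central ``coverage`` quantile range so the window includes most of the
    detected onset and offset times.
    """
    on = np.asarray(onsets_ms, float)
    off = np.asarray(offsets_ms, float)
    if on.size == 0 or off.size == 0:
        raise ValueError("need at least one detected pause")
    if method == "mean":
        return QuantWindow(float(on.mean()), float(off.mean()))
    if method == "central_coverage":
        lo_q = (1.0 - coverage) / 2.0
        return QuantWindow(float(np.quantile(on, lo_q)),
                           float(np.quantile(off, 1.0 - lo_q)))
    raise ValueError(f"unknown method {method!r}")


def detect_session(session: Session, align_event: str = "cue_on",
                   config: Optional[ScanConfig] = None,
                   by_interval: bool = True) -> pd.DataFrame:
    """Scan every unit of a session; one row per unit x interval.

    Reward-aligned scans use rewarded trials only (reward exists only there).
    Control is the pre-cue period of the same trials entering the scan.
    """
    if config is None:
        config = ScanConfig(align_event=align_event)
    else:
        config = ScanConfig(**{**config.__dict__, "align_event": align_event})
    intervals = ["short", "long"] if by_interval else [None]
    rows = []
    for unit in session.units:
        spikes = session.spike_train(unit.unit_id).times
        for interval in intervals:
            trials = session.trials_where(interval=interval)
            trials = [t for t in trials
                      if getattr(t, "t_" + align_event if align_event != "cue_on"
                                 else "t_cue_on") is not None]
            if not trials:
                continue
            events = session.event_times(align_event, trials)
            cues = session.event_times("cue_on", trials)
            res = scan(spikes, events, config, control_event_times=cues)
            rows.append({
                "unit_id": unit.unit_id, "align_event": align_event,
                "interval": interval or "all",
                "pause_onset_ms": res.pause_onset_ms,
                "pause_offset_ms": res.pause_offset_ms,
                "direction": res.direction, "n_trials": res.n_trials,
            })
    return pd.DataFrame(rows, columns=["unit_id", "align_event", "interval",
                                       "pause_onset_ms", "pause_offset_ms",
                                       "direction", "n_trials"])
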