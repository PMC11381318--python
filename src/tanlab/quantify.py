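"""Response-magnitude quantification and population activity curves.

Magnitude is the signed percent change of the mean aligned firing rate in a
fixed quantification window relative to the pre-cue baseline rate,

    magnitude = 100 x (window_rate - baseline_rate) / baseline_rate,

negative for pauses. It is rated for every unit and condition irrespective of
whether the unit was individually significant, and feeds all group-level
statistics. Population curves are across-unit means (+/- SEM) of trial-averaged
rates in contiguous 10 ms bins, optionally Gaussian-smoothed for region
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import baseline_rate as _control_rate
from .detect import QuantWindow, aligned_counts, aligned_rate, preset_quant_window
from .session import Session, TrialEvents

CONTROL_MS = (-500.0, 0.0)


def magnitude(spike_times, event_times, window, baseline: float) -> float:
    """Signed percent change of aligned window rate vs baseline rate."""
    if not baseline > 0:
        raise ValueError("magnitude undefined for zero baseline rate")
    bounds = window.bounds if isinstance(window, QuantWindow) else tuple(window)
    rate = aligned_rate(spike_times, event_times, bounds)
    return 100.0 * (rate - baseline) / baseline


def resolve_windows(session: Session, align_event: str,
                    windows: Optional[dict] = None) -> dict[str, QuantWindow]:
    """Quantification window per interval for this session's monkey.

    ``windows`` may map interval -> (start_ms, end_ms) to override; otherwise
    the published per-monkey presets are used (falling back to the monkey of
    the first unit).
    """
    out = {}
    for interval in ("short", "long"):
        if windows and interval in windows:
            w = windows[interval]
            out[interval] = w if isinstance(w, QuantWindow) else QuantWindow(*w)
        else:
            monkey = session.units[0].monkey if session.units else "monkeyC"
            out[interval] = preset_quant_window(monkey, align_event, interval)
    return out


def magnitude_table(session: Session, align_event: str = "cue_on",
                    windows: Optional[dict] = None,
                    unit_ids: Optional[Sequence[str]] = None,
                    rewarded_only: Optional[bool] = None) -> pd.DataFrame:
    """One row per unit x interval with baseline, window rate and magnitude.

    For reward-aligned quantification only rewarded trials are included (the
    default); conditions with zero trials are omitted. The baseline is the
    pre-cue control rate of the condition's own trials.
    """
    if rewarded_only is None:
        rewarded_only = align_event == "reward"
    win = resolve_windows(session, align_event, windows)
    ids = unit_ids if unit_ids is not None else [u.unit_id for u in session.units]
    rows = []
    for uid in ids:
        unit = session.unit(uid)
        spikes = session.spike_train(uid)
        for interval in ("short", "long"):
            trials = session.trials_where(interval=interval)
            if rewarded_only:
                trials = [t for t in trials if t.t_reward is not None]
            trials = [t for t in trials if _event_time(t, align_event) is not None]
            if not trials:
                continue
            events = session.event_times(align_event, trials)
            cues = session.event_times("cue_on", trials)
            base = _control_rate(spikes, cues, CONTROL_MS)
            if base <= 0:
                continue
            w = win[interval]
            rows.append({
                "unit_id": uid, "monkey": unit.monkey, "region": unit.region,
                "label": unit.label, "align_event": align_event,
                "interval": interval,
                "baseline_rate": base,
                "window_rate": aligned_rate(spikes.times, events, w.bounds),
                "magnitude": magnitude(spikes.times, events, w, base),
                "n_trials": len(trials),
            })
    return pd.DataFrame(rows, columns=["unit_id", "monkey", "region", "label",
                                       "align_event", "interval",
                                       "baseline_rate", "window_rate",
                                       "magnitude", "n_trials"])


def _event_time(trial: TrialEvents, event: str) -> Optional[float]:
    return getattr(trial, "t_cue_on" if event == "cue_on" else "t_" + event)


def trial_magnitudes(session: Session, unit_id: str, align_event: str,
                     window, trials: Optional[Sequence[TrialEvents]] = None
                     ) -> pd.DataFrame:
    """Single-trial magnitudes (one row per trial, n_trials = 1 each).

    The single-trial window rate is compared against the unit's session-wide
    pre-cue baseline; noisier than the across-trial magnitude but needed for
    the movement-timing and correct-run trend analyses.
    """
    spikes = session.spike_train(unit_id)
    pool = session.trials if trials is None else list(trials)
    pool = [t for t in pool if _event_time(t, align_event) is not None]
    if not pool:
        return pd.DataFrame(columns=["unit_id", "trial_index", "interval",
                                     "mot", "magnitude"])
    cues = session.event_times("cue_on", pool)
    base = _control_rate(spikes, cues, CONTROL_MS)
    if not base > 0:
        raise ValueError(f"unit {unit_id}: zero baseline rate")
    bounds = window.bounds if isinstance(window, QuantWindow) else tuple(window)
    dur_s = (bounds[1] - bounds[0]) / 1000.0
    events = session.event_times(align_event, pool)
    counts = aligned_counts(spikes.times, events, bounds)
    rows = []
    for t, c in zip(pool, counts):
        rate = c / dur_s
        mot = (t.t_bar_release - t.t_cue_on) if t.t_bar_release is not None else None
        rows.append({"unit_id": unit_id, "trial_index": t.trial_index,
                     "interval": t.interval, "mot": mot,
                     "magnitude": 100.0 * (rate - base) / base})
    return pd.DataFrame(rows)


@dataclass
class PopulationCurve:
    """Across-unit mean +/- SEM of trial-averaged binned rates."""
    bin_starts_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_units: int
    smoothing: str = "none"


def population_curve(session: Session, unit_ids: Sequence[str],
                     align_event: str = "cue_on",
                     span_ms: tuple[float, float] = (-500.0, 1000.0),
                     bin_ms: float = 10.0,
                     smooth_sigma_bins: Optional[float] = None,
                     trials: Optional[Sequence[TrialEvents]] = None
                     ) -> PopulationCurve:
    """Population activity around an event in non-overlapping ``bin_ms`` bins.

    Each unit contributes its trial-averaged rate per bin; the curve is the
    across-unit mean with SEM. ``smooth_sigma_bins`` applies a normalized
    Gaussian kernel (sigma in bins) to each unit's curve before averaging.
    """
    if len(unit_ids) == 0:
        raise ValueError("empty unit set")
    pool = session.trials if trials is None else list(trials)
    pool = [t for t in pool if _event_time(t, align_event) is not None]
    events = session.event_times(align_event, pool)
    edges = np.arange(span_ms[0], span_ms[1] + bin_ms / 2, bin_ms)
    starts = edges[:-1]
    per_unit = np.empty((len(unit_ids), len(starts)))
    for i, uid in enumerate(unit_ids):
        t = session.spike_train(uid).times
        counts = np.zeros(len(starts))
        for e in events:
            rel = (t[(t >= e + span_ms[0] / 1000.0)
                     & (t < e + span_ms[1] / 1000.0)] - e) * 1000.0
            counts += np.histogram(rel, bins=edges)[0]
        per_unit[i] = counts / len(events) / (bin_ms / 1000.0)
        if smooth_sigma_bins:
            from scipy.ndimage import gaussian_filter1d
            per_unit[i] = gaussian_filter1d(per_unit[i], smooth_sigma_bins,
                                            mode="nearest")
    mean = per_unit.mean(axis=0)
    sem = (per_unit.std(axis=0, ddof=1) / np.sqrt(len(unit_ids))
           if len(unit_ids) > 1 else np.zeros_like(mean))
    return PopulationCurve(starts, mean, sem, len(unit_ids),
                           smoothing="none" if not smooth_sigma_bins
                           else f"gaussian(sigma={smooth_sigma_bins} bins)")
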