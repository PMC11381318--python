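"""Synthetic session generator.

Emulates the statistical structure the downstream analyses assume:

* scalar-timing behavior — movement onset times (MOTs) drawn per interval from
  a truncated normal whose SD is ``weber_fraction`` times its mean, so the
  coefficient of variation is constant across intervals;
* task scheduling — pseudorandom cue side balanced within blocks of 10, with
  an error trial enqueueing an immediate repetition of the same side;
* tonic TAN firing — a gamma-interval renewal process (shape = firing
  regularity; shape 2 is more regular than Poisson) whose rate is modulated
  multiplicatively by event-locked response windows (pause: factor < 1,
  rebound: factor > 1). Modulation is realized by time rescaling: the renewal
  process runs homogeneously in operational time and is mapped through the
  inverse cumulative modulation, which preserves the renewal structure and
  makes the expected aligned-window rate exactly ``baseline × factor``;
* low-rate phasic PAN firing with event-locked activations;
* the Pavlovian variant, where reward follows the cue at a fixed delay and no
  action is required.

Pause depths can be coupled linearly to the trial's MOT or to the trial's
position within a run of consecutive correct trials, to emulate movement-timing
and reward-prediction effects on response magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import behavior as _behavior
from .session import (PRE_CUE_HOLD_S, Session, SpikeTrain, TaskConfig,
                      TrialEvents, Unit)


@dataclass
class BehaviorParams:
    """Parameters of the behavioral generator (seconds unless noted)."""

    n_trials: int = 200
    mot_mean_short: float = 1.7
    mot_mean_long: float = 2.7
    weber_fraction: float = 0.15
    p_no_response: float = 0.0
    movement_time_mean: float = 0.4
    movement_time_sd: float = 0.08
    seed: int = 0

    def validate(self, config: TaskConfig) -> None:
        if not (0 <= self.p_no_response <= 1):
            raise ValueError("p_no_response must be in [0, 1]")
        if self.weber_fraction < 0:
            raise ValueError("weber_fraction must be >= 0")
        horizon = config.trial_duration - PRE_CUE_HOLD_S
        for name in ("mot_mean_short", "mot_mean_long"):
            m = getattr(self, name)
            if not m > 0:
                raise ValueError(f"{name} must be positive")
            if config.task_kind == "TET" and m >= horizon:
                raise ValueError(
                    f"{name}={m} not feasible: movement would fall past trial end")


@dataclass
class ResponseSpec:
    """One event-locked firing-rate modulation window.

    ``rate_factor`` multiplies the baseline rate over
    ``[latency, latency + duration)`` ms after ``align_event`` (< 1: pause,
    > 1: rebound/activation). ``interval``/``outcome`` restrict the spec to
    matching trials. ``mot_coupling_slope`` (percent magnitude per second)
    tilts the per-trial depth linearly around the mean MOT of applicable
    trials; ``sequence_coupling_slope`` (percent per consecutive-correct
    position) tilts it with the trial's 1-based position in a correct run.
    """

    align_event: str = "cue_on"
    latency_ms: float = 100.0
    duration_ms: float = 200.0
    rate_factor: float = 0.25
    interval: Optional[str] = None
    outcome: Optional[str] = None
    mot_coupling_slope: float = 0.0
    sequence_coupling_slope: float = 0.0

    def __post_init__(self):
        if self.latency_ms < 0:
            raise ValueError("latency_ms must be >= 0")
        if not self.duration_ms > 0:
            raise ValueError("duration_ms must be > 0")
        if self.rate_factor < 0:
            raise ValueError("rate_factor must be >= 0")

    def applies(self, trial: TrialEvents) -> bool:
        if self.interval is not None and trial.interval != self.interval:
            return False
        if self.outcome is not None and trial.outcome != self.outcome:
            return False
        return True


@dataclass
class UnitParams:
    """Parameters of one synthetic unit's spike-train generator."""

    kind: str = "TAN"
    baseline_rate: float = 6.0
    firing_regularity: float = 2.0
    spike_width: float = 900.0
    responses: list[ResponseSpec] = field(default_factory=list)
    seed: int = 0
    unit_id: str = "u0"
    monkey: str = ""
    region: str = "motor"

    def __post_init__(self):
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be > 0")
        if self.firing_regularity < 1:
            raise ValueError("firing_regularity must be >= 1")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lower: float = 0.0) -> np.ndarray:
    """Normal(mean, sd) truncated below at ``lower``, by rejection."""
    if sd == 0:
        return np.full(size, max(mean, lower))
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def _balanced_sides(rng: np.random.Generator, n: int) -> list[str]:
    """Pseudorandom left/right sequence balanced within blocks of 10."""
    out: list[str] = []
    while len(out) < n:
        block = ["left"] * 5 + ["right"] * 5
        rng.shuffle(block)
        out.extend(block)
    return out[:n]


def generate_behavior(config: TaskConfig, params: BehaviorParams) -> list[TrialEvents]:
    """Generate ``params.n_trials`` chronological trials with classified outcomes.

    An uncorrect trial (including excluded no-response trials) causes the same
    cue side to be repeated on the next trial, as the task rules prescribe.
    """
    params.validate(config)
    rng = np.random.default_rng(params.seed)
    n = params.n_trials
    sides = _balanced_sides(rng, n)

    mot_sd = {iv: params.weber_fraction * m for iv, m in
              (("short", params.mot_mean_short), ("long", params.mot_mean_long))}
    mot_mean = {"short": params.mot_mean_short, "long": params.mot_mean_long}
    mots = {iv: _truncated_normal(rng, mot_mean[iv], mot_sd[iv], n, lower=1e-3)
            for iv in ("short", "long")}
    move_times = _truncated_normal(rng, params.movement_time_mean,
                                   params.movement_time_sd, n, lower=0.02)
    no_resp = rng.random(n) < params.p_no_response

    trials: list[TrialEvents] = []
    queue_pos = 0
    prev_side: Optional[str] = None
    repeat = False
    for i in range(n):
        if repeat and prev_side is not None:
            side = prev_side
        else:
            side = sides[queue_pos]
            queue_pos += 1
        interval = config.cue_map[side]
        t_cue = i * config.trial_duration + PRE_CUE_HOLD_S
        trial = TrialEvents(trial_index=i + 1, cue_side=side,
                            interval=interval, t_cue_on=t_cue)
        if config.task_kind == "PCT":
            trial.t_reward = t_cue + config.threshold(interval)
            trial.outcome = "correct"
        elif no_resp[i]:
            trial.outcome = "excluded"
        else:
            trial.t_bar_release = t_cue + mots[interval][i]
            trial.t_target_contact = trial.t_bar_release + move_times[i]
            trial.outcome = _behavior.classify_outcome(trial, config)
            if trial.outcome == "correct":
                trial.t_reward = trial.t_target_contact
        trials.append(trial)
        repeat = trial.outcome != "correct"
        prev_side = side
    return trials


# ---------------------------------------------------------------------------
# spike-train generation


def _correct_run_positions(trials: Sequence[TrialEvents]) -> dict[int, int]:
    """1-based position of each correct trial within its streak of correct
    trials; non-correct trials map to 1 (no sequence adjustment)."""
    pos: dict[int, int] = {}
    streak = 0
    for t in trials:
        streak = streak + 1 if t.outcome == "correct" else 0
        pos[t.trial_index] = max(streak, 1)
    return pos


def _modulation_segments(unit: UnitParams, trials: Sequence[TrialEvents],
                         config: TaskConfig) -> list[tuple[float, float, float]]:
    """(t0, t1, factor) windows on the session clock, one per response x trial."""
    segments: list[tuple[float, float, float]] = []
    run_pos = _correct_run_positions(trials)
    for spec in unit.responses:
        applicable = [t for t in trials if spec.applies(t)]
        mots = [m for t in applicable
                if (m := _behavior.compute_mot(t)) is not None]
        mot_ref = float(np.mean(mots)) if mots else 0.0
        for t in applicable:
            event_t = {"cue_on": t.t_cue_on, "bar_release": t.t_bar_release,
                       "target_contact": t.t_target_contact,
                       "reward": t.t_reward}[spec.align_event]
            if event_t is None:
                continue
            mag = (spec.rate_factor - 1.0) * 100.0
            if spec.mot_coupling_slope and t.t_bar_release is not None:
                mag += spec.mot_coupling_slope * (
                    _behavior.compute_mot(t) - mot_ref)
            if spec.sequence_coupling_slope:
                mag += spec.sequence_coupling_slope * (run_pos[t.trial_index] - 1)
            factor = 1.0 + mag / 100.0
            factor = max(factor, 0.0)
            if spec.rate_factor <= 1.0:
                factor = min(factor, 1.0)
            segments.append((event_t + spec.latency_ms / 1000.0,
                             event_t + (spec.latency_ms + spec.duration_ms) / 1000.0,
                             factor))
    return segments


def _piecewise_factor(segments, t_end: float):
    """Collapse overlapping windows to a piecewise-constant factor on [0, t_end].

    Returns (breaks, factors): ``factors[i]`` applies on
    ``[breaks[i], breaks[i+1])``; overlaps multiply.
    """
    pts = {0.0, t_end}
    for t0, t1, _ in segments:
        pts.add(min(max(t0, 0.0), t_end))
        pts.add(min(max(t1, 0.0), t_end))
    breaks = np.array(sorted(pts))
    factors = np.ones(len(breaks) - 1)
    for t0, t1, f in segments:
        i0 = np.searchsorted(breaks, max(t0, 0.0))
        i1 = np.searchsorted(breaks, min(t1, t_end))
        factors[i0:i1] *= f
    return breaks, factors


def generate_spike_train(unit: UnitParams, trials: Sequence[TrialEvents],
                         config: TaskConfig,
                         rng: Optional[np.random.Generator] = None) -> SpikeTrain:
    """Simulate one unit's spike train over the whole session.

    A homogeneous gamma renewal process (shape ``firing_regularity``, mean rate
    ``baseline_rate``) is generated in operational time and warped through the
    inverse cumulative modulation, so regions with factor 0 are exactly silent
    and the long-run rate in a factor-f window is ``f × baseline_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(unit.seed)
    if not trials:
        return SpikeTrain(unit.unit_id, np.empty(0))
    t_end = max(t.t_cue_on for t in trials) + config.trial_duration

    breaks, factors = _piecewise_factor(
        _modulation_segments(unit, trials, config), t_end)
    lam = np.concatenate([[0.0], np.cumsum(factors * np.diff(breaks))])
    total_op = lam[-1]

    rate, shape = unit.baseline_rate, unit.firing_regularity
    scale = 1.0 / (shape * rate)
    burn = 20.0 / rate  # discard a stationarizing prefix of ~20 mean ISIs
    arrivals: list[np.ndarray] = []
    t_op, target = 0.0, total_op + burn
    while t_op < target:
        chunk = rng.gamma(shape, scale, size=max(64, int(rate * (target - t_op) * 1.5)))
        cum = t_op + np.cumsum(chunk)
        arrivals.append(cum)
        t_op = cum[-1]
    a = np.concatenate(arrivals) - burn
    a = a[(a > 0) & (a < total_op)]

    idx = np.searchsorted(lam, a, side="right") - 1
    idx = np.clip(idx, 0, len(factors) - 1)
    slope = factors[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        times = breaks[idx] + np.where(slope > 0, (a - lam[idx]) / slope, 0.0)
    return SpikeTrain(unit.unit_id, np.sort(times))


# ---------------------------------------------------------------------------
# presets


#: per-monkey population parameters: baseline-rate and spike-width moments of
#: the two unit classes, task thresholds, MOT calibration, and the fractions
#: of TANs with cue/reward pause responses.
PRESETS: dict[str, dict] = {
    "monkeyC_TET": dict(
        monkey="monkeyC", task_kind="TET", short_threshold=1.3, long_threshold=2.3,
        mot_offset=0.40,
        tan_rate=(5.94, 1.94), tan_width=(905.0, 169.0),
        pan_rate=(1.47, 1.91), pan_width=(758.0, 80.0),
        p_cue_pause=0.45, p_reward_pause=0.25, p_rebound=0.12),
    "monkeyD_TET": dict(
        monkey="monkeyD", task_kind="TET", short_threshold=1.0, long_threshold=2.0,
        mot_offset=0.225,
        tan_rate=(4.82, 1.72), tan_width=(1220.0, 194.0),
        pan_rate=(1.83, 1.92), pan_width=(656.0, 114.0),
        p_cue_pause=0.27, p_reward_pause=0.36, p_rebound=0.12),
    "monkeyC_PCT": dict(
        monkey="monkeyC", task_kind="PCT", short_threshold=1.0, long_threshold=2.0,
        mot_offset=0.40,
        tan_rate=(5.94, 1.94), tan_width=(905.0, 169.0),
        pan_rate=(1.47, 1.91), pan_width=(758.0, 80.0),
        p_cue_pause=0.27, p_reward_pause=0.62, p_rebound=0.12),
    "monkeyD_PCT": dict(
        monkey="monkeyD", task_kind="PCT", short_threshold=1.0, long_threshold=2.0,
        mot_offset=0.225,
        tan_rate=(4.82, 1.72), tan_width=(1220.0, 194.0),
        pan_rate=(1.83, 1.92), pan_width=(656.0, 114.0),
        p_cue_pause=0.71, p_reward_pause=0.53, p_rebound=0.12),
}

#: fraction of cue-responsive TANs whose pause occurs for only one interval
P_INTERVAL_SELECTIVE = 0.86


def preset_config(preset: str) -> TaskConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    return TaskConfig(task_kind=p["task_kind"],
                      short_threshold=p["short_threshold"],
                      long_threshold=p["long_threshold"])


def preset_behavior_params(preset: str, n_trials: int = 200,
                           seed: int = 0) -> BehaviorParams:
    p = PRESETS[preset]
    return BehaviorParams(
        n_trials=n_trials,
        mot_mean_short=p["short_threshold"] + p["mot_offset"],
        mot_mean_long=p["long_threshold"] + p["mot_offset"],
        weber_fraction=0.15, p_no_response=0.02, seed=seed)


def _preset_unit_params(preset: str, index: int,
                        rng: np.random.Generator, seed: int) -> UnitParams:
    p = PRESETS[preset]
    is_tan = rng.random() < 0.6
    kind = "TAN" if is_tan else "PAN"
    rate_mu, rate_sd = p["tan_rate"] if is_tan else p["pan_rate"]
    width_mu, width_sd = p["tan_width"] if is_tan else p["pan_width"]
    baseline = float(_truncated_normal(rng, rate_mu, rate_sd, 1, lower=0.3)[0])
    width = float(_truncated_normal(rng, width_mu, width_sd, 1, lower=100.0)[0])
    region = "associative" if rng.random() < 0.6 else "motor"

    responses: list[ResponseSpec] = []
    if is_tan:
        if rng.random() < p["p_cue_pause"]:
            interval = None
            if rng.random() < P_INTERVAL_SELECTIVE:
                interval = "short" if rng.random() < 0.5 else "long"
            lat = float(rng.normal(110.0, 15.0))
            dur = float(rng.normal(190.0, 25.0))
            responses.append(ResponseSpec("cue_on", max(lat, 20.0),
                                          max(dur, 80.0), 0.25,
                                          interval=interval))
            if rng.random() < p["p_rebound"]:
                responses.append(ResponseSpec(
                    "cue_on", max(lat, 20.0) + max(dur, 80.0), 150.0, 1.6,
                    interval=interval))
        if rng.random() < p["p_reward_pause"]:
            lat = float(rng.normal(150.0, 20.0))
            dur = float(rng.normal(210.0, 25.0))
            responses.append(ResponseSpec("reward", max(lat, 20.0),
                                          max(dur, 80.0), 0.30))
    else:
        if rng.random() < 0.5:
            responses.append(ResponseSpec("cue_on", 50.0, 300.0, 3.0))

    return UnitParams(kind=kind, baseline_rate=baseline,
                      firing_regularity=2.0 if is_tan else 1.0,
                      spike_width=width, responses=responses, seed=seed,
                      unit_id=f"{p['monkey']}_{kind}_{index:03d}",
                      monkey=p["monkey"], region=region)


def generate_session(preset: str = "monkeyC_TET", n_units: int = 30,
                     n_trials: int = 200, seed: int = 0,
                     behavior_params: Optional[BehaviorParams] = None,
                     unit_params: Optional[Sequence[UnitParams]] = None) -> Session:
    """Generate a complete valid session for one of the presets.

    Deterministic given (preset, n_units, n_trials, seed). ``behavior_params``
    and ``unit_params`` override the preset's defaults for custom designs.
    """
    config = preset_config(preset)
    ss = np.random.SeedSequence(seed)
    beh_seed, pop_seed, *unit_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2 + max(n_units, 1))]

    if behavior_params is None:
        behavior_params = preset_behavior_params(preset, n_trials, seed=beh_seed)
    trials = generate_behavior(config, behavior_params)

    if unit_params is None:
        pop_rng = np.random.default_rng(pop_seed)
        unit_params = [_preset_unit_params(preset, i, pop_rng, unit_seeds[i])
                       for i in range(n_units)]

    units, spikes = [], []
    for up in unit_params:
        units.append(Unit(unit_id=up.unit_id, monkey=up.monkey,
                          region=up.region, baseline_rate=up.baseline_rate,
                          spike_width=up.spike_width, label=up.kind))
        spikes.append(generate_spike_train(up, trials, config))

    return Session(config=config, trials=trials, units=units, spikes=spikes,
                   metadata={"preset": preset, "seed": seed,
                             "n_units": n_units, "n_trials": n_trials})
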