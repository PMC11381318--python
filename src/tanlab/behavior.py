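"""Behavioral analysis: movement onset times, trial outcomes, timing summaries.

The movement onset time (MOT) is the interval from cue onset to bar release.
A trial is correctly timed when the bar is released after the interval's time
threshold but no later than a limited hold beyond it, and the target is touched
within the movement time limit after release. Releases before the threshold are
underestimation errors. Trials with no release or no target contact are
excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .session import Session, TaskConfig, TrialEvents, INTERVALS, OUTCOMES


def compute_mot(trial: TrialEvents) -> Optional[float]:
    """Movement onset time in seconds, or ``None`` if the bar was not released."""
    if trial.t_bar_release is None:
        return None
    return trial.t_bar_release - trial.t_cue_on


def classify_outcome(trial: TrialEvents, config: TaskConfig) -> str:
    """Apply the task rules to one trial and return its outcome category.

    A release at exactly the threshold counts as correct (the waiting period
    has elapsed). In the Pavlovian task no action is required, so every trial
    is correct.
    """
    if config.task_kind == "PCT":
        return "correct"
    if trial.t_bar_release is None or trial.t_target_contact is None:
        return "excluded"
    mot = trial.t_bar_release - trial.t_cue_on
    threshold = config.threshold(trial.interval)
    if mot < threshold:
        return "underestimation"
    if mot > threshold + config.limited_hold:
        return "late_release"
    if trial.t_target_contact - trial.t_bar_release > config.movement_time_limit:
        return "slow_movement"
    return "correct"


def classify_session(session: Session) -> Session:
    """Fill the ``outcome`` field of every trial in place; returns the session."""
    for t in session.trials:
        t.outcome = classify_outcome(t, session.config)
        if t.outcome != "correct" and session.config.task_kind == "TET":
            t.t_reward = None
    return session


@dataclass
class BehaviorSummary:
    """Per-interval MOT moments, per-block percent correct, outcome counts."""

    mot_mean: dict[str, float]
    mot_sd: dict[str, float]
    mot_cv: dict[str, float]
    percent_correct_blocks: dict[str, list[float]]
    percent_correct: dict[str, float]
    percent_correct_overall: float
    n_by_outcome: dict[str, int]
    n_trials: int

    def as_dict(self) -> dict:
        return {
            "mot_mean": self.mot_mean,
            "mot_sd": self.mot_sd,
            "mot_cv": self.mot_cv,
            "percent_correct_blocks": self.percent_correct_blocks,
            "percent_correct": self.percent_correct,
            "percent_correct_overall": self.percent_correct_overall,
            "n_by_outcome": self.n_by_outcome,
            "n_trials": self.n_trials,
        }


def summarize_behavior(session: Session, block_size: int = 40) -> BehaviorSummary:
    """Summarize timing performance over a session with classified outcomes.

    MOT moments are taken over non-excluded trials of each interval. Percent
    correct is computed among non-excluded trials, overall and per block of
    ``block_size`` consecutive trials (chronological, non-overlapping).
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    trials = session.trials
    if any(t.outcome is None for t in trials):
        classify_session(session)

    mot_mean, mot_sd, mot_cv, pct, blocks = {}, {}, {}, {}, {}
    for interval in INTERVALS:
        sel = [t for t in trials if t.interval == interval and t.outcome != "excluded"]
        mots = np.array([compute_mot(t) for t in sel if t.t_bar_release is not None])
        if mots.size:
            mot_mean[interval] = float(np.mean(mots))
            mot_sd[interval] = float(np.std(mots, ddof=1)) if mots.size > 1 else 0.0
            mot_cv[interval] = mot_sd[interval] / mot_mean[interval]
        n_ok = sum(t.outcome == "correct" for t in sel)
        pct[interval] = 100.0 * n_ok / len(sel) if sel else float("nan")
        blocks[interval] = []

    for i in range(0, len(trials), block_size):
        block = trials[i:i + block_size]
        for interval in INTERVALS:
            sel = [t for t in block if t.interval == interval and t.outcome != "excluded"]
            if sel:
                blocks[interval].append(
                    100.0 * sum(t.outcome == "correct" for t in sel) / len(sel))

    included = [t for t in trials if t.outcome != "excluded"]
    overall = (100.0 * sum(t.outcome == "correct" for t in included) / len(included)
               if included else float("nan"))
    counts = {o: sum(t.outcome == o for t in trials) for o in OUTCOMES}
    return BehaviorSummary(mot_mean, mot_sd, mot_cv, blocks, pct, overall,
                           counts, len(trials))


def scalar_property_check(mots_short: Sequence[float],
                          mots_long: Sequence[float]) -> dict[str, float]:
    """Descriptive statistics of the scalar (Weber) timing property.

    Under scalar timing the SD of produced intervals grows proportionally with
    their mean, so ``sd_ratio`` approximately equals ``mean_ratio`` and the two
    coefficients of variation match.
    """
    s = np.asarray(mots_short, float)
    l = np.asarray(mots_long, float)
    if s.size < 2 or l.size < 2:
        raise ValueError("need at least 2 observations per interval")
    ms, ml = s.mean(), l.mean()
    if ms == 0 or ml == 0:
        raise ValueError("degenerate zero-mean input")
    sds, sdl = s.std(ddof=1), l.std(ddof=1)
    return {
        "cv_short": float(sds / ms),
        "cv_long": float(sdl / ml),
        "sd_ratio": float(sdl / sds) if sds > 0
        else (float("nan") if sdl == 0 else float("inf")),
        "mean_ratio": float(ml / ms),
    }
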