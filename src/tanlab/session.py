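"""Session data model and on-disk format.

A *session* is one recording context: the task configuration, the chronological
list of trials with their event times, the recorded units with their metadata,
and one spike train per unit. All event and spike times are absolute seconds on
a single session clock starting at 0; alignment to task events is always
computed downstream, never stored.

On disk a session is a directory with three plain-text files:

* ``manifest.json`` — task configuration, unit metadata, free-form metadata
* ``trials.csv``    — one row per trial
* ``spikes.csv``    — long format, one row per spike (unit_id, time_s)

The writer is deterministic: sorted JSON keys, fixed 6-decimal formatting of
seconds, so two saves of the same session are byte-identical.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

TASK_KINDS = ("TET", "PCT")
SIDES = ("left", "right")
INTERVALS = ("short", "long")
REGIONS = ("motor", "associative")
LABELS = ("TAN", "PAN", "unclassified")
OUTCOMES = ("correct", "underestimation", "late_release", "slow_movement", "excluded")
ALIGN_EVENTS = ("cue_on", "bar_release", "target_contact", "reward")

#: seconds between trial start (hand on bar) and cue onset
PRE_CUE_HOLD_S = 1.0


class SessionValidationError(ValueError):
    """Raised when a session violates its structural invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("session validation failed:\n" + "\n".join(self.violations))


@dataclass
class TaskConfig:
    """Timing-task configuration.

    ``short_threshold``/``long_threshold`` are the minimum waiting periods
    (seconds from cue onset) associated with the two cue locations. In the
    Pavlovian variant (PCT) they are the fixed cue→reward delays instead.
    """

    task_kind: str = "TET"
    short_threshold: float = 1.3
    long_threshold: float = 2.3
    cue_duration: float = 0.5
    trial_duration: float = 6.0
    limited_hold: float = 2.0
    movement_time_limit: float = 1.0
    cue_map: dict = field(default_factory=lambda: {"left": "short", "right": "long"})

    def threshold(self, interval: str) -> float:
        if interval == "short":
            return self.short_threshold
        if interval == "long":
            return self.long_threshold
        raise ValueError(f"unknown interval {interval!r}")

    def side_for(self, interval: str) -> str:
        for side, iv in self.cue_map.items():
            if iv == interval:
                return side
        raise ValueError(f"cue_map has no side for interval {interval!r}")


@dataclass
class TrialEvents:
    """Event times (session clock, seconds) and labels for one trial.

    Missing events (e.g. no bar release on an excluded trial) are ``None``.
    ``outcome`` is derived by :mod:`tanlab.behavior`; it may be ``None`` on a
    freshly generated or imported session.
    """

    trial_index: int
    cue_side: str
    interval: str
    t_cue_on: float
    t_bar_release: Optional[float] = None
    t_target_contact: Optional[float] = None
    t_reward: Optional[float] = None
    outcome: Optional[str] = None


@dataclass
class Unit:
    """One recorded unit and its metadata (spike width in microseconds)."""

    unit_id: str
    monkey: str = ""
    region: str = "motor"
    baseline_rate: float = 0.0
    spike_width: float = 1.0
    label: str = "unclassified"
    ap_position_mm: Optional[float] = None


@dataclass
class SpikeTrain:
    """Sorted spike times (seconds, session clock) for one unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)


@dataclass
class Session:
    config: TaskConfig
    trials: list[TrialEvents]
    units: list[Unit]
    spikes: list[SpikeTrain]
    metadata: dict = field(default_factory=dict)

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def spike_train(self, unit_id: str) -> SpikeTrain:
        for s in self.spikes:
            if s.unit_id == unit_id:
                return s
        raise KeyError(unit_id)

    def event_times(
        self, event: str, trials: Optional[Sequence[TrialEvents]] = None
    ) -> np.ndarray:
        """Times of ``event`` over ``trials`` (default: all), skipping absences."""
        if event not in ALIGN_EVENTS:
            raise ValueError(f"unknown align event {event!r}")
        attr = "t_" + event if event != "cue_on" else "t_cue_on"
        pool = self.trials if trials is None else trials
        out = [getattr(t, attr) for t in pool]
        return np.array([t for t in out if t is not None], dtype=float)

    def trials_where(self, interval=None, outcome=None) -> list[TrialEvents]:
        out = self.trials
        if interval is not None:
            out = [t for t in out if t.interval == interval]
        if outcome is not None:
            out = [t for t in out if t.outcome == outcome]
        return out

    @property
    def end_time(self) -> float:
        if not self.trials:
            return 0.0
        return max(t.t_cue_on for t in self.trials) + self.config.trial_duration


# ---------------------------------------------------------------------------
# validation


def validate_session(session: Session) -> list[str]:
    """Check every structural invariant; return a list of human-readable
    violations (empty iff the session is valid). Never raises."""
    v: list[str] = []
    cfg = session.config

    if cfg.task_kind not in TASK_KINDS:
        v.append(f"config: unknown task_kind {cfg.task_kind!r}")
    for name in ("short_threshold", "long_threshold", "cue_duration",
                 "trial_duration", "limited_hold", "movement_time_limit"):
        if not getattr(cfg, name) > 0:
            v.append(f"config: {name} must be positive")
    if not (0 < cfg.short_threshold < cfg.long_threshold < cfg.trial_duration):
        v.append("config: need 0 < short_threshold < long_threshold < trial_duration")
    if sorted(cfg.cue_map.values()) != ["long", "short"]:
        v.append("config: cue_map must map the two sides onto short and long")

    expected = None
    prev_cue = -math.inf
    for t in session.trials:
        tag = f"trial {t.trial_index}"
        if expected is None:
            expected = t.trial_index
        if t.trial_index != expected:
            v.append(f"{tag}: indices not contiguous (expected {expected})")
        expected = t.trial_index + 1
        if t.cue_side not in SIDES:
            v.append(f"{tag}: bad cue_side {t.cue_side!r}")
        if t.interval not in INTERVALS:
            v.append(f"{tag}: bad interval {t.interval!r}")
        if t.outcome is not None and t.outcome not in OUTCOMES:
            v.append(f"{tag}: bad outcome {t.outcome!r}")
        if t.t_cue_on <= prev_cue:
            v.append(f"{tag}: trials not chronological")
        prev_cue = t.t_cue_on
        if t.t_bar_release is not None and not (t.t_cue_on < t.t_bar_release):
            v.append(f"{tag}: t_bar_release not after t_cue_on")
        if t.t_target_contact is not None:
            if t.t_bar_release is None or not (t.t_bar_release < t.t_target_contact):
                v.append(f"{tag}: t_target_contact not after t_bar_release")
        if t.outcome is not None and cfg.task_kind == "TET":
            if (t.t_reward is not None) != (t.outcome == "correct"):
                v.append(f"{tag}: t_reward present iff outcome is correct")

    seen_units: dict[str, int] = {}
    for u in session.units:
        tag = f"unit {u.unit_id}"
        seen_units[u.unit_id] = seen_units.get(u.unit_id, 0) + 1
        if u.baseline_rate < 0:
            v.append(f"{tag}: baseline_rate must be >= 0")
        if not u.spike_width > 0:
            v.append(f"{tag}: spike_width must be > 0")
        if u.region not in REGIONS:
            v.append(f"{tag}: bad region {u.region!r}")
        if u.label not in LABELS:
            v.append(f"{tag}: bad label {u.label!r}")
    for uid, n in seen_units.items():
        if n > 1:
            v.append(f"unit {uid}: duplicated {n} times")

    span = session.end_time
    for s in session.spikes:
        tag = f"spike train {s.unit_id}"
        if seen_units.get(s.unit_id, 0) != 1:
            v.append(f"{tag}: unit_id does not match exactly one unit")
        t = s.times
        if t.size and np.any(np.diff(t) < 0):
            v.append(f"{tag}: spike times not sorted")
        if t.size and (t[0] < 0 or t[-1] > span + 1e-9):
            v.append(f"{tag}: spike times outside session span [0, {span:.6f}]")
    return v


def _require_valid(session: Session) -> None:
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)


# ---------------------------------------------------------------------------
# serialization helpers

def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.6f}"


def _parse(s: str) -> Optional[float]:
    return None if s == "" else float(s)


_TRIAL_COLS = ("trial_index", "cue_side", "interval", "t_cue_on",
               "t_bar_release", "t_target_contact", "t_reward", "outcome")


def save_session(session: Session, path) -> Path:
    """Write ``session`` to directory ``path`` (created if needed).

    Output is byte-stable for a given session: keys sorted, all seconds
    rendered with 6 decimal places.
    """
    _require_valid(session)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    cfg = session.config
    manifest = {
        "task": {
            "task_kind": cfg.task_kind,
            "short_threshold": round(cfg.short_threshold, 6),
            "long_threshold": round(cfg.long_threshold, 6),
            "cue_duration": round(cfg.cue_duration, 6),
            "trial_duration": round(cfg.trial_duration, 6),
            "limited_hold": round(cfg.limited_hold, 6),
            "movement_time_limit": round(cfg.movement_time_limit, 6),
            "cue_map": cfg.cue_map,
        },
        "units": [
            {
                "unit_id": u.unit_id,
                "monkey": u.monkey,
                "region": u.region,
                "baseline_rate": round(u.baseline_rate, 6),
                "spike_width": round(u.spike_width, 6),
                "label": u.label,
                "ap_position_mm": None if u.ap_position_mm is None
                else round(u.ap_position_mm, 6),
            }
            for u in session.units
        ],
        "metadata": session.metadata,
    }
    (path / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")

    with open(path / "trials.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_TRIAL_COLS)
        for t in session.trials:
            w.writerow([t.trial_index, t.cue_side, t.interval, _fmt(t.t_cue_on),
                        _fmt(t.t_bar_release), _fmt(t.t_target_contact),
                        _fmt(t.t_reward), t.outcome or ""])

    with open(path / "spikes.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["unit_id", "time_s"])
        for s in session.spikes:
            for t in s.times:
                w.writerow([s.unit_id, f"{t:.6f}"])
    return path


def load_session(path) -> Session:
    """Read a session directory written by :func:`save_session`.

    Raises ``FileNotFoundError`` for missing files and
    :class:`SessionValidationError` if invariants are violated.
    """
    path = Path(path)
    for name in ("manifest.json", "trials.csv", "spikes.csv"):
        if not (path / name).exists():
            raise FileNotFoundError(path / name)

    manifest = json.loads((path / "manifest.json").read_text())
    task = manifest["task"]
    config = TaskConfig(
        task_kind=task["task_kind"],
        short_threshold=task["short_threshold"],
        long_threshold=task["long_threshold"],
        cue_duration=task["cue_duration"],
        trial_duration=task["trial_duration"],
        limited_hold=task["limited_hold"],
        movement_time_limit=task["movement_time_limit"],
        cue_map=dict(task["cue_map"]),
    )
    units = [
        Unit(unit_id=u["unit_id"], monkey=u.get("monkey", ""),
             region=u.get("region", "motor"),
             baseline_rate=u.get("baseline_rate", 0.0),
             spike_width=u.get("spike_width", 1.0),
             label=u.get("label", "unclassified"),
             ap_position_mm=u.get("ap_position_mm"))
        for u in manifest["units"]
    ]

    trials: list[TrialEvents] = []
    with open(path / "trials.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            trials.append(TrialEvents(
                trial_index=int(row["trial_index"]),
                cue_side=row["cue_side"],
                interval=row["interval"],
                t_cue_on=float(row["t_cue_on"]),
                t_bar_release=_parse(row["t_bar_release"]),
                t_target_contact=_parse(row["t_target_contact"]),
                t_reward=_parse(row["t_reward"]),
                outcome=row["outcome"] or None,
            ))

    by_unit: dict[str, list[float]] = {}
    with open(path / "spikes.csv", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            by_unit.setdefault(row["unit_id"], []).append(float(row["time_s"]))
    spikes = [SpikeTrain(uid, np.array(ts)) for uid, ts in by_unit.items()]

    session = Session(config=config, trials=trials, units=units,
                      spikes=spikes, metadata=manifest.get("metadata", {}))
    _require_valid(session)
    return session
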