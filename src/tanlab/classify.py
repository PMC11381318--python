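"""Electrophysiological unit classification.

Tonically active neurons (TANs, putative cholinergic interneurons) fire
regularly at ~5-6 spikes/s with broad spikes; phasically active neurons
(PANs, projection neurons) fire below ~2 spikes/s with narrower spikes. The
classifier thresholds baseline rate and spike width, with an unclassified
band between the class cut-offs. Task responsiveness is deliberately NOT a
classification criterion, so downstream pause detection stays independent of
how units were labelled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .detect import aligned_counts
from .session import Session, SpikeTrain


@dataclass
class ClassifierRule:
    """Decision thresholds: rate in spikes/s, width in microseconds.

    Defaults are midpoints between the reported class means of the monkey C
    population (TAN 5.94 sp/s / 905 us vs PAN 1.47 sp/s / 758 us); the
    monkey D preset uses its own width midpoint because the two animals'
    width distributions differ strongly.
    """

    min_tan_rate: float = 3.5
    max_pan_rate: float = 2.5
    min_tan_width: float = 830.0
    max_pan_width: float = 830.0

    def __post_init__(self):
        if self.max_pan_rate > self.min_tan_rate:
            raise ValueError("max_pan_rate must not exceed min_tan_rate")


#: per-monkey presets; widths are midpoints of the reported class means
PRESET_RULES = {
    "monkeyC": ClassifierRule(3.5, 2.5, 830.0, 830.0),
    "monkeyD": ClassifierRule(3.5, 2.5, 938.0, 938.0),
}


def baseline_rate(spikes: SpikeTrain, cue_times,
                  control_window=(-500.0, 0.0)) -> float:
    """Firing rate (spikes/s) over the pre-cue control period of all trials:
    total spikes in the half-open window across trials / total control time."""
    import numpy as np

    cue_times = np.asarray(cue_times, float)
    if cue_times.size == 0:
        raise ValueError("need at least one trial")
    dur_s = (control_window[1] - control_window[0]) / 1000.0
    if dur_s <= 0:
        raise ValueError("zero or negative control time")
    counts = aligned_counts(spikes.times, cue_times, control_window)
    return float(counts.sum() / (dur_s * cue_times.size))


def classify_unit(rate: float, width: float, rule: ClassifierRule) -> str:
    """TAN / PAN / unclassified from baseline rate and spike width."""
    if rate >= rule.min_tan_rate and width >= rule.min_tan_width:
        return "TAN"
    if rate <= rule.max_pan_rate and width <= rule.max_pan_width:
        return "PAN"
    return "unclassified"


def classify_session(session: Session, rule: ClassifierRule | None = None,
                     overwrite_baseline: bool = True) -> dict[str, str]:
    """Measure each unit's control-period rate and classify it.

    Returns {unit_id: label}; also updates ``Unit.label`` (and
    ``Unit.baseline_rate`` unless ``overwrite_baseline`` is False).
    """
    cue_times = session.event_times("cue_on")
    labels = {}
    for unit in session.units:
        rule_u = rule if rule is not None else PRESET_RULES.get(
            unit.monkey, ClassifierRule())
        rate = baseline_rate(session.spike_train(unit.unit_id), cue_times)
        label = classify_unit(rate, unit.spike_width, rule_u)
        labels[unit.unit_id] = label
        unit.label = label
        if overwrite_baseline:
            unit.baseline_rate = rate
    return labels
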