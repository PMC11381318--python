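"""End-to-end pipeline: simulate -> behavior -> classify -> detect -> quantify
-> stats, with every stage writing its output to disk so any stage can be
rerun in isolation. Deterministic under a fixed seed."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, classify, detect, quantify, simulate, stats
from .session import Session, load_session, save_session


@dataclass
class RunConfig:
    preset: Optional[str] = "monkeyC_TET"
    session_dir: Optional[str] = None   # load instead of simulate
    out_dir: str = "tanlab_run"
    seed: int = 0
    n_units: int = 30
    n_trials: int = 200
    block_size: int = 40
    alpha: float = 0.01
    min_run: int = 5
    stages: tuple[str, ...] = ("simulate", "behavior", "classify",
                               "detect", "quantify", "stats")

    def validate(self) -> None:
        known = {"simulate", "behavior", "classify", "detect", "quantify", "stats"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if "stats" in self.stages and "quantify" not in self.stages:
            raise ValueError("stage 'stats' requires stage 'quantify'")
        if self.preset is None and self.session_dir is None:
            raise ValueError("need either a preset or a session_dir")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, log=None) -> dict:
    """Run the configured stages; returns the report dict written to
    ``report.json`` in the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name):
        return name in config.stages

    def _log(msg):
        if log:
            log(msg)

    t0 = time.time()
    try:
        if stage("simulate") and config.session_dir is None:
            session = simulate.generate_session(
                config.preset, n_units=config.n_units,
                n_trials=config.n_trials, seed=config.seed)
            save_session(session, out / "session")
        else:
            session = load_session(config.session_dir or out / "session")
        _log(f"session ready ({len(session.trials)} trials, "
             f"{len(session.units)} units) [{time.time() - t0:.1f}s]")
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    if stage("behavior"):
        try:
            summary = behavior.summarize_behavior(session, config.block_size)
            (out / "behavior.json").write_text(
                json.dumps(summary.as_dict(), indent=2, sort_keys=True))
            report["stages"]["behavior"] = {
                "percent_correct_overall": summary.percent_correct_overall}
        except Exception as e:  # noqa: BLE001
            raise StageError("behavior", e) from e

    if stage("classify"):
        try:
            labels = classify.classify_session(session)
            pd.DataFrame(
                [{"unit_id": u, "label": l} for u, l in sorted(labels.items())]
            ).to_csv(out / "labels.csv", index=False)
            report["stages"]["classify"] = {
                "n_tan": sum(v == "TAN" for v in labels.values()),
                "n_pan": sum(v == "PAN" for v in labels.values())}
        except Exception as e:  # noqa: BLE001
            raise StageError("classify", e) from e

    detections = None
    if stage("detect"):
        try:
            cfg = detect.ScanConfig(alpha=config.alpha, min_run=config.min_run)
            frames = [detect.detect_session(session, ev, cfg)
                      for ev in ("cue_on", "reward")]
            detections = pd.concat(frames, ignore_index=True)
            detections.to_csv(out / "detections.csv", index=False,
                              float_format="%.3f")
            report["stages"]["detect"] = {
                "n_pauses": int((detections["direction"] == "decrease").sum())}
        except Exception as e:  # noqa: BLE001
            raise StageError("detect", e) from e

    mags = {}
    if stage("quantify"):
        try:
            for ev in ("cue_on", "reward"):
                mags[ev] = quantify.magnitude_table(session, ev)
            pd.concat(mags.values(), ignore_index=True).to_csv(
                out / "magnitudes.csv", index=False, float_format="%.4f")
            report["stages"]["quantify"] = {
                "n_rows": int(sum(len(m) for m in mags.values()))}
        except Exception as e:  # noqa: BLE001
            raise StageError("quantify", e) from e

    if stage("stats"):
        try:
            result = _group_stats(session, mags, detections)
            (out / "stats.json").write_text(
                json.dumps(result, indent=2, sort_keys=True, default=float))
            report["stages"]["stats"] = {"analyses": sorted(result)}
        except Exception as e:  # noqa: BLE001
            raise StageError("stats", e) from e

    report["provenance"] = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def _group_stats(session: Session, mags: dict, detections) -> dict:
    """Interval contrasts, responsive proportions, and correct-run trends."""
    out: dict = {}
    tan_ids = [u.unit_id for u in session.units if u.label == "TAN"]

    for ev, table in mags.items():
        sub = table[table["unit_id"].isin(tan_ids)]
        short = sub[sub["interval"] == "short"].set_index("unit_id")["magnitude"]
        long_ = sub[sub["interval"] == "long"].set_index("unit_id")["magnitude"]
        common = short.index.intersection(long_.index)
        if len(common) >= 2:
            r = stats.rank_compare(short.loc[common], long_.loc[common],
                                   paired=True)
            out[f"{ev}_short_vs_long"] = {
                "z": r.z, "p": r.p, "n": len(common), "paired": True}

    if detections is not None and len(detections):
        tan_det = detections[detections["unit_id"].isin(tan_ids)]
        for ev in tan_det["align_event"].unique():
            sub = tan_det[tan_det["align_event"] == ev]
            resp = sub.groupby("unit_id")["direction"].apply(
                lambda d: bool((d == "decrease").any()))
            out[f"{ev}_responsive"] = {
                "n_responsive": int(resp.sum()), "n_units": int(len(resp))}

    runs = stats.find_correct_runs(session.trials, min_len=5)
    out["correct_runs"] = {"n_runs": len(runs),
                           "max_length": max((r.length for r in runs), default=0)}
    if runs and tan_ids and "cue_on" in mags:
        win = quantify.resolve_windows(session, "cue_on")
        frames = []
        for uid in tan_ids:
            for iv in ("short", "long"):
                frames.append(quantify.trial_magnitudes(
                    session, uid, "cue_on", win[iv],
                    trials=session.trials_where(interval=iv)))
        tm = pd.concat(frames, ignore_index=True)
        try:
            tr = stats.sequence_trend(runs, tm)
            out["cue_sequence_trend"] = {"slope": tr.slope, "rho": tr.spearman_rho,
                                         "p": tr.p, "n": tr.n}
        except ValueError:
            pass
    return out
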