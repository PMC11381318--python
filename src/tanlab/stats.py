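"""Group-level statistics linking responses to intervals, timing and reward.

Covers: Pearson chi-square on 2x2 proportions of responsive units (no
continuity correction — this reproduces the published statistics from their
counts), rank-based magnitude comparisons (unpaired rank-sum or paired
signed-rank), magnitude-vs-MOT linear regression with Spearman correlation,
500-ms MOT binning, maximal runs of consecutive correct trials, within-run
magnitude trends, and motor-vs-associative region contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._rank import mann_whitney, signed_rank
from .session import TrialEvents


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    chi2: float
    df: int
    p: float


def chi2_2x2(a: int, b: int, c: int, d: int,
             yates: bool = False) -> ContingencyResult:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    Without continuity correction by default (``yates=True`` enables it for
    sensitivity checks). Raises on zero margins.
    """
    from scipy.stats import chi2 as chi2_dist

    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be nonnegative integers")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("degenerate table: zero margin")
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    stat = n * det ** 2 / np.prod([float(m) for m in margins])
    return ContingencyResult(((a, b), (c, d)), float(stat), 1,
                             float(chi2_dist.sf(stat, 1)))


@dataclass
class RankTestResult:
    z: float
    p: float
    n1: int
    n2: int
    paired: bool


def rank_compare(x, y, paired: bool = False,
                 method: str = "auto") -> RankTestResult:
    """Compare two magnitude samples.

    Unpaired: Mann-Whitney/Dunn rank-sum z with tie correction. Paired:
    Wilcoxon signed-rank z on the differences (all-zero differences give
    z = 0, p = 1). ``method`` selects exact enumeration vs the normal
    approximation for the p-value ('auto' uses exact for small tie-free
    samples).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison needs equal lengths")
        z, p, n_used = signed_rank(x, y, method=method)
        return RankTestResult(z, p, len(x), len(y), True)
    z, p = mann_whitney(x, y, method=method)
    return RankTestResult(z, p, len(x), len(y), False)


@dataclass
class TrendResult:
    slope: float
    intercept: float
    spearman_rho: float
    p: float
    n: int


def mot_trend(magnitudes, mots) -> TrendResult:
    """Least-squares line plus Spearman rank correlation of magnitude vs MOT."""
    from scipy.stats import linregress, spearmanr

    y = np.asarray(magnitudes, float)
    x = np.asarray(mots, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = linregress(x, y)
    if np.ptp(y) == 0:
        rho, p = 0.0, 1.0
    else:
        rho, p = spearmanr(x, y)
    return TrendResult(float(fit.slope), float(fit.intercept),
                       float(rho), float(p), len(x))


def mot_binned_magnitudes(magnitudes, mots, bin_ms: float = 500.0) -> pd.DataFrame:
    """Mean +/- SEM magnitude within consecutive half-open MOT bins.

    Bins tile the MOT axis from 0 in steps of ``bin_ms``; empty bins are
    omitted. A MOT exactly on a boundary belongs to the upper bin.
    """
    if not bin_ms > 0:
        raise ValueError("bin width must be positive")
    y = np.asarray(magnitudes, float)
    x = np.asarray(mots, float)
    bw = bin_ms / 1000.0
    idx = np.floor(x / bw).astype(int)
    rows = []
    for k in sorted(set(idx)):
        sel = y[idx == k]
        rows.append({"bin_start_s": k * bw, "bin_end_s": (k + 1) * bw,
                     "mean": float(sel.mean()),
                     "sem": float(sel.std(ddof=1) / np.sqrt(len(sel)))
                     if len(sel) > 1 else 0.0,
                     "n": int(len(sel))})
    return pd.DataFrame(rows, columns=["bin_start_s", "bin_end_s",
                                       "mean", "sem", "n"])


@dataclass
class CorrectRun:
    """Maximal run of consecutive correct trials (inclusive trial indices)."""
    start_index: int
    end_index: int

    @property
    def length(self) -> int:
        return self.end_index - self.start_index + 1

    def positions(self) -> range:
        return range(self.start_index, self.end_index + 1)


def find_correct_runs(trials: Sequence[TrialEvents] | Sequence[str],
                      min_len: int = 5) -> list[CorrectRun]:
    """Maximal runs of >= ``min_len`` consecutive correct trials.

    Short- and long-interval trials are pooled to preserve chronological
    order. Accepts TrialEvents (using their ``trial_index``) or a plain
    outcome sequence (1-based positional indices).
    """
    if trials and isinstance(trials[0], TrialEvents):
        items = [(t.trial_index, t.outcome == "correct") for t in trials]
    else:
        items = [(i + 1, o in ("correct", "C")) for i, o in enumerate(trials)]
    runs: list[CorrectRun] = []
    start = None
    prev_idx = None
    for idx, ok in items:
        if ok:
            if start is None:
                start = idx
        else:
            if start is not None and prev_idx - start + 1 >= min_len:
                runs.append(CorrectRun(start, prev_idx))
            start = None
        prev_idx = idx
    if start is not None and prev_idx - start + 1 >= min_len:
        runs.append(CorrectRun(start, prev_idx))
    return runs


def sequence_trend(runs: Sequence[CorrectRun],
                   trial_magnitudes: pd.DataFrame) -> TrendResult:
    """Magnitude trend across positions within correct runs.

    ``trial_magnitudes`` must have columns ``trial_index`` and ``magnitude``
    (one row per unit per trial). For every trial inside a run the magnitude
    is averaged across units; the trend is fit on (position in run, averaged
    magnitude) points pooled over runs.
    """
    if not runs:
        raise ValueError("no correct runs provided")
    per_trial = trial_magnitudes.groupby("trial_index")["magnitude"].mean()
    xs, ys = [], []
    for run in runs:
        for pos, idx in enumerate(run.positions(), start=1):
            if idx in per_trial.index:
                xs.append(pos)
                ys.append(per_trial.loc[idx])
    if len(set(xs)) < 2:
        raise ValueError("need >= 2 distinct within-run positions")
    return mot_trend(ys, xs)


def region_contrast(mag_table: pd.DataFrame, interval: str,
                    responsive: Optional[Mapping[str, bool]] = None
                    ) -> dict[str, object]:
    """Motor vs associative striatum contrast for one interval.

    Returns an unpaired rank comparison of magnitudes between regions and,
    when per-unit responsiveness flags are given, a 2x2 chi-square of
    responsive proportions.
    """
    sel = mag_table[mag_table["interval"] == interval]
    groups = {r: sel[sel["region"] == r] for r in ("associative", "motor")}
    for r, g in groups.items():
        if g.empty:
            raise ValueError(f"region {r!r} has no units for {interval!r}")
    out: dict[str, object] = {
        "magnitude": rank_compare(groups["associative"]["magnitude"],
                                  groups["motor"]["magnitude"], paired=False)
    }
    if responsive is not None:
        counts = {}
        for r, g in groups.items():
            ids = g["unit_id"].unique()
            n_resp = sum(bool(responsive.get(u, False)) for u in ids)
            counts[r] = (n_resp, len(ids) - n_resp)
        out["frequency"] = chi2_2x2(*counts["associative"], *counts["motor"])
    return out
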