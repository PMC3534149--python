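"""Benchmarking detection against planted ground truth.

Over an evaluation universe (by default the core-mapped probes, the same
probes eligible for spiking) flags are scored as TP (spiked and flagged),
FP (flagged only), FN (spiked only) and TN (neither), giving

    precision = TP / (TP + FP),    recall = TP / (TP + FN).

Sweeping the flagging threshold over all distinct score values yields a
precision-recall curve; probes tied at a score enter together as a single
point. Replicate agreement of summarized probeset values is quantified by
the mean absolute deviation from the identity diagonal of a replicate
scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import FlagMask, ProbesetMap
from .noise import NoiseScoreGrid
from .spike import SpikeGroundTruth

__all__ = ["ConfusionCounts", "PRCurve", "confusion_counts", "pr_curve",
           "precision_at_recall", "mad_from_diagonal", "universe_from_map"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else float("nan")

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")


@dataclass
class PRCurve:
    """Ordered (threshold, recall, precision) points, thresholds descending.

    The point at threshold v corresponds to the flag set {s >= v}, i.e. the
    strict criterion s > t for t just below v; recall is non-decreasing
    along the curve.
    """

    points: pd.DataFrame
    positive_count: int

    def __post_init__(self):
        req = ["threshold", "recall", "precision"]
        if list(self.points.columns) != req:
            raise ValueError(f"points must have columns {req}")
        r = self.points["recall"].to_numpy()
        p = self.points["precision"].to_numpy()
        if len(r) and (np.diff(r) < 0).any():
            raise ValueError("recall must be non-decreasing as thresholds fall")
        for arr in (r, p):
            if len(arr) and ((arr < 0) | (arr > 1)).any():
                raise ValueError("precision/recall must lie in [0, 1]")


def universe_from_map(pmap: ProbesetMap, shape: tuple[int, int],
                      core_only: bool = True) -> np.ndarray:
    """Boolean eligibility grid of (core-)mapped probes."""
    df = pmap.entries
    if core_only:
        df = df[df["is_core"]]
    u = np.zeros(shape, dtype=bool)
    u[df["y"].to_numpy(), df["x"].to_numpy()] = True
    return u


def _as_universe(universe, shape) -> np.ndarray:
    u = np.asarray(universe, dtype=bool)
    if u.shape != shape:
        raise ValueError(f"universe dimensions {u.shape} != grid {shape}")
    return u


def confusion_counts(mask: FlagMask, truth: SpikeGroundTruth,
                     universe) -> ConfusionCounts:
    """TP/FP/TN/FN of a flag mask over the eligible universe."""
    if (truth.n_rows, truth.n_cols) != mask.shape:
        raise ValueError("mask and ground truth dimensions differ")
    u = _as_universe(universe, mask.shape)
    spiked = truth.mask() & u
    flagged = mask.flagged & u
    tp = int((spiked & flagged).sum())
    fp = int((~spiked & flagged & u).sum())
    fn = int((spiked & ~flagged).sum())
    tn = int(u.sum()) - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def pr_curve(scores: NoiseScoreGrid, truth: SpikeGroundTruth, universe) -> PRCurve:
    """Precision-recall over all distinct score thresholds, descending."""
    u = _as_universe(universe, scores.shape)
    s = scores.scores[u]
    pos = (truth.mask() & u)[u]
    n_pos = int(pos.sum())
    if n_pos == 0:
        raise ValueError("no spiked probes in the evaluation universe; recall undefined")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = pos[order]
    tp_cum = np.cumsum(pos_sorted)
    n_cum = np.arange(1, len(s_sorted) + 1)
    # last index of each run of tied scores = the point where the whole tie
    # group has entered the flag set
    is_last = np.empty(len(s_sorted), dtype=bool)
    is_last[:-1] = s_sorted[:-1] != s_sorted[1:]
    is_last[-1] = True
    idx = np.nonzero(is_last)[0]
    points = pd.DataFrame({
        "threshold": s_sorted[idx],
        "recall": tp_cum[idx] / n_pos,
        "precision": tp_cum[idx] / n_cum[idx],
    })
    return PRCurve(points, n_pos)


def precision_at_recall(curve: PRCurve, target_recall: float) -> float:
    """Precision at the highest threshold whose recall >= target."""
    if not 0 < target_recall <= 1:
        raise ValueError("target recall must be in (0, 1]")
    ok = curve.points[curve.points["recall"] >= target_recall]
    # recall reaches 1 at the minimum threshold, so ok is never empty
    return float(ok.iloc[0]["precision"])


def mad_from_diagonal(a: pd.Series, b: pd.Series,
                      exclude=()) -> float:
    """Mean |a_i - b_i| over the shared probeset universe.

    ``exclude`` lists probeset ids to drop (e.g. probesets zeroed by the
    all-flagged correction rule, whose summarized value is meaningless).
    """
    shared = a.index.intersection(b.index).difference(pd.Index(list(exclude)))
    if len(shared) == 0:
        raise ValueError("no shared probesets between the two summaries")
    return float((a.loc[shared] - b.loc[shared]).abs().mean())
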