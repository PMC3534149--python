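"""Threshold-based flagging of corrupted probes.

A probe is flagged when its noise score strictly exceeds a threshold t
(the epsilon-criterion); applied to window-smoothed scores this is the
window-criterion. Thresholds are chosen manually in practice, by reading
probe-noise and replicate-scatter plots, so this module also produces
flagged-count-versus-threshold tables to support that choice, plus an
optional score-quantile default that is a convenience only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import FlagMask
from .noise import NoiseScoreGrid

__all__ = ["flag_probes", "threshold_table", "quantile_threshold"]


def flag_probes(scores: NoiseScoreGrid, t: float) -> FlagMask:
    """Flag every probe with score strictly greater than ``t``."""
    if not np.isfinite(t):
        raise ValueError("threshold must be finite")
    return FlagMask(scores.scores > t, threshold=float(t), source_kind=scores.kind)


def threshold_table(scores: NoiseScoreGrid, thresholds=None) -> pd.DataFrame:
    """Flagged-probe counts over a grid of candidate thresholds."""
    if thresholds is None:
        thresholds = np.quantile(scores.scores, np.linspace(0.5, 1.0, 21))
    thresholds = np.asarray(thresholds, dtype=float)
    counts = [(scores.scores > t).sum() for t in thresholds]
    return pd.DataFrame({"threshold": thresholds, "n_flagged": counts})


def quantile_threshold(scores: NoiseScoreGrid, q: float = 0.999) -> float:
    """Score quantile usable as a default threshold (convenience, not a
    replacement for manual threshold choice)."""
    if not 0 < q < 1:
        raise ValueError("quantile must be in (0, 1)")
    return float(np.quantile(scores.scores, q))
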