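"""Per-probe noise scores and distance-weighted window smoothing.

The basic score for probe j is the pseudocounted log fold-change against a
control value,

    s_j = log2((v_j + c) / (v'_j + c)),

where v_j is the probe's intensity on the array under scrutiny, v'_j its
value on the control (a replicate, the fitted lambda1*N + lambda2*P sum, or
the across-replicate median) and the pseudocount c is the platform's
estimated detection limit (default 16). Spatial artefacts — stains from
uneven hybridization or array drying — corrupt contiguous regions, so the
window score averages s over a (2k+1) x (2k+1) neighborhood with weights
1/d(p, j) (Euclidean grid distance) for p != j and ``self_weight`` (default
2) at the center, truncating the window at array borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .grids import ProbeGrid

__all__ = [
    "NoiseScoreGrid",
    "fc_noise_scores",
    "median_control",
    "window_smooth",
    "window_smooth_naive",
    "distance_weight_kernel",
]

DEFAULT_PSEUDOCOUNT = 16.0
DEFAULT_WINDOW_K = 25
DEFAULT_SELF_WEIGHT = 2.0

_KINDS = {"fc", "abs_residual", "windowed"}


@dataclass
class NoiseScoreGrid:
    """Per-probe noise scores s_j (raw) or sw_j (window-smoothed)."""

    scores: np.ndarray
    kind: str
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    control_desc: str = ""
    window_k: int | None = None
    self_weight: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2D (n_rows, n_cols) array")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown score kind {self.kind!r}")
        if self.kind == "windowed" and self.window_k is None:
            raise ValueError("windowed score grids must record the window half-width k")

    @property
    def n_rows(self) -> int:
        return self.scores.shape[0]

    @property
    def n_cols(self) -> int:
        return self.scores.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


def fc_noise_scores(target: ProbeGrid, control: ProbeGrid,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    absolute: bool = True) -> NoiseScoreGrid:
    """Fold-change noise score of ``target`` against ``control``.

    ``absolute=True`` (the default used for detection) returns |s_j|;
    signed scores are kept for diagnostic plots.
    """
    if target.shape != control.shape:
        raise ValueError(f"grid dimension mismatch: {target.shape} vs {control.shape}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    s = np.log2(target.intensities + pseudocount) - np.log2(control.intensities + pseudocount)
    if absolute:
        s = np.abs(s)
    return NoiseScoreGrid(s, kind="fc", pseudocount=pseudocount,
                          control_desc=control.label or "control")


def median_control(grids: list[ProbeGrid]) -> ProbeGrid:
    """Per-probe median across replicate arrays (the error-image control
    when no dedicated clean control is available)."""
    if not grids:
        raise ValueError("median_control needs at least one grid")
    shape = grids[0].shape
    for g in grids[1:]:
        if g.shape != shape:
            raise ValueError("grid dimension mismatch")
    med = np.median(np.stack([g.intensities for g in grids]), axis=0)
    out = grids[0].with_intensities(med, label=f"median of {len(grids)} arrays")
    out.metadata = {}
    return out


def distance_weight_kernel(k: int, self_weight: float = DEFAULT_SELF_WEIGHT) -> np.ndarray:
    """(2k+1) x (2k+1) kernel of weights 1/d to the center, ``self_weight``
    at the center itself."""
    offsets = np.arange(-k, k + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    d = np.hypot(dx, dy)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    w[k, k] = self_weight
    return w


def window_smooth(scores: NoiseScoreGrid, k: int = DEFAULT_WINDOW_K,
                  self_weight: float = DEFAULT_SELF_WEIGHT) -> NoiseScoreGrid:
    """Distance-weighted window average sw_j of the noise scores.

    Implemented as two translation-invariant correlations (numerator
    kernel * s, denominator kernel * 1) with zero padding, which reproduces
    border truncation exactly: padded positions contribute zero weight, so
    near a border the weighted average runs over the in-bounds probes only.
    """
    if k < 1:
        raise ValueError("window half-width k must be >= 1")
    n_rows, n_cols = scores.shape
    if k >= max(n_rows, n_cols) > 1:
        raise ValueError(f"k={k} too large for a {n_rows}x{n_cols} grid")
    kernel = distance_weight_kernel(k, self_weight)
    num = scipy.ndimage.correlate(scores.scores, kernel, mode="constant", cval=0.0)
    den = scipy.ndimage.correlate(np.ones(scores.shape), kernel, mode="constant", cval=0.0)
    return NoiseScoreGrid(num / den, kind="windowed", pseudocount=scores.pseudocount,
                          control_desc=scores.control_desc, window_k=k,
                          self_weight=self_weight,
                          metadata={"source_kind": scores.kind})


def window_smooth_naive(scores: NoiseScoreGrid, k: int,
                        self_weight: float = DEFAULT_SELF_WEIGHT) -> NoiseScoreGrid:
    """Literal double-loop evaluation of the window average (test oracle).

    O(n * k^2); use :func:`window_smooth` for anything but tiny grids.
    """
    if k < 1:
        raise ValueError("window half-width k must be >= 1")
    n_rows, n_cols = scores.shape
    if k >= max(n_rows, n_cols) > 1:
        raise ValueError(f"k={k} too large for a {n_rows}x{n_cols} grid")
    s = scores.scores
    out = np.empty_like(s)
    for y in range(n_rows):
        for x in range(n_cols):
            num = 0.0
            den = 0.0
            for py in range(max(0, y - k), min(n_rows, y + k + 1)):
                for px in range(max(0, x - k), min(n_cols, x + k + 1)):
                    if px == x and py == y:
                        w = self_weight
                    else:
                        w = 1.0 / np.hypot(px - x, py - y)
                    num += s[py, px] * w
                    den += w
            out[y, x] = num / den
    return NoiseScoreGrid(out, kind="windowed", pseudocount=scores.pseudocount,
                          control_desc=scores.control_desc, window_k=k,
                          self_weight=self_weight,
                          metadata={"source_kind": scores.kind})
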