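"""Normalizations applied before noise scoring and summarization.

Three tools are provided:

* :func:`quantile_normalize` — forces all arrays onto the across-array mean
  distribution (the standard companion of RMA summarization).
* :func:`loess_pair_normalize` — removes the intensity-dependent trend of
  M = log2(target/control) against A = (1/2) log2(target*control) before
  replicate fold-change scoring.
* :func:`fit_fraction_model` — for 4sU metabolic-labeling designs where
  total RNA (T) splits into newly transcribed (N) and pre-existing (P)
  fractions, fits T = lambda1*N + lambda2*P by nonnegative least squares;
  the fitted sum lambda1*N + lambda2*P then serves as a biological control
  for T (:func:`control_from_fractions`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .grids import ProbeGrid

__all__ = [
    "FractionModel",
    "quantile_normalize",
    "loess_pair_normalize",
    "fit_fraction_model",
    "control_from_fractions",
]


@dataclass(frozen=True)
class FractionModel:
    """Fitted RNA-fraction mixing coefficients, both constrained >= 0."""

    lambda1: float
    lambda2: float
    residual_sum_sq: float

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("fraction coefficients must be nonnegative")


def _check_same_shape(grids):
    shape = grids[0].shape
    for g in grids[1:]:
        if g.shape != shape:
            raise ValueError(f"grid dimension mismatch: {g.shape} vs {shape}")


def quantile_normalize(grids: list[ProbeGrid]) -> list[ProbeGrid]:
    """Map every array onto the mean of the per-array sorted intensity vectors.

    Within-array rank order is preserved; tied input values receive the
    mean of the reference values over their tied ranks, so the result does
    not depend on the (arbitrary) order among ties.
    """
    if len(grids) < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    _check_same_shape(grids)
    flat = np.stack([g.intensities.ravel() for g in grids])
    n = flat.shape[1]
    order = np.argsort(flat, axis=1, kind="stable")
    reference = np.take_along_axis(flat, order, axis=1).mean(axis=0)

    out = []
    for i, g in enumerate(grids):
        v = flat[i]
        idx = order[i]
        sorted_v = v[idx]
        normalized_sorted = np.empty(n)
        # average the reference over each run of tied input values
        start = 0
        for end in range(1, n + 1):
            if end == n or sorted_v[end] != sorted_v[start]:
                normalized_sorted[start:end] = reference[start:end].mean()
                start = end
        result = np.empty(n)
        result[idx] = normalized_sorted
        out.append(g.with_intensities(result.reshape(g.shape)))
    return out


def loess_pair_normalize(target: ProbeGrid, control: ProbeGrid, *,
                         pseudocount: float = 0.0, span: float = 2 / 3,
                         robust_iters: int = 2, max_fit_points: int = 50_000,
                         seed: int = 0) -> ProbeGrid:
    """Remove the loess trend of M on A from ``target`` relative to ``control``.

    M = log2(target/control), A = (1/2) log2(target*control), both after
    adding ``pseudocount``. The smoother is locally linear with the given
    span and robustness iterations; above ``max_fit_points`` probes the
    trend is fitted on a seeded random subsample and interpolated, which
    keeps multi-million-probe grids tractable.
    """
    _check_same_shape([target, control])
    t = target.intensities.ravel() + pseudocount
    c = control.intensities.ravel() + pseudocount
    if np.any(t <= 0) or np.any(c <= 0):
        raise ValueError("intensities must be positive after pseudocount addition")
    m = np.log2(t) - np.log2(c)
    a = 0.5 * (np.log2(t) + np.log2(c))
    a_range = a.max() - a.min()
    if a_range == 0:
        raise ValueError("degenerate input: constant A, loess trend undefined")

    if a.size > max_fit_points:
        rng = np.random.default_rng(seed)
        pick = rng.choice(a.size, size=max_fit_points, replace=False)
    else:
        pick = slice(None)
    fit_sorted = lowess(m[pick], a[pick], frac=span, it=robust_iters,
                        delta=0.003 * a_range, return_sorted=True)
    trend = np.interp(a, fit_sorted[:, 0], fit_sorted[:, 1])
    normalized = target.intensities.ravel() * np.exp2(-trend)
    return target.with_intensities(normalized.reshape(target.shape))


def fit_fraction_model(T: ProbeGrid, N: ProbeGrid, P: ProbeGrid) -> FractionModel:
    """Least-squares fit of T = lambda1*N + lambda2*P with lambda_i >= 0."""
    _check_same_shape([T, N, P])
    design = np.column_stack([N.intensities.ravel(), P.intensities.ravel()])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("N and P are collinear: fraction model is rank-deficient")
    coef, rnorm = scipy.optimize.nnls(design, T.intensities.ravel())
    return FractionModel(float(coef[0]), float(coef[1]), float(rnorm ** 2))


def control_from_fractions(model: FractionModel, N: ProbeGrid, P: ProbeGrid) -> ProbeGrid:
    """Per-probe control v' = lambda1*N + lambda2*P for scoring T against."""
    _check_same_shape([N, P])
    values = model.lambda1 * N.intensities + model.lambda2 * P.intensities
    out = N.with_intensities(values, label="lambda1*N + lambda2*P")
    out.role = "generic"
    out.metadata = {}
    return out
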