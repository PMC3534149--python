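"""RMA-style probeset summarization by median polish.

Each probeset's log2 probe-by-array matrix is decomposed additively,

    y_ij = mu + r_i + c_j + e_ij,

by alternating row/column median sweeps (Tukey's median polish, the
summarization step of RMA). The chip effect mu + c_j is the probeset's
expression value on array j; the residuals e_ij form a second noise-score
channel: large |e_ij| marks probes whose measurements disagree with the
additive probe-affinity/array-effect model, which is how artefacts surface
in residual quality plots. Residual estimation should be run per condition
(on the replicates of that condition), not across heterogeneous samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import ArraySet, ProbesetMap
from .noise import DEFAULT_PSEUDOCOUNT, NoiseScoreGrid
from .normalize import quantile_normalize

__all__ = ["ProbesetSummary", "median_polish_fit", "summarize_arrays",
           "residual_noise_scores"]

MAX_POLISH_ITER = 10
POLISH_TOL = 0.01


@dataclass
class ProbesetSummary:
    """Probeset expression values and per-probe residuals, log2 scale.

    ``expression``: DataFrame indexed by probeset_id, one column per array
    label. ``residuals``: DataFrame indexed by (probeset_id, probe_id) with
    the same columns. ``iterations_used``: largest sweep count any probeset
    needed.
    """

    expression: pd.DataFrame
    residuals: pd.DataFrame
    iterations_used: int

    @property
    def array_labels(self) -> list[str]:
        return list(self.expression.columns)

    def column(self, label: str) -> pd.Series:
        if label not in self.expression.columns:
            raise KeyError(f"unknown array label {label!r}")
        return self.expression[label]


def median_polish_fit(values: np.ndarray, max_iter: int = MAX_POLISH_ITER,
                      tol: float = POLISH_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Median polish of one probe x array matrix.

    Returns ``(chip_effects, residuals)`` where ``chip_effects[j]`` is
    mu + c_j. Sweeps rows first, then columns, for at most ``max_iter``
    rounds, stopping when the total absolute residual changes by less than
    ``tol``.
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("values must be a non-empty 2D matrix")
    if not np.all(np.isfinite(z)):
        raise ValueError("values must be finite")
    chip, resid, _ = _median_polish_batch(z[None, :, :], max_iter=max_iter, tol=tol)
    return chip[0], resid[0]


def _median_polish_batch(stack: np.ndarray, max_iter: int = MAX_POLISH_ITER,
                         tol: float = POLISH_TOL) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized median polish over a (n_sets, n_probes, n_arrays) stack.

    All matrices are swept in lockstep (row medians, column medians,
    re-centering) until every matrix's total absolute residual has
    stabilized. Equivalent to per-matrix :func:`median_polish_fit` up to
    the shared stopping point.
    """
    z = np.array(stack, dtype=float)
    n_sets = z.shape[0]
    overall = np.zeros(n_sets)
    row = np.zeros(z.shape[:2])
    col = np.zeros((n_sets, z.shape[2]))
    last = np.abs(z).sum(axis=(1, 2))
    active = np.ones(n_sets, dtype=bool)  # per-matrix stop, as in the single fit
    used = 0
    for it in range(1, max_iter + 1):
        a = active
        za = z[a]
        rdelta = np.median(za, axis=2)
        za -= rdelta[:, :, None]
        row[a] += rdelta
        cola = col[a]
        cmed = np.median(cola, axis=1)
        cola -= cmed[:, None]
        overall[a] += cmed

        cdelta = np.median(za, axis=1)
        za -= cdelta[:, None, :]
        cola += cdelta
        rowa = row[a]
        rmed = np.median(rowa, axis=1)
        rowa -= rmed[:, None]
        overall[a] += rmed
        z[a] = za
        col[a] = cola
        row[a] = rowa

        total = np.abs(za).sum(axis=(1, 2))
        used = it
        converged = np.abs(total - last[a]) < tol
        last[a] = total
        active = active.copy()
        active[np.nonzero(a)[0][converged]] = False
        if not active.any():
            break
    chip = overall[:, None] + col
    return chip, z, used


def summarize_arrays(aset: ArraySet, quantile: bool = True,
                     core_only: bool = False,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ProbesetSummary:
    """Summarize every probeset of an array set to expression values.

    Optionally quantile-normalizes first, log2-transforms (intensities below
    the detection-limit pseudocount enter as log2(pseudocount), so zeroed
    probes contribute log2(0 + c)), then median-polishes each probeset
    (or meta-probeset). Probesets with no mapped probes after core
    filtering are skipped with a warning.
    """
    grids = list(aset.grids)
    if quantile and len(grids) > 1:
        grids = quantile_normalize(grids)
    labels = []
    for i, g in enumerate(grids):
        labels.append(g.label if g.label else f"array_{i}")
    if len(set(labels)) != len(labels):
        raise ValueError(f"array labels must be unique, got {labels}")

    pmap = aset.map.core_only() if core_only else aset.map
    entries = pmap.entries
    if len(entries) == 0:
        raise ValueError("probeset map is empty" + (" after core filtering" if core_only else ""))

    log_stack = np.stack([
        np.log2(np.maximum(g.intensities, pseudocount)) for g in grids
    ])  # (n_arrays, n_rows, n_cols)

    present = set(entries["probeset_id"])
    skipped = [ps for ps in aset.map.probeset_ids if ps not in present]
    if skipped:
        warnings.warn(f"{len(skipped)} probeset(s) with zero mapped probes skipped: "
                      f"{skipped[:5]}...")

    # batch probesets by size so each batch median-polishes as one 3D stack,
    # with no per-probeset Python loop
    entries = entries.sort_values("probeset_id", kind="stable").reset_index(drop=True)
    codes, unique_ids = pd.factorize(entries["probeset_id"], sort=True)
    group_sizes = np.bincount(codes)
    offsets = np.concatenate([[0], np.cumsum(group_sizes)])
    ys_all = entries["y"].to_numpy()
    xs_all = entries["x"].to_numpy()

    n_arrays = len(grids)
    expr_chunks, resid_chunks = [], []
    iterations = 0
    for size in np.unique(group_sizes):
        gsel = np.nonzero(group_sizes == size)[0]
        rows = offsets[gsel][:, None] + np.arange(size)          # (m, size)
        stack = log_stack[:, ys_all[rows], xs_all[rows]]          # (arrays, m, size)
        stack = stack.transpose(1, 2, 0)                          # (m, size, arrays)
        chip, resid, used = _median_polish_batch(stack)
        iterations = max(iterations, used)
        expr_chunks.append(pd.DataFrame(chip, index=unique_ids[gsel], columns=labels))
        midx = pd.MultiIndex.from_arrays(
            [entries["probeset_id"].to_numpy()[rows.ravel()],
             entries["probe_id"].to_numpy()[rows.ravel()]],
            names=["probeset_id", "probe_id"])
        resid_chunks.append(pd.DataFrame(resid.reshape(-1, n_arrays),
                                         index=midx, columns=labels))

    expression = pd.concat(expr_chunks).sort_index()
    expression.index.name = "probeset_id"
    residuals = pd.concat(resid_chunks).sort_index()
    return ProbesetSummary(expression, residuals, iterations)


def residual_noise_scores(summary: ProbesetSummary, array_label: str,
                          pmap: ProbesetMap, n_rows: int, n_cols: int) -> NoiseScoreGrid:
    """Absolute median-polish residuals laid out on the probe grid.

    Positions not covered by the probeset map score 0. The resulting grid
    is the residual-channel input to the epsilon/window criteria and to the
    residual quality plot.
    """
    col = summary.residuals[array_label] if array_label in summary.residuals.columns else None
    if col is None:
        raise KeyError(f"unknown array label {array_label!r}")
    scores = np.zeros((n_rows, n_cols))
    by_probe = col.abs().groupby(level="probe_id").max()
    entries = pmap.entries.drop_duplicates("probe_id")
    lookup = entries.set_index("probe_id")[["x", "y"]]
    shared = by_probe.index.intersection(lookup.index)
    xy = lookup.loc[shared]
    scores[xy["y"].to_numpy(), xy["x"].to_numpy()] = by_probe.loc[shared].to_numpy()
    return NoiseScoreGrid(scores, kind="abs_residual", control_desc=f"residuals:{array_label}")
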