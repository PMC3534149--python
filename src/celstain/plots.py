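"""Diagnostic plots: probe-noise images and replicate scatter plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluate import mad_from_diagonal
from .noise import NoiseScoreGrid

__all__ = ["probe_noise_plot", "replicate_scatter_plot"]

_MAX_RENDER = 2000

# flagged-fraction legend classes: exactly 0, then quarters, then fully flagged
_FRACTION_BINS = [(-0.001, 0.0, "0%"), (0.0, 0.25, "<=25%"), (0.25, 0.5, "<=50%"),
                  (0.5, 0.75, "<=75%"), (0.75, 1.0, "100%")]
_FRACTION_COLORS = ["#bbbbbb", "#fdd49e", "#fc8d59", "#d7301f", "#7f0000"]


def _block_max_downsample(a: np.ndarray, limit: int) -> np.ndarray:
    """Reduce an image by block maxima so stains stay visible."""
    f = int(np.ceil(max(a.shape) / limit))
    if f <= 1:
        return a
    ny, nx = (a.shape[0] + f - 1) // f, (a.shape[1] + f - 1) // f
    padded = np.full((ny * f, nx * f), -np.inf)
    padded[:a.shape[0], :a.shape[1]] = a
    return padded.reshape(ny, f, nx, f).max(axis=(1, 3))


def probe_noise_plot(scores: NoiseScoreGrid, out) -> None:
    """Color-coded noise score at each probe location.

    Signed scores use a diverging colormap symmetric about 0; absolute or
    windowed scores a sequential one. For residual scores this is the
    classic residual quality plot. Grids larger than 2000 px a side are
    block-max downsampled.
    """
    img = _block_max_downsample(scores.scores, _MAX_RENDER)
    signed = bool((scores.scores < 0).any())
    if signed:
        vmax = float(np.abs(img).max()) or 1.0
        cmap, vmin = "RdBu_r", -vmax
    else:
        vmax = float(img.max()) or 1.0
        cmap, vmin = "viridis", 0.0
    fig, ax = plt.subplots(figsize=(6, 6 * img.shape[0] / max(img.shape[1], 1)))
    im = ax.imshow(img, cmap=cmap, vmin=vmin, vmax=vmax, origin="lower",
                   interpolation="nearest")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    kind = scores.kind if scores.kind != "windowed" else \
        f"windowed (k={scores.window_k})"
    ax.set_title(f"probe noise score [{kind}] vs {scores.control_desc}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    try:
        fig.savefig(out, dpi=150)
    finally:
        plt.close(fig)


def replicate_scatter_plot(a: pd.Series, b: pd.Series, flags_fraction: pd.Series,
                           out, label_a: str = "affected array",
                           label_b: str = "control array") -> None:
    """Probeset values of an affected array against a control.

    Points are classed by the fraction of each probeset's probes that were
    flagged as corrupted; the identity diagonal and the mean absolute
    deviation from it are drawn for reference.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared probesets between the two summaries")
    av, bv = a.loc[shared], b.loc[shared]
    frac = flags_fraction.reindex(shared).fillna(0.0)
    mad = mad_from_diagonal(a, b)
    fig, ax = plt.subplots(figsize=(6, 6))
    for (lo, hi, name), color in zip(_FRACTION_BINS, _FRACTION_COLORS):
        sel = (frac > lo) & (frac <= hi)
        if sel.any():
            ax.scatter(bv[sel], av[sel], s=4, c=color, label=name, alpha=0.6,
                       linewidths=0)
    lims = [min(av.min(), bv.min()), max(av.max(), bv.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel(label_b)
    ax.set_ylabel(label_a)
    ax.set_title(f"replicate scatter (MAD from diagonal = {mad:.3g})")
    ax.legend(title="probes flagged", loc="upper left", fontsize=8)
    try:
        fig.savefig(out, dpi=150)
    finally:
        plt.close(fig)
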