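"""Synthetic arrays and spike-in benchmarks.

Real ground truth for spatial artefacts is unavailable, so detection is
benchmarked on planted ones: replicate-consistent baseline grids are
generated, then corrupted either probe-by-probe at random (noise level
delta) or with a contiguous stain. Planted intensities are drawn as
2^z, z ~ Normal(mu, sigma) with defaults mu = log2(850), sigma = 1 — a
log-normal on the log2 scale matching the intensity level observed inside
real drying-stain artefacts on ST arrays. Realistically shaped stains can
also be projected from a higher-resolution array onto a lower-resolution
one by block-max downscaling with 75th-percentile intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ArraySet, FlagMask, ProbeGrid, ProbesetMap, probe_id_from_xy

__all__ = [
    "SpikeGroundTruth",
    "generate_baseline_arrays",
    "random_spike",
    "stain_spike",
    "stain_mask",
    "project_artefact",
    "DEFAULT_MU_LOG2",
    "DEFAULT_SIGMA_LOG2",
]

DEFAULT_MU_LOG2 = float(np.log2(850))
DEFAULT_SIGMA_LOG2 = 1.0


@dataclass
class SpikeGroundTruth:
    """Record of planted artefacts: which probes, what values, how drawn."""

    n_rows: int
    n_cols: int
    spiked_xy: np.ndarray          # (n, 2) of (x, y)
    planted_values: np.ndarray     # intensity per spiked probe
    delta: float | None = None     # per-probe spiking probability, if random
    mu_log2: float | None = None
    sigma_log2: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.spiked_xy = np.asarray(self.spiked_xy, dtype=int).reshape(-1, 2)
        self.planted_values = np.asarray(self.planted_values, dtype=float)
        if len(self.planted_values) != len(self.spiked_xy):
            raise ValueError("one planted value per spiked probe required")
        if len(self.planted_values) and self.planted_values.min() <= 0:
            raise ValueError("planted values must be > 0")
        xy = self.spiked_xy
        if len(xy) and not ((xy[:, 0] < self.n_cols).all() and (xy[:, 1] < self.n_rows).all()
                            and (xy >= 0).all()):
            raise ValueError("spiked positions must lie on the grid")

    @property
    def n_spiked(self) -> int:
        return len(self.spiked_xy)

    def mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) array of spiked positions."""
        m = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        m[self.spiked_xy[:, 1], self.spiked_xy[:, 0]] = True
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.spiked_xy[:, 0], "y": self.spiked_xy[:, 1],
                             "planted_value": self.planted_values})


def generate_baseline_arrays(n_rows: int, n_cols: int, n_replicates: int,
                             seed: int, *, mean_log2: float = 8.0,
                             sd_log2: float = 2.0, replicate_sd_log2: float = 0.25,
                             probeset_size: int = 4) -> ArraySet:
    """Artefact-free replicate arrays with a scattered probeset layout.

    Each probe gets a true log2 intensity ~ Normal(mean_log2, sd_log2)
    shared across replicates, plus independent per-replicate log2 noise
    Normal(0, replicate_sd_log2); intensities are 2^value. Probes are
    assigned to probesets of ``probeset_size`` by striding the row-major
    order, so probes of one probeset are never grid-adjacent — mirroring
    the scattered layout of real arrays. Leftover probes (when the probe
    count is not a multiple of the probeset size) stay unmapped.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    n = n_rows * n_cols
    n_probesets = n // probeset_size
    if n_probesets < 2 or n_probesets == n_cols or n_probesets == 1:
        raise ValueError(f"{n_rows}x{n_cols} grid too small for scattered "
                         f"probesets of size {probeset_size}")
    rng = np.random.default_rng(seed)
    true_log2 = rng.normal(mean_log2, sd_log2, size=(n_rows, n_cols))
    grids = []
    for r in range(n_replicates):
        noise = rng.normal(0.0, replicate_sd_log2, size=(n_rows, n_cols)) \
            if replicate_sd_log2 > 0 else 0.0
        grids.append(ProbeGrid(np.exp2(true_log2 + noise), label=f"rep{r + 1}"))

    lin = np.arange(n_probesets * probeset_size)
    ps_index = lin % n_probesets
    xs, ys = lin % n_cols, lin // n_cols
    width = len(str(n_probesets))
    entries = pd.DataFrame({
        "probeset_id": [f"PS{int(i):0{width}d}" for i in ps_index],
        "probe_id": probe_id_from_xy(xs, ys, n_cols),
        "x": xs, "y": ys,
        "is_core": True,
    })
    return ArraySet(grids, ProbesetMap(entries, granularity="probeset"))


def _draw_spike_values(rng, n, mu_log2, sigma_log2):
    return np.exp2(rng.normal(mu_log2, sigma_log2, size=n))


def random_spike(grid: ProbeGrid, pmap: ProbesetMap, delta: float,
                 mu_log2: float = DEFAULT_MU_LOG2,
                 sigma_log2: float = DEFAULT_SIGMA_LOG2,
                 seed: int = 0) -> tuple[ProbeGrid, SpikeGroundTruth]:
    """Spike each core-mapped probe independently with probability delta.

    Spiked raw intensities are replaced (pre-normalization) by
    2^Normal(mu_log2, sigma_log2); everything else is bit-identical.
    """
    if not 0 <= delta <= 1:
        raise ValueError("delta must be in [0, 1]")
    pmap.validate_against(*grid.shape)
    eligible = pmap.entries[pmap.entries["is_core"]].drop_duplicates("probe_id")
    rng = np.random.default_rng(seed)
    hit = rng.random(len(eligible)) < delta
    xs = eligible["x"].to_numpy()[hit]
    ys = eligible["y"].to_numpy()[hit]
    values = _draw_spike_values(rng, hit.sum(), mu_log2, sigma_log2)
    out = grid.intensities.copy()
    out[ys, xs] = values
    truth = SpikeGroundTruth(grid.n_rows, grid.n_cols,
                             np.column_stack([xs, ys]), values,
                             delta=delta, mu_log2=mu_log2, sigma_log2=sigma_log2,
                             seed=seed)
    return grid.with_intensities(out), truth


def stain_spike(grid: ProbeGrid, stain: FlagMask,
                mu_log2: float = DEFAULT_MU_LOG2,
                sigma_log2: float = DEFAULT_SIGMA_LOG2,
                seed: int = 0, pmap: ProbesetMap | None = None
                ) -> tuple[ProbeGrid, SpikeGroundTruth]:
    """Plant a contiguous stain: every masked probe (optionally restricted
    to core-mapped probes when a map is given) gets a fresh log-normal
    intensity 2^Normal(mu_log2, sigma_log2)."""
    if stain.shape != grid.shape:
        raise ValueError("stain mask dimensions must match the grid")
    m = stain.flagged
    if pmap is not None:
        core = pmap.entries[pmap.entries["is_core"]]
        keep = np.zeros(grid.shape, dtype=bool)
        keep[core["y"].to_numpy(), core["x"].to_numpy()] = True
        m = m & keep
    ys, xs = np.nonzero(m)
    rng = np.random.default_rng(seed)
    values = _draw_spike_values(rng, len(xs), mu_log2, sigma_log2)
    out = grid.intensities.copy()
    out[ys, xs] = values
    truth = SpikeGroundTruth(grid.n_rows, grid.n_cols,
                             np.column_stack([xs, ys]), values,
                             mu_log2=mu_log2, sigma_log2=sigma_log2, seed=seed)
    return grid.with_intensities(out), truth


def stain_mask(n_rows: int, n_cols: int, coverage: float = 0.02,
               seed: int = 0) -> FlagMask:
    """Procedural disc-plus-diffuse-halo stain covering ~``coverage`` of the
    grid — a synthetic stand-in for the shape of a real drying stain.

    A filled disc holds ~70% of the target footprint; a halo of scattered
    probes with radially decaying hit probability surrounds it.
    """
    if not 0 < coverage < 0.5:
        raise ValueError("coverage must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    n = n_rows * n_cols
    r_disc = np.sqrt(0.7 * coverage * n / np.pi)
    margin_x = max(int(np.ceil(1.8 * r_disc)), 1)
    margin_y = max(int(np.ceil(1.8 * r_disc)), 1)
    if 2 * margin_x >= n_cols or 2 * margin_y >= n_rows:
        raise ValueError("grid too small for the requested stain coverage")
    cx = rng.integers(margin_x, n_cols - margin_x)
    cy = rng.integers(margin_y, n_rows - margin_y)
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    d = np.hypot(xx - cx, yy - cy)
    disc = d <= r_disc
    halo_zone = (d > r_disc) & (d <= 1.7 * r_disc)
    p_halo = np.exp(-(d - r_disc) / (0.25 * r_disc))
    halo = halo_zone & (rng.random(d.shape) < 0.5 * p_halo)
    return FlagMask(disc | halo, source_kind="stain")


def project_artefact(shape_mask: FlagMask, source: ProbeGrid, target: ProbeGrid,
                     factor: int = 2) -> tuple[ProbeGrid, SpikeGroundTruth]:
    """Project a stain from a fine grid onto a coarser one.

    Each ``factor`` x ``factor`` source block containing at least one
    masked probe maps to the single target probe at the block position;
    the planted value is the block's max masked intensity rescaled by the
    ratio of the two arrays' 75th intensity percentiles (coarser platforms
    run at different overall intensity levels).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if shape_mask.shape != source.shape:
        raise ValueError("shape mask must live on the source grid")
    ys, xs = np.nonzero(shape_mask.flagged)
    if len(xs) == 0:
        truth = SpikeGroundTruth(target.n_rows, target.n_cols,
                                 np.empty((0, 2), dtype=int), np.empty(0))
        return target.with_intensities(target.intensities.copy()), truth
    bx, by = xs // factor, ys // factor
    if bx.max() >= target.n_cols or by.max() >= target.n_rows:
        raise ValueError("stain footprint exceeds target grid bounds")
    scale = np.percentile(target.intensities, 75) / np.percentile(source.intensities, 75)
    block_max: dict[tuple[int, int], float] = {}
    src = source.intensities
    for x, y, sx, sy in zip(bx, by, xs, ys):
        key = (int(x), int(y))
        v = src[sy, sx]
        if v > block_max.get(key, -np.inf):
            block_max[key] = v
    keys = sorted(block_max)
    txy = np.array(keys, dtype=int).reshape(-1, 2)
    values = np.array([block_max[k] * scale for k in keys])
    out = target.intensities.copy()
    out[txy[:, 1], txy[:, 0]] = values
    truth = SpikeGroundTruth(target.n_rows, target.n_cols, txy, values)
    return target.with_intensities(out), truth
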