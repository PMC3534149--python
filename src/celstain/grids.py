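"""Core in-memory containers for probe-level array data.

Conventions used throughout the package:

* Intensities live on a 2D lattice of ``n_rows`` x ``n_cols`` probes and are
  stored as a float array of shape ``(n_rows, n_cols)`` indexed ``[y, x]``.
* Coordinates are 0-based, ``x`` in ``[0, n_cols)``, ``y`` in ``[0, n_rows)``.
* ``probe_id`` is the 1-based row-major linearization
  ``probe_id = y * n_cols + x + 1``, matching the common Affymetrix layout.
  All public APIs take ``(x, y)`` pairs, never linear indices, to avoid
  silent transposition; ``probe_id`` appears only in probeset tables and
  kill lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeGrid",
    "ProbesetMap",
    "ArraySet",
    "FlagMask",
    "probe_id_from_xy",
    "xy_from_probe_id",
]

_ROLES = {"total", "newly_transcribed", "pre_existing", "generic"}


def probe_id_from_xy(x, y, n_cols: int):
    """1-based row-major probe id for grid position(s) (x, y)."""
    return np.asarray(y) * n_cols + np.asarray(x) + 1


def xy_from_probe_id(probe_id, n_cols: int):
    """Inverse of :func:`probe_id_from_xy`; returns (x, y)."""
    lin = np.asarray(probe_id) - 1
    return lin % n_cols, lin // n_cols


@dataclass
class ProbeGrid:
    """One array's probe intensities on a 2D lattice.

    Parameters
    ----------
    intensities
        Array of shape ``(n_rows, n_cols)``; finite, non-negative.
    label
        Array/sample name.
    role
        One of ``total``, ``newly_transcribed``, ``pre_existing``,
        ``generic``. Total RNA (T) splits into newly transcribed (N) and
        pre-existing (P) fractions in 4sU metabolic-labeling designs, where
        T ~ lambda1*N + lambda2*P serves as a biological control.
    metadata
        Opaque per-file state (raw CEL header lines, per-cell STDV/NPIXELS
        strings, trailing sections) preserved for bit-exact round-trips.
    """

    intensities: np.ndarray
    label: str = ""
    role: str = "generic"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2D (n_rows, n_cols) array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(_ROLES)}")

    @property
    def n_rows(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_cols(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def with_intensities(self, values: np.ndarray, label: str | None = None) -> "ProbeGrid":
        """Copy of this grid with new intensity values, metadata preserved."""
        out = replace(self, intensities=np.array(values, dtype=float))
        if label is not None:
            out.label = label
        return out

    def __getitem__(self, xy: tuple[int, int]) -> float:
        x, y = xy
        return float(self.intensities[y, x])


@dataclass
class ProbesetMap:
    """Probe-to-probeset membership with grid coordinates.

    ``entries`` is a DataFrame with columns ``probeset_id`` (str),
    ``probe_id`` (int, 1-based), ``x``, ``y`` (0-based), ``is_core`` (bool).
    ``granularity`` is ``"probeset"`` (each probe in at most one set) or
    ``"meta_probeset"`` (gene-level groupings that may share probes).
    """

    entries: pd.DataFrame
    granularity: str = "probeset"

    def __post_init__(self):
        if self.granularity not in ("probeset", "meta_probeset"):
            raise ValueError(f"unknown granularity {self.granularity!r}")
        df = pd.DataFrame(self.entries).copy()
        required = ["probeset_id", "probe_id", "x", "y", "is_core"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"probeset map missing columns: {missing}")
        df["probeset_id"] = df["probeset_id"].astype(str)
        for c in ("probe_id", "x", "y"):
            df[c] = df[c].astype(int)
        df["is_core"] = df["is_core"].astype(bool)
        if df.duplicated(["probeset_id", "probe_id"]).any():
            dup = df[df.duplicated(["probeset_id", "probe_id"])].iloc[0]
            raise ValueError(
                f"duplicate (probeset_id, probe_id) pair: ({dup.probeset_id}, {dup.probe_id})"
            )
        if self.granularity == "probeset" and df["probe_id"].duplicated().any():
            pid = int(df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0])
            raise ValueError(
                f"probe_id {pid} belongs to more than one probeset "
                "(inconsistent with granularity='probeset')"
            )
        self.entries = df.reset_index(drop=True)

    def validate_against(self, n_rows: int, n_cols: int) -> None:
        """Check coordinates lie on the grid and agree with probe_id."""
        df = self.entries
        if len(df) == 0:
            return
        if (df["x"].min() < 0 or df["x"].max() >= n_cols
                or df["y"].min() < 0 or df["y"].max() >= n_rows):
            raise ValueError("probeset map coordinates outside grid bounds")
        expect = probe_id_from_xy(df["x"].to_numpy(), df["y"].to_numpy(), n_cols)
        bad = df["probe_id"].to_numpy() != expect
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"probe_id {row.probe_id} inconsistent with (x={row.x}, y={row.y}) "
                f"for n_cols={n_cols}"
            )

    def core_only(self) -> "ProbesetMap":
        return ProbesetMap(self.entries[self.entries["is_core"]], self.granularity)

    @property
    def probeset_ids(self) -> list[str]:
        return list(dict.fromkeys(self.entries["probeset_id"]))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ArraySet:
    """An ordered collection of same-shaped grids plus one probeset map."""

    grids: Sequence[ProbeGrid]
    map: ProbesetMap

    def __post_init__(self):
        self.grids = list(self.grids)
        if not self.grids:
            raise ValueError("ArraySet needs at least one grid")
        shape = self.grids[0].shape
        for g in self.grids[1:]:
            if g.shape != shape:
                raise ValueError(f"grid dimension mismatch: {g.shape} vs {shape}")
        self.map.validate_against(*shape)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids[0].shape

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.grids]


@dataclass
class FlagMask:
    """Boolean corrupted/clean status per probe.

    ``flagged[y, x]`` is True for probes whose noise score exceeded the
    threshold ``threshold`` (strict inequality) at creation time;
    ``source_kind`` records which noise-score channel produced the mask.
    """

    flagged: np.ndarray
    threshold: float = float("nan")
    source_kind: str = ""

    def __post_init__(self):
        self.flagged = np.asarray(self.flagged, dtype=bool)
        if self.flagged.ndim != 2:
            raise ValueError("flagged must be a 2D (n_rows, n_cols) array")

    @property
    def n_rows(self) -> int:
        return self.flagged.shape[0]

    @property
    def n_cols(self) -> int:
        return self.flagged.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.flagged.shape

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    def flagged_xy(self) -> np.ndarray:
        """(n, 2) array of flagged (x, y) positions, row-major order."""
        ys, xs = np.nonzero(self.flagged)
        return np.column_stack([xs, ys])

    def probe_ids(self) -> np.ndarray:
        """Sorted 1-based probe ids of flagged probes."""
        ys, xs = np.nonzero(self.flagged)
        return np.sort(probe_id_from_xy(xs, ys, self.n_cols))
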