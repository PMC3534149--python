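"""Correction of flagged probes.

Two strategies, mirroring what a practitioner can feed back into a standard
pipeline:

* value replacement — a flagged probe's intensity becomes the mean of its
  probeset's unflagged probes *on the same array* (between-array intensity
  differences therefore never enter); if every probe of a probeset is
  flagged no meaningful value can be inferred and all its probes are set
  to 0, producing a zero probeset intensity that should be excluded
  downstream. The corrected grid can be re-emitted as a text CEL file.
* definition filtering — flagged probes are removed from the probeset map
  (equivalently exported as a kill list); probesets losing every probe are
  dropped and reported.
"""

from __future__ import annotations

import warnings

import numpy as np

from .grids import FlagMask, ProbeGrid, ProbesetMap

__all__ = ["correct_by_probeset_mean", "filter_probesets", "fully_flagged_probesets"]


def _check_dims(grid_shape, mask: FlagMask):
    if mask.shape != grid_shape:
        raise ValueError(f"mask dimensions {mask.shape} != grid {grid_shape}")


def fully_flagged_probesets(mask: FlagMask, pmap: ProbesetMap) -> list[str]:
    """Probeset ids whose every mapped probe is flagged."""
    df = pmap.entries
    flagged = mask.flagged[df["y"].to_numpy(), df["x"].to_numpy()]
    agg = df.assign(flagged=flagged).groupby("probeset_id")["flagged"].all()
    return sorted(agg.index[agg])


def correct_by_probeset_mean(grid: ProbeGrid, mask: FlagMask,
                             pmap: ProbesetMap) -> ProbeGrid:
    """Replace each flagged probe by the mean of its probeset's clean probes.

    Unflagged probes and flagged-but-unmapped probes (controls, background
    features) are left bit-identical. Fully flagged probesets are zeroed
    and surfaced via a warning; collect them with
    :func:`fully_flagged_probesets` to exclude downstream.
    """
    _check_dims(grid.shape, mask)
    if pmap.granularity != "probeset":
        raise ValueError("mean replacement needs granularity='probeset' "
                         "(meta-probesets share probes, so the replacement pool "
                         "is ill-defined)")
    pmap.validate_against(*grid.shape)
    out = grid.intensities.copy()
    df = pmap.entries
    flagged = mask.flagged[df["y"].to_numpy(), df["x"].to_numpy()]
    zeroed = []
    for ps_id, sub in df.assign(flagged=flagged).groupby("probeset_id", sort=False):
        f = sub["flagged"].to_numpy()
        if not f.any():
            continue
        ys, xs = sub["y"].to_numpy(), sub["x"].to_numpy()
        if f.all():
            out[ys, xs] = 0.0
            zeroed.append(ps_id)
        else:
            clean_mean = grid.intensities[ys[~f], xs[~f]].mean()
            out[ys[f], xs[f]] = clean_mean
    if zeroed:
        warnings.warn(f"{len(zeroed)} probeset(s) fully flagged and zeroed "
                      f"(exclude from further analysis): {sorted(zeroed)[:10]}")
    return grid.with_intensities(out)


def filter_probesets(pmap: ProbesetMap, mask: FlagMask
                     ) -> tuple[ProbesetMap, list[int], list[str]]:
    """Remove flagged probes from the probeset definition.

    Returns ``(filtered_map, kill_list, emptied)``: the map without any
    flagged probe, the removed probe ids (ascending, deduplicated), and the
    ids of probesets dropped because they lost every probe.
    """
    pmap.validate_against(mask.n_rows, mask.n_cols)
    df = pmap.entries
    flagged = mask.flagged[df["y"].to_numpy(), df["x"].to_numpy()]
    kill_list = sorted(set(df.loc[flagged, "probe_id"].astype(int)))
    kept = df[~flagged]
    before = set(df["probeset_id"])
    after = set(kept["probeset_id"])
    emptied = sorted(before - after)
    return ProbesetMap(kept, pmap.granularity), kill_list, emptied
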