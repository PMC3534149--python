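"""Reading and writing probe grids and probeset tables.

The reference on-disk dialect is the version-3 *text* CEL format
(``[CEL]`` / ``[HEADER]`` / ``[INTENSITY]`` sections with a
``CellHeader=X Y MEAN STDV NPIXELS`` table). Reads preserve every byte that
is not a MEAN value — header lines, per-cell STDV/NPIXELS fields and any
trailing sections (``[MASKS]``, ``[OUTLIERS]``, ``[MODIFIED]``) — so that
``write_cel_text(read_cel_text(f))`` is byte-identical for well-formed
files and a corrected grid differs only in the corrected MEAN fields.

Probeset membership travels as a plain TSV
(``probeset_id  probe_id  x  y  is_core``) standing in for the vendor's
PGF/CLF annotation pair, and flagged probes can be exported as a kill list
(header ``probe_id``, one id per line) in the dialect accepted by the
Affymetrix Power Tools ``--kill-list`` option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import FlagMask, ProbeGrid, ProbesetMap, probe_id_from_xy

__all__ = [
    "CelFormatError",
    "read_cel_text",
    "write_cel_text",
    "read_probeset_map",
    "write_probeset_map",
    "write_kill_list",
    "read_kill_list",
    "write_scores_tsv",
    "write_flags_tsv",
]


class CelFormatError(ValueError):
    """Raised when a file does not conform to the text CEL v3 dialect."""


def _format_mean(v: float) -> str:
    return f"{v:.1f}"


def read_cel_text(path) -> ProbeGrid:
    """Parse a version-3 text CEL file into a :class:`ProbeGrid`.

    The grid label defaults to the file stem. Raw header lines, cell lines
    and trailing sections are kept in ``grid.metadata`` for round-tripping.
    """
    import os

    with open(path, "r", newline="") as fh:
        text = fh.read()
    lines = text.split("\n")

    # locate first non-empty line; must open the [CEL] section
    first = next((ln for ln in lines if ln.strip()), "")
    if first.strip() != "[CEL]":
        raise CelFormatError(f"{path}: first section must be [CEL], found {first.strip()!r}")

    def _kv(section_lines, key):
        prefix = key + "="
        for ln in section_lines:
            if ln.startswith(prefix):
                return ln[len(prefix):].strip()
        return None

    # split into sections by "[NAME]" lines, keeping raw text
    version = _kv(lines, "Version")
    if version != "3":
        raise CelFormatError(f"{path}: expected Version=3, found {version!r}")

    try:
        n_cols = int(_kv(lines, "Cols"))
        n_rows = int(_kv(lines, "Rows"))
    except (TypeError, ValueError):
        raise CelFormatError(f"{path}: [HEADER] must define integer Cols and Rows") from None

    try:
        intensity_at = lines.index("[INTENSITY]")
    except ValueError:
        raise CelFormatError(f"{path}: missing [INTENSITY] section") from None

    number_cells = _kv(lines[intensity_at:], "NumberCells")
    if number_cells is None:
        raise CelFormatError(f"{path}: [INTENSITY] missing NumberCells")
    number_cells = int(number_cells)
    if number_cells != n_rows * n_cols:
        raise CelFormatError(
            f"{path}: NumberCells={number_cells} inconsistent with "
            f"Rows*Cols={n_rows * n_cols}"
        )

    # cell table starts after the CellHeader line
    header_at = None
    for i in range(intensity_at, len(lines)):
        if lines[i].startswith("CellHeader="):
            header_at = i
            break
    if header_at is None:
        raise CelFormatError(f"{path}: [INTENSITY] missing CellHeader")

    cell_lines = lines[header_at + 1:header_at + 1 + number_cells]
    if len(cell_lines) < number_cells:
        raise CelFormatError(f"{path}: expected {number_cells} cell lines")

    intensities = np.zeros((n_rows, n_cols))
    xs = np.empty(number_cells, dtype=int)
    ys = np.empty(number_cells, dtype=int)
    for i, ln in enumerate(cell_lines):
        parts = ln.split()
        if len(parts) < 3:
            raise CelFormatError(f"{path}: malformed cell line {ln!r}")
        try:
            x, y = int(parts[0]), int(parts[1])
            mean = float(parts[2])
        except ValueError:
            raise CelFormatError(f"{path}: non-numeric cell fields in {ln!r}") from None
        if not (0 <= x < n_cols and 0 <= y < n_rows):
            raise CelFormatError(f"{path}: cell ({x}, {y}) outside {n_rows}x{n_cols} grid")
        intensities[y, x] = mean
        xs[i], ys[i] = x, y

    metadata = {
        "cel_preamble": lines[:header_at + 1],
        "cel_cells_raw": cell_lines,
        "cel_cells_xy": (xs, ys),
        "cel_trailer": lines[header_at + 1 + number_cells:],
    }
    label = os.path.splitext(os.path.basename(str(path)))[0]
    return ProbeGrid(intensities, label=label, metadata=metadata)


def write_cel_text(grid: ProbeGrid, path) -> None:
    """Write a grid as a version-3 text CEL file.

    If the grid came from :func:`read_cel_text` its raw lines are re-emitted
    verbatim wherever the intensity is unchanged; otherwise a canonical file
    is generated with STDV=0.0 and NPIXELS=1.
    """
    md = grid.metadata
    out_lines: list[str] = []
    if "cel_cells_raw" in md:
        out_lines.extend(md["cel_preamble"])
        xs, ys = md["cel_cells_xy"]
        for i, raw in enumerate(md["cel_cells_raw"]):
            x, y = int(xs[i]), int(ys[i])
            v = grid.intensities[y, x]
            if float(raw.split()[2]) == v:
                out_lines.append(raw)
            else:
                parts = raw.split("\t") if "\t" in raw else raw.split()
                stdv = parts[3] if len(parts) > 3 else "0.0"
                npix = parts[4] if len(parts) > 4 else "1"
                out_lines.append(f"{x}\t{y}\t{_format_mean(v)}\t{stdv.strip()}\t{npix.strip()}")
        out_lines.extend(md["cel_trailer"])
        text = "\n".join(out_lines)
    else:
        n_rows, n_cols = grid.shape
        out_lines = [
            "[CEL]",
            "Version=3",
            "",
            "[HEADER]",
            f"Cols={n_cols}",
            f"Rows={n_rows}",
            "",
            "[INTENSITY]",
            f"NumberCells={n_rows * n_cols}",
            "CellHeader=X\tY\tMEAN\tSTDV\tNPIXELS",
        ]
        for y in range(n_rows):
            for x in range(n_cols):
                out_lines.append(f"{x}\t{y}\t{_format_mean(grid.intensities[y, x])}\t0.0\t1")
        text = "\n".join(out_lines) + "\n"
    with open(path, "w", newline="") as fh:
        fh.write(text)


def read_probeset_map(path, granularity: str = "probeset",
                      n_rows: int | None = None, n_cols: int | None = None) -> ProbesetMap:
    """Read a probeset membership TSV.

    Expects header columns ``probeset_id, probe_id, x, y, is_core``. When
    grid dimensions are supplied, probe ids are checked against the
    row-major linearization of (x, y).
    """
    df = pd.read_csv(path, sep="\t")
    pmap = ProbesetMap(df, granularity=granularity)
    if n_rows is not None and n_cols is not None:
        pmap.validate_against(n_rows, n_cols)
    return pmap


def write_probeset_map(pmap: ProbesetMap, path) -> None:
    df = pmap.entries.copy()
    df["is_core"] = df["is_core"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def write_kill_list(mask: FlagMask, pmap: ProbesetMap, path) -> None:
    """Write flagged, probeset-mapped probe ids, one per line.

    Flagged probes that belong to no probeset (control or background
    features) are omitted; ids are ascending under a single ``probe_id``
    header, the dialect of the APT ``--kill-list`` option.
    """
    mapped = set(pmap.entries["probe_id"])
    ids = [int(i) for i in mask.probe_ids() if int(i) in mapped]
    with open(path, "w", newline="") as fh:
        fh.write("probe_id\n")
        for i in ids:
            fh.write(f"{i}\n")


def read_kill_list(path) -> list[int]:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "probe_id":
            raise ValueError(f"{path}: kill list must start with a 'probe_id' header")
        return [int(ln) for ln in fh if ln.strip()]


def write_scores_tsv(scores, path) -> None:
    """Write a noise-score grid as (x, y, score) TSV rows."""
    n_rows, n_cols = scores.scores.shape
    ys, xs = np.divmod(np.arange(n_rows * n_cols), n_cols)
    pd.DataFrame({"x": xs, "y": ys, "score": scores.scores.ravel()}).to_csv(
        path, sep="\t", index=False)


def write_flags_tsv(mask: FlagMask, path) -> None:
    """Write flagged probe positions as (x, y) TSV rows."""
    xy = mask.flagged_xy()
    pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}).to_csv(path, sep="\t", index=False)
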