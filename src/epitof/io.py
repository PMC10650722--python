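"""Reading, writing and assembling per-cell marker tables.

Canonical on-disk format is TSV (one row per cell: ``sample_id``,
``group``, then marker columns) with a sidecar JSON panel descriptor.
FCS ingest is a convenience path for data exported directly from gating
software; the pipeline itself starts after dead-cell removal and
de-barcoding, which happen upstream.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _fcs
from .containers import CellMatrix, NormalizedMatrix
from .panels import MarkerPanel, SchemaError

log = logging.getLogger(__name__)

_META_COLUMNS = ("sample_id", "group")


def read_cell_matrix(path: str | Path, panel: MarkerPanel) -> CellMatrix:
    """Read a TSV/CSV cell table and validate it against ``panel``.

    The header must contain ``sample_id``, ``group`` and every panel
    marker; any extra columns are preserved as annotations.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    missing += [m for m in panel.all_markers if m not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    for marker in panel.all_markers:
        col = pd.to_numeric(frame[marker], errors="coerce")
        if col.isna().any():
            row = int(np.flatnonzero(col.isna())[0])
            raise SchemaError(
                f"{path}: non-numeric abundance in column {marker!r} at row {row}")
        frame[marker] = col
    extra = [c for c in frame.columns
             if c not in _META_COLUMNS and c not in panel.all_markers]
    return CellMatrix(
        values=frame[list(panel.all_markers)],
        sample_id=frame["sample_id"],
        group=frame["group"],
        panel=panel,
        annotations=frame[extra] if extra else None,
    )


def write_cell_matrix(cells: CellMatrix, path: str | Path) -> None:
    """Write a CellMatrix to TSV with full float precision."""
    frame = pd.concat(
        [cells.sample_id, cells.group, cells.values], axis=1)
    if cells.annotations is not None:
        frame = pd.concat([frame, cells.annotations], axis=1)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_normalized_matrix(norm: NormalizedMatrix, path: str | Path) -> None:
    frame = pd.concat([norm.sample_id, norm.group, norm.residuals], axis=1)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_normalized_matrix(path: str | Path, panel: MarkerPanel) -> NormalizedMatrix:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in (*_META_COLUMNS, *panel.hptm_markers)
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    return NormalizedMatrix(
        residuals=frame[list(panel.hptm_markers)].astype(float),
        sample_id=frame["sample_id"],
        group=frame["group"],
        panel=panel,
    )


def read_fcs_events(
    path: str | Path,
    panel: MarkerPanel,
    channel_map: Mapping[str, str],
    sample_id: str = "sample",
    group: str = "HCB",
) -> CellMatrix:
    """Read an FCS file and map instrument channels onto panel markers.

    ``channel_map`` maps FCS channel names ($PnN) to panel marker names
    and must cover every panel marker; unmapped channels are dropped with
    a logged warning. Sample identity and group are supplied by the
    caller because a de-barcoded per-sample FCS file carries neither.
    """
    _, data, names = _fcs.read_fcs(path)
    inverse = {}
    for chan, marker in channel_map.items():
        if chan not in names:
            raise SchemaError(
                f"channel_map references channel {chan!r} absent from {path}")
        inverse[marker] = names.index(chan)
    missing = [m for m in panel.all_markers if m not in inverse]
    if missing:
        raise SchemaError(
            f"channel_map does not cover panel marker(s): {missing}")
    unmapped = [n for n in names if n not in channel_map]
    if unmapped:
        log.warning("dropping unmapped FCS channels: %s", unmapped)
    cols = {m: data[:, inverse[m]] for m in panel.all_markers}
    values = pd.DataFrame(cols)
    n = len(values)
    return CellMatrix(
        values=values,
        sample_id=pd.Series([sample_id] * n, dtype=object),
        group=pd.Series([group] * n, dtype=object),
        panel=panel,
    )


def concat_samples(matrices: Sequence[CellMatrix]) -> CellMatrix:
    """Row-concatenate per-sample matrices sharing one panel."""
    if not matrices:
        raise SchemaError("concat_samples requires at least one matrix")
    panel = matrices[0].panel
    for m in matrices[1:]:
        if m.panel != panel:
            raise SchemaError("all matrices must share the same panel")
    values = pd.concat([m.values for m in matrices], ignore_index=True)
    sample_id = pd.concat([m.sample_id for m in matrices], ignore_index=True)
    group = pd.concat([m.group for m in matrices], ignore_index=True)
    annots = [m.annotations for m in matrices]
    annotations = None
    if all(a is not None for a in annots):
        annotations = pd.concat(annots, ignore_index=True)
    return CellMatrix(values=values, sample_id=sample_id, group=group,
                      panel=panel, annotations=annotations)
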