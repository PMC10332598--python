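"""Annotation tables of detected vocalisations.

The unit of analysis throughout the package is one *detected vocalisation*
(one row): a source WAV file, a centre time, a duration, and optionally an
expert type label.  Tables are plain :class:`pandas.DataFrame` objects with
a fixed schema, read from / written to CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
]

#: Required CSV columns.  ``label`` may be empty (unlabelled detection);
#: ``individual`` is optional and preserved when present.
COLUMNS = ["filename", "center_s", "duration_s", "label"]


def validate_annotations(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants; returns the table with normalised dtypes.

    Rows may give either ``center_s`` or an ``onset_s`` (with ``duration_s``);
    onsets are converted to centres via ``center = onset + duration / 2``.
    """
    table = table.copy()
    if "center_s" not in table.columns:
        if {"onset_s", "duration_s"} <= set(table.columns):
            table["center_s"] = table["onset_s"] + table["duration_s"] / 2
        else:
            raise ValueError(
                "annotation table needs a 'center_s' column or "
                "'onset_s' + 'duration_s'"
            )
    missing = [c for c in ("filename", "center_s", "duration_s") if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns: {missing}")
    if "label" not in table.columns:
        table["label"] = pd.NA
    table["center_s"] = table["center_s"].astype(float)
    table["duration_s"] = table["duration_s"].astype(float)
    # empty strings count as unlabelled
    table["label"] = table["label"].replace("", pd.NA)
    if (table["center_s"] < 0).any():
        bad = table.index[table["center_s"] < 0].tolist()
        raise ValueError(f"negative center_s at rows {bad}")
    finite_dur = table["duration_s"].dropna()
    if (finite_dur <= 0).any():
        bad = finite_dur.index[finite_dur <= 0].tolist()
        raise ValueError(f"non-positive duration_s at rows {bad}")
    return table


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a detection table from CSV and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation CSV not found: {path}")
    table = pd.read_csv(path, dtype={"filename": str, "label": "string"})
    return validate_annotations(table)


def write_annotations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a detection table to CSV (stable column order)."""
    cols = [c for c in COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.to_csv(path, index=False, columns=cols)


def label_counts(table: pd.DataFrame) -> pd.Series:
    """Occurrence count per label, ignoring unlabelled rows."""
    return table["label"].dropna().value_counts()


def mode_sampling_rate(rates: "np.ndarray | list[float]") -> float:
    """Most common sampling rate among files; ties go to the lower rate."""
    values, counts = np.unique(np.asarray(rates, dtype=float), return_counts=True)
    return float(values[np.argmax(counts)])
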