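"""Reading and writing MSD workbooks, CSV tables and result files.

The canonical input is a spreadsheet workbook with two sheets:

``data``
    Long (tidy) layout with columns ``video_id, particle_id, lag_s,
    msd_um2`` — one row per (particle, lag) pair.  A long layout is
    unambiguous for ragged trajectory lengths, unlike one column per
    particle.
``metadata``
    Two-column key/value sheet.  ``reference_D`` (um^2/s) is required;
    ``sample_name``, ``frame_interval``, ``control_D`` and ``notes`` are
    optional.

CSV input uses the same columns (one file for data, one for metadata).
All parsing is locale-independent (decimal point).
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DataIntegrityError, Metadata, MSDCurve, TrackDataset

DATA_SHEET = "data"
METADATA_SHEET = "metadata"
DATA_COLUMNS = ["video_id", "particle_id", "lag_s", "msd_um2"]

#: Column order of the per-particle results table.
RESULT_COLUMNS = [
    "video_id",
    "particle_id",
    "n_segments",
    "alpha_star",
    "D",
    "D_short",
    "D_over_Dref",
    "R2",
    "RSS",
    "RMSE",
    "transport_class",
    "kept",
    "discard_reason",
]


class WorkbookFormatError(ValueError):
    """Raised when an input workbook does not match the expected schema."""


def _metadata_from_mapping(pairs: dict) -> Metadata:
    if "reference_D" not in pairs:
        raise WorkbookFormatError(
            "metadata is missing the required 'reference_D' key"
        )
    kwargs: dict = {
        "sample_name": str(pairs.get("sample_name", "unnamed")),
        "reference_D": float(pairs["reference_D"]),
    }
    if "frame_interval" in pairs:
        kwargs["frame_interval"] = float(pairs["frame_interval"])
    if "control_D" in pairs and pairs["control_D"] not in (None, ""):
        val = float(pairs["control_D"])
        if not math.isnan(val):
            kwargs["control_D"] = val
    if "notes" in pairs and pairs["notes"] not in (None, ""):
        kwargs["notes"] = str(pairs["notes"])
    return Metadata(**kwargs)


def _dataset_from_frames(data: pd.DataFrame, meta_pairs: dict) -> TrackDataset:
    missing = [c for c in DATA_COLUMNS if c not in data.columns]
    if missing:
        raise WorkbookFormatError(f"data sheet is missing columns: {missing}")
    metadata = _metadata_from_mapping(meta_pairs)

    df = data[DATA_COLUMNS].copy()
    df["lag_s"] = pd.to_numeric(df["lag_s"], errors="coerce")
    df["msd_um2"] = pd.to_numeric(df["msd_um2"], errors="coerce")
    n_before = len(df)
    df = df.dropna(subset=["lag_s", "msd_um2"])
    n_rejected = n_before - len(df)

    dup = df.duplicated(subset=["video_id", "particle_id", "lag_s"])
    if dup.any():
        row = df[dup].iloc[0]
        raise DataIntegrityError(
            "duplicate (video, particle, lag) entry: "
            f"({row['video_id']}, {row['particle_id']}, {row['lag_s']})"
        )

    df = df.sort_values(["video_id", "particle_id", "lag_s"], kind="mergesort")
    curves = [
        MSDCurve(
            video_id=vid,
            particle_id=pid,
            lags=grp["lag_s"].to_numpy(float),
            msd=grp["msd_um2"].to_numpy(float),
        )
        for (vid, pid), grp in df.groupby(
            ["video_id", "particle_id"], sort=True
        )
    ]
    return TrackDataset(
        metadata=metadata, curves=curves, n_rejected_rows=n_rejected
    )


def read_msd_workbook(path: str | Path) -> TrackDataset:
    """Read an XLSX workbook with ``data`` and ``metadata`` sheets.

    Raises
    ------
    WorkbookFormatError
        If a required sheet, column or metadata key is missing.
    DataIntegrityError
        If a (video, particle, lag) triple appears twice.
    """
    sheets = pd.read_excel(path, sheet_name=None)
    if METADATA_SHEET not in sheets:
        raise WorkbookFormatError(
            f"workbook has no '{METADATA_SHEET}' sheet (found: {list(sheets)})"
        )
    if DATA_SHEET not in sheets:
        raise WorkbookFormatError(
            f"workbook has no '{DATA_SHEET}' sheet (found: {list(sheets)})"
        )
    meta_df = sheets[METADATA_SHEET]
    if meta_df.shape[1] < 2:
        raise WorkbookFormatError("metadata sheet needs key and value columns")
    pairs = dict(
        zip(meta_df.iloc[:, 0].astype(str), meta_df.iloc[:, 1], strict=True)
    )
    return _dataset_from_frames(sheets[DATA_SHEET], pairs)


def read_msd_csv(
    data_path: str | Path, metadata_path: str | Path
) -> TrackDataset:
    """Read the CSV equivalent of the workbook (data file + metadata file)."""
    data = pd.read_csv(data_path, float_precision="round_trip")
    meta_df = pd.read_csv(metadata_path, float_precision="round_trip")
    if meta_df.shape[1] < 2:
        raise WorkbookFormatError("metadata file needs key and value columns")
    pairs = dict(
        zip(meta_df.iloc[:, 0].astype(str), meta_df.iloc[:, 1], strict=True)
    )
    return _dataset_from_frames(data, pairs)


def dataset_to_frames(ds: TrackDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (data, metadata) DataFrames in the workbook layout."""
    rows = []
    for c in ds.curves:
        rows.append(
            pd.DataFrame(
                {
                    "video_id": c.video_id,
                    "particle_id": c.particle_id,
                    "lag_s": c.lags,
                    "msd_um2": c.msd,
                }
            )
        )
    data = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=DATA_COLUMNS)
    )
    meta = ds.metadata
    pairs = [
        ("sample_name", meta.sample_name),
        ("reference_D", meta.reference_D),
        ("frame_interval", meta.frame_interval),
    ]
    if meta.control_D is not None:
        pairs.append(("control_D", meta.control_D))
    if meta.notes is not None:
        pairs.append(("notes", meta.notes))
    meta_df = pd.DataFrame(pairs, columns=["key", "value"])
    return data, meta_df


def write_msd_workbook(ds: TrackDataset, path: str | Path) -> None:
    """Write a dataset to an XLSX workbook readable by read_msd_workbook."""
    data, meta_df = dataset_to_frames(ds)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        data.to_excel(writer, sheet_name=DATA_SHEET, index=False)
        meta_df.to_excel(writer, sheet_name=METADATA_SHEET, index=False)


def write_msd_csv(
    ds: TrackDataset, data_path: str | Path, metadata_path: str | Path
) -> None:
    data, meta_df = dataset_to_frames(ds)
    data.to_csv(data_path, index=False)
    meta_df.to_csv(metadata_path, index=False)


def filter_min_segments(
    ds: TrackDataset, min_segments: int = 10
) -> TrackDataset:
    """Drop trajectories with fewer than ``min_segments`` lag points.

    Short trajectories are dominated by localisation noise and linking
    artifacts, so only trajectories with n_ij >= min_segments (default 10)
    are analysed.  The boundary is inclusive.  Per-video removal counts are
    kept on the returned dataset for reporting.
    """
    if min_segments < 1:
        raise ValueError("min_segments must be >= 1")
    kept = [c for c in ds.curves if c.n_segments >= min_segments]
    removed: dict = {}
    for c in ds.curves:
        if c.n_segments < min_segments:
            removed[c.video_id] = removed.get(c.video_id, 0) + 1
    return TrackDataset(
        metadata=ds.metadata,
        curves=kept,
        removed_per_video=removed,
        n_rejected_rows=ds.n_rejected_rows,
    )


def write_results_table(
    records, path: str | Path, format: str = "csv"
) -> None:
    """Write the per-particle fit + screening table (CSV or XLSX).

    ``records`` is a DataFrame or list of dicts with the RESULT_COLUMNS
    fields; missing columns are filled with NA so the header is stable.
    """
    df = pd.DataFrame(records)
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[RESULT_COLUMNS]
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValueError(f"unknown format {format!r} (use 'csv' or 'xlsx')")
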