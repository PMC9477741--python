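"""Readers and writers for track tables.

Two dialects are supported:

``canonical``
    Long/tidy delimited text (comma or tab, autodetected), one row per
    tracked position, with header columns ``track_id, frame, t_min, x_um,
    y_um[, z_um], cell_class, condition``. This is the package's native
    interchange format; the writer emits it deterministically (sorted by
    track id, then time) so identical track sets produce identical files.

``imaris_position``
    The position-per-row CSV layout exported by common commercial tracking
    software: three preamble lines, then a header containing ``Position X``
    / ``Position Y`` / ``Position Z`` (µm), a 1-based ``Time`` frame index
    and a ``TrackID`` column. Frame indices are converted to minutes using
    the configured frame interval; internal time starts at 0.

All files are UTF-8 with "." as the decimal separator regardless of locale.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AcquisitionParams, Track, TrackSet, validate_track

__all__ = ["ReadError", "read_tracks", "write_tracks"]

CANONICAL_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um", "z_um", "cell_class", "condition"]
_REQUIRED = ["track_id", "frame", "t_min", "x_um", "y_um"]


class ReadError(ValueError):
    """Malformed track table: missing column, duplicate row, bad number."""


def _check_numeric(df: pd.DataFrame, columns: list[str], header_rows: int) -> pd.DataFrame:
    """Coerce columns to float, reporting the 1-based file row of any failure."""
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + header_rows + 2  # +1 header, +1 one-based
            raise ReadError(f"unparseable numeric value {df[col][bad].iloc[0]!r} in column {col!r} at file row {row}")
        df[col] = coerced
    return df


def _read_canonical(path: Path, acquisition: AcquisitionParams) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        sample = fh.readline()
    delim = "\t" if sample.count("\t") >= sample.count(",") and "\t" in sample else ","
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ReadError(f"missing required column(s) {missing} in {path}")
    df = _check_numeric(df, [c for c in ["frame", "t_min", "x_um", "y_um", "z_um"] if c in df.columns], 0)
    for col in ("cell_class", "condition"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    return df


def _read_imaris(path: Path, acquisition: AcquisitionParams) -> pd.DataFrame:
    df = pd.read_csv(path, skiprows=3, dtype=str, keep_default_na=False, na_values=[""])
    colmap = {}
    for want, key in [("Position X", "x_um"), ("Position Y", "y_um"), ("Position Z", "z_um"),
                      ("Time", "frame"), ("TrackID", "track_id")]:
        match = [c for c in df.columns if str(c).strip().startswith(want)]
        if not match and want != "Position Z":
            raise ReadError(f"missing required column {want!r} in {path}")
        if match:
            colmap[match[0]] = key
    df = df[list(colmap)].rename(columns=colmap)
    df = _check_numeric(df, [c for c in ["frame", "x_um", "y_um", "z_um"] if c in df.columns], 3)
    # vendor exports use a 1-based frame index; internal time origin is 0 min
    df["t_min"] = (df["frame"] - 1) * acquisition.frame_interval
    df["cell_class"] = ""
    df["condition"] = ""
    return df


def read_tracks(
    path: str | Path,
    dialect: str = "canonical",
    acquisition: AcquisitionParams | None = None,
    condition: str | None = None,
) -> TrackSet:
    """Read a track table into a :class:`TrackSet`.

    One :class:`Track` is built per distinct ``track_id``, points sorted by
    time. Duplicate (track_id, frame) pairs, missing columns and
    unparseable numeric cells raise :class:`ReadError` with the offending
    row or column named.
    """
    path = Path(path)
    if not path.exists():
        raise ReadError(f"no such file: {path}")
    acquisition = acquisition or AcquisitionParams()
    if dialect == "canonical":
        df = _read_canonical(path, acquisition)
    elif dialect == "imaris_position":
        df = _read_imaris(path, acquisition)
    else:
        raise ReadError(f"unknown dialect {dialect!r}; choose 'canonical' or 'imaris_position'")

    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        key = (df.loc[df.index[dup][0], "track_id"], df.loc[df.index[dup][0], "frame"])
        raise ReadError(f"duplicate (track_id, frame) = {key} at file row {row}")

    has_z = "z_um" in df.columns and df["z_um"].notna().all() and len(df) > 0
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("t_min")
        tr = Track(
            track_id=str(tid),
            t=grp["t_min"].to_numpy(float),
            x=grp["x_um"].to_numpy(float),
            y=grp["y_um"].to_numpy(float),
            z=grp["z_um"].to_numpy(float) if has_z else None,
            cell_class=str(grp["cell_class"].iloc[0]),
            condition=str(grp["condition"].iloc[0]),
            frame_interval=acquisition.frame_interval,
        )
        tracks.append(validate_track(tr))
    conditions = {tr.condition for tr in tracks if tr.condition}
    label = condition if condition is not None else (conditions.pop() if len(conditions) == 1 else "")
    return TrackSet(tracks=tracks, condition=label, acquisition=acquisition, projected=not has_z)


def write_tracks(ts: TrackSet, path: str | Path, delimiter: str = ",") -> Path:
    """Write a :class:`TrackSet` in the canonical dialect.

    Rows are ordered by (track_id, t); an empty track set yields a
    header-only file. Floats are written at full precision so a
    write/read round trip is the identity.
    """
    path = Path(path)
    has_z = any(tr.z is not None for tr in ts.tracks)
    cols = [c for c in CANONICAL_COLUMNS if has_z or c != "z_um"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for tr in sorted(ts.tracks, key=lambda tr: tr.track_id):
            frames = np.round(tr.t / tr.frame_interval).astype(int)
            for i in range(tr.n_points):
                row = [tr.track_id, frames[i], repr(float(tr.t[i])),
                       repr(float(tr.x[i])), repr(float(tr.y[i]))]
                if has_z:
                    row.append(repr(float(tr.z[i])) if tr.z is not None else "")
                row += [tr.cell_class, tr.condition or ts.condition]
                writer.writerow(row)
    return path
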