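"""Readers and writers for the CSV / TIFF / YAML formats the stages consume.

CSV dialect: comma separator, '.' decimal (the packaged ratio table fixture
additionally normalises ','), UTF-8, header required.  Malformed rows are
reported with their line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .locomotion import DEFAULT_FPS, LarvaTrack
from .quantal import EventSeries

__all__ = [
    "read_events_csv",
    "write_events_csv",
    "read_track_csv",
    "write_track_csv",
    "read_tiff",
    "write_tiff",
    "read_diameters_csv",
    "read_abundance_csv",
]


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[coerced.isna() & df[column].notna()]
    if len(bad):
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in bad[:20]]
        raise ValidationError(f"{path}: non-numeric {column!r} at lines {lines}")
    return coerced


def read_events_csv(path, duration: float | None = None) -> dict[str, EventSeries]:
    """Read mEPSP events (columns: cell_id, amplitude_mV[, time_s[, duration_s]]).

    ``duration`` overrides any per-cell duration_s column.  Returns a mapping
    cell_id -> EventSeries.
    """
    df = pd.read_csv(path)
    _require_columns(df, {"cell_id", "amplitude_mV"}, path)
    amps = _numeric(df, "amplitude_mV", path)
    times = _numeric(df, "time_s", path) if "time_s" in df.columns else None
    durations = _numeric(df, "duration_s", path) if "duration_s" in df.columns else None
    out: dict[str, EventSeries] = {}
    for cell, sub in df.groupby("cell_id", sort=False):
        idx = sub.index
        cell_dur = duration
        if cell_dur is None and durations is not None:
            cell_dur = float(durations.loc[idx].iloc[0])
        out[str(cell)] = EventSeries(
            amplitudes=amps.loc[idx].to_numpy(),
            times=None if times is None else times.loc[idx].to_numpy(),
            duration=cell_dur,
            cell_id=str(cell),
        )
    if not out:
        raise ValidationError(f"{path}: no event rows")
    return out


def write_events_csv(events: Mapping[str, EventSeries] | EventSeries, path) -> None:
    if isinstance(events, EventSeries):
        events = {events.cell_id: events}
    frames = []
    for cell, ev in events.items():
        d = {"cell_id": cell, "amplitude_mV": ev.amplitudes}
        if ev.times is not None:
            d["time_s"] = ev.times
        if ev.duration is not None:
            d["duration_s"] = ev.duration
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_TRACK_COLS = {"frame", "x", "y", "area", "spine_length", "width"}


def read_track_csv(path, fps: float = DEFAULT_FPS) -> dict[str, LarvaTrack]:
    """Read tracker tables (FIMtrack-like layout).

    Wide layout: one larva per file with columns frame, x, y, area,
    spine_length, width.  Long layout: an additional larva_id column.  Frame
    numbers must be consecutive (uniform spacing at 1/fps s).
    """
    df = pd.read_csv(path)
    _require_columns(df, _TRACK_COLS, path)
    for col in _TRACK_COLS:
        df[col] = _numeric(df, col, path)
    if "larva_id" not in df.columns:
        df["larva_id"] = "larva1"
    out: dict[str, LarvaTrack] = {}
    for larva, sub in df.groupby("larva_id", sort=False):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if len(frames) >= 2 and not np.all(np.diff(frames) == 1):
            raise ValidationError(
                f"{path}: larva {larva!r} has non-consecutive frame numbers"
            )
        out[str(larva)] = LarvaTrack(
            frame_times=frames / fps,
            centroid_xy=sub[["x", "y"]].to_numpy(),
            area=sub["area"].to_numpy(),
            spine_length=sub["spine_length"].to_numpy(),
            width=sub["width"].to_numpy(),
            larva_id=str(larva),
        )
    if not out:
        raise ValidationError(f"{path}: no track rows")
    return out


def write_track_csv(tracks: Mapping[str, LarvaTrack] | LarvaTrack, path) -> None:
    if isinstance(tracks, LarvaTrack):
        tracks = {tracks.larva_id: tracks}
    frames = []
    for larva, tr in tracks.items():
        frames.append(
            pd.DataFrame(
                {
                    "larva_id": larva,
                    "frame": np.arange(tr.n_frames),
                    "x": tr.centroid_xy[:, 0],
                    "y": tr.centroid_xy[:, 1],
                    "area": tr.area,
                    "spine_length": tr.spine_length,
                    "width": tr.width,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tiff(path, channel: int | None = None) -> np.ndarray:
    """Read a grayscale TIFF image or Z-stack.

    Multi-channel (RGB/RGBA) data requires an explicit ``channel``; 3-D output
    is a stack awaiting projection.
    """
    import tifffile

    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and min(arr.shape[:2]) > 4:
        if channel is None:
            raise ValidationError(
                f"{path}: multi-channel image; pass channel= to select one"
            )
        arr = arr[..., channel]
    if arr.ndim not in (2, 3):
        raise ValidationError(f"{path}: expected a 2-D image or 3-D stack, got shape {arr.shape}")
    return arr.astype(float)


def write_tiff(array: np.ndarray, path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(array), photometric="minisblack")


def read_diameters_csv(path, column: str = "diameter_um") -> np.ndarray:
    """Read a bouton diameter list (single ``diameter_um`` column)."""
    df = pd.read_csv(path)
    _require_columns(df, {column}, path)
    return _numeric(df, column, path).dropna().to_numpy()


def read_abundance_csv(path):
    """Read a protein- or peptide-level abundance table for the co-IP chain.

    Long layout with columns protein_id, experiment, group, abundance (or
    ``intensity`` plus ``peptide_id`` for peptide-level data, which is first
    collapsed with TOP3).  Returns an AbundanceMatrix at the 'raw' stage.
    """
    from .coip import AbundanceMatrix, top3_abundance

    df = pd.read_csv(path)
    if "peptide_id" in df.columns:
        _require_columns(df, {"protein_id", "peptide_id", "experiment", "group", "intensity"}, path)
        return top3_abundance(df)
    _require_columns(df, {"protein_id", "experiment", "group", "abundance"}, path)
    df["abundance"] = _numeric(df, "abundance", path)
    data = df.pivot_table(
        index="protein_id", columns=["experiment", "group"], values="abundance", aggfunc="first"
    ).sort_index(axis=1)
    meta_cols = [c for c in ("gene_symbol", "accession") if c in df.columns]
    meta = (
        df.drop_duplicates("protein_id").set_index("protein_id")[meta_cols].reindex(data.index)
        if meta_cols
        else None
    )
    if meta is not None:
        if "gene_symbol" not in meta:
            meta["gene_symbol"] = meta.index
        if "accession" not in meta:
            meta["accession"] = meta.index
    return AbundanceMatrix(data=data, meta=meta, stage="raw")
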