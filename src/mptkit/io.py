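"""Trajectory readers, writers, and quality filters.

Two on-disk formats are supported: the TrackMate-style tracking XML export
(read-only) and a canonical CSV with columns
``trajectory_id, frame, t_s, x_um, y_um`` (read/write, lossless round-trip).
Parsers are the only place unit conversion happens — everything downstream
consumes a :class:`~mptkit.trajectories.TrajectorySet` in μm and seconds.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .trajectories import FilterReport, Trajectory, TrajectorySet

log = logging.getLogger(__name__)

CSV_COLUMNS = ["trajectory_id", "frame", "t_s", "x_um", "y_um"]

# attribute aliases across tracking-XML dialects
_FRAME_ATTRS = ("t", "frame", "FRAME", "POSITION_T")
_X_ATTRS = ("x", "X", "POSITION_X")
_Y_ATTRS = ("y", "Y", "POSITION_Y")
_ID_ATTRS = ("id", "ID", "TRACK_ID", "name")


def _get_attr(elem: ET.Element, names: tuple[str, ...]) -> Optional[str]:
    for name in names:
        if name in elem.attrib:
            return elem.attrib[name]
    return None


def read_tracking_xml(
    path, frame_interval: float, unit_scale: float = 1.0
) -> TrajectorySet:
    """Read a tracking-XML export into a :class:`TrajectorySet`.

    Supports the TrackMate "Export tracks to XML" dialect
    (``<Tracks><particle><detection t= x= y=/>``) and generic
    ``<Track><Spot frame= x= y=/>`` exports. Positions are multiplied by
    ``unit_scale`` (μm per pixel; pass 1 if the file is already in μm) and
    times are ``frame × frame_interval``. Tracks with fewer than two spots
    are dropped with a logged warning.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed tracking XML {path}: {exc}") from exc

    track_elems = [
        el for el in root.iter() if el.tag.lower() in ("particle", "track")
    ]
    trajectories: list[Trajectory] = []
    n_dropped = 0
    for i, track in enumerate(track_elems):
        track_id = _get_attr(track, _ID_ATTRS) or str(i)
        spots = []
        for spot in track:
            if spot.tag.lower() not in ("detection", "spot"):
                continue
            frame = _get_attr(spot, _FRAME_ATTRS)
            x = _get_attr(spot, _X_ATTRS)
            y = _get_attr(spot, _Y_ATTRS)
            if frame is None or x is None or y is None:
                raise ValueError(
                    f"track {track_id!r}: spot missing frame/x/y attributes"
                )
            spots.append((int(float(frame)), float(x), float(y)))
        if len(spots) < 2:
            n_dropped += 1
            log.warning("dropping track %r with %d spot(s)", track_id, len(spots))
            continue
        spots.sort(key=lambda s: s[0])
        frames = np.array([s[0] for s in spots], dtype=np.int64)
        x_um = np.array([s[1] for s in spots]) * unit_scale
        y_um = np.array([s[2] for s in spots]) * unit_scale
        trajectories.append(
            Trajectory(track_id, frames, frames * frame_interval, x_um, y_um)
        )
    if n_dropped:
        log.info("dropped %d track(s) with < 2 spots", n_dropped)
    return TrajectorySet(trajectories, frame_interval, source=str(path))


def write_trajectory_csv(ts: TrajectorySet, path) -> None:
    """Write the canonical trajectory CSV, rows sorted by id then frame."""
    frames = []
    for tr in ts:
        frames.append(
            pd.DataFrame(
                {
                    "trajectory_id": tr.trajectory_id,
                    "frame": tr.frames,
                    "t_s": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["trajectory_id", "frame"], kind="mergesort")
    else:
        df = pd.DataFrame(columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path, frame_interval: Optional[float] = None) -> TrajectorySet:
    """Read the canonical trajectory CSV.

    ``frame_interval`` is inferred from the data (median of per-row Δt/Δframe)
    when not given; an empty file falls back to 1.0 s.
    """
    df = pd.read_csv(path, dtype={"trajectory_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.duplicated(subset=["trajectory_id", "frame"]).any():
        dup = df[df.duplicated(subset=["trajectory_id", "frame"], keep=False)]
        raise ValueError(
            f"{path}: duplicated (trajectory_id, frame) pairs, e.g. "
            f"{dup.iloc[0]['trajectory_id']!r} frame {dup.iloc[0]['frame']}"
        )
    df = df.sort_values(["trajectory_id", "frame"], kind="mergesort")
    trajectories = []
    dts = []
    for tid, sub in df.groupby("trajectory_id", sort=True):
        frames = sub["frame"].to_numpy(dtype=np.int64)
        t = sub["t_s"].to_numpy(dtype=np.float64)
        if len(frames) >= 2:
            step = np.diff(frames)
            dts.extend((np.diff(t) / step).tolist())
        trajectories.append(
            Trajectory(
                str(tid),
                frames,
                t,
                sub["x_um"].to_numpy(dtype=np.float64),
                sub["y_um"].to_numpy(dtype=np.float64),
            )
        )
    if frame_interval is None:
        frame_interval = float(np.median(dts)) if dts else 1.0
    return TrajectorySet(trajectories, frame_interval, source=str(path))


def filter_trajectories(
    ts: TrajectorySet,
    min_length: int = 10,
    max_gap: int = 1,
    gap_policy: str = "split",
) -> TrajectorySet:
    """Apply the pipeline's trajectory-quality filters.

    A *gap* is a frame step larger than ``max_gap`` (so the default
    ``max_gap=1`` tolerates only consecutive frames). Per ``gap_policy``,
    trajectories containing a gap are either dropped wholesale or split into
    gap-free segments (ids suffixed ``#s<k>``); splitting is the default
    because interpolating across a gap would fabricate displacements that
    bias the MSD downward at short lags. Afterwards anything shorter than
    ``min_length`` points is removed. A :class:`FilterReport` is attached to
    the returned set. The operation is idempotent.
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    if gap_policy not in ("drop", "split"):
        raise ValueError("gap_policy must be 'drop' or 'split'")
    report = FilterReport(n_input=len(ts))
    kept: list[Trajectory] = []
    for tr in ts:
        steps = np.diff(tr.frames)
        gap_positions = np.nonzero(steps > max_gap)[0]
        if gap_positions.size == 0:
            segments = [tr]
        elif gap_policy == "drop":
            report.n_gap_dropped += 1
            continue
        else:
            bounds = [0, *(gap_positions + 1), tr.n_points]
            segments = []
            for k in range(len(bounds) - 1):
                lo, hi = bounds[k], bounds[k + 1]
                if hi - lo < 2:
                    continue  # a 1-point fragment is not a trajectory
                segments.append(
                    Trajectory(
                        f"{tr.trajectory_id}#s{k}",
                        tr.frames[lo:hi],
                        tr.t[lo:hi],
                        tr.x[lo:hi],
                        tr.y[lo:hi],
                    )
                )
            report.n_split_segments += len(segments)
        for seg in segments:
            if seg.n_points >= min_length:
                kept.append(seg)
            else:
                report.n_removed_short += 1
    report.n_output = len(kept)
    out = TrajectorySet(kept, ts.frame_interval, source=ts.source)
    out.filter_report = report
    return out
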