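"""CSV/JSON plumbing for tracks, phases and solver output.

Times in labelled-track files are plain numbers in the track's native
unit (seconds for microscopy-scale data, days for telemetry); GPS
timestamps are ISO-8601 UTC and are converted to fractional days since
the first epoch midnight on read.  No unit conversion is ever applied.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import GPSTrack, LabelledTrack, Segment
from .simulator import SamplePath

__all__ = [
    "write_labelled_tracks", "read_labelled_tracks",
    "write_gps_tracks", "read_gps_tracks",
    "write_segments", "read_segments",
    "write_paths", "write_msd", "write_moments", "write_json",
]

GPS_EPOCH = pd.Timestamp("2012-07-01", tz="UTC")


def write_labelled_tracks(tracks: list[LabelledTrack], path):
    rows = [
        pd.DataFrame({"track_id": tr.track_id, "t": tr.t, "x": tr.x,
                      "y": tr.y, "state": tr.state})
        for tr in tracks
    ]
    df = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["track_id", "t", "x", "y", "state"])
    df.to_csv(path, index=False)


def read_labelled_tracks(path) -> list[LabelledTrack]:
    df = pd.read_csv(path, dtype={"track_id": str})
    return [
        LabelledTrack(g["t"].to_numpy(float), g["x"].to_numpy(float),
                      g["y"].to_numpy(float), g["state"].to_numpy(str), track_id=tid)
        for tid, g in df.groupby("track_id", sort=False)
    ]


def write_gps_tracks(tracks: list[GPSTrack], path, epoch: pd.Timestamp = GPS_EPOCH):
    rows = []
    for tr in tracks:
        ts = epoch + pd.to_timedelta(np.asarray(tr.t, dtype=float), unit="D")
        rows.append(pd.DataFrame({
            "track_id": tr.track_id,
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%fZ"),
            "lat": tr.lat, "lon": tr.lon,
        }))
    df = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame(columns=["track_id", "timestamp", "lat", "lon"])
    df.to_csv(path, index=False)


def read_gps_tracks(path) -> list[GPSTrack]:
    df = pd.read_csv(path, dtype={"track_id": str})
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    epoch = ts.min().normalize()
    days = (ts - epoch) / pd.Timedelta(days=1)
    df = df.assign(_days=days.to_numpy())
    return [
        GPSTrack(g["_days"].to_numpy(float), g["lat"].to_numpy(float),
                 g["lon"].to_numpy(float), track_id=tid)
        for tid, g in df.groupby("track_id", sort=False)
    ]


def write_segments(segments_by_track: dict[str, list[Segment]], path):
    rows = [
        {"track_id": tid, "state": s.state, "t_start": s.start,
         "t_end": s.end, "merged": s.merged}
        for tid, segs in segments_by_track.items() for s in segs
    ]
    pd.DataFrame(rows, columns=["track_id", "state", "t_start", "t_end", "merged"]) \
        .to_csv(path, index=False)


def read_segments(path) -> dict[str, list[Segment]]:
    df = pd.read_csv(path, dtype={"track_id": str})
    out: dict[str, list[Segment]] = {}
    for tid, g in df.groupby("track_id", sort=False):
        out[tid] = [Segment(r.state, r.t_start, r.t_end, bool(r.merged))
                    for r in g.itertuples()]
    return out


def write_paths(paths: list[SamplePath], path):
    rows = []
    for k, p in enumerate(paths):
        x, y = p.origin
        for i, ph in enumerate(p.phases):
            rows.append({
                "track_id": k, "phase_index": i, "state": ph.state,
                "t_start": ph.start_time, "duration": ph.duration,
                "vx": ph.velocity[0], "vy": ph.velocity[1],
                "x_start": x, "y_start": y,
            })
            if ph.state == "run":
                x += ph.velocity[0] * ph.duration
                y += ph.velocity[1] * ph.duration
    cols = ["track_id", "phase_index", "state", "t_start", "duration",
            "vx", "vy", "x_start", "y_start"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_msd(t, msd, n_paths: int, path):
    pd.DataFrame({"t": t, "msd": msd, "n_paths": n_paths}).to_csv(path, index=False)


def write_moments(state, path):
    df = pd.DataFrame({"t": state.t, **state.series})
    df["total_msd"] = (df["D_p2"] + df["D_r2"]) / state.n_total
    df.to_csv(path, index=False)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if hasattr(v, "spec_string"):
        return v.spec_string()
    return v


def write_json(obj: dict, path):
    Path(path).write_text(json.dumps({k: _jsonable(v) for k, v in obj.items()},
                                     indent=2) + "\n")
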