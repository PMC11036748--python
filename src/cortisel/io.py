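"""CSV/JSON readers and writers for tracks, samples, events, and fits.

Tracks use a Movebank-like layout: individual_id, timestamp (ISO-8601 UTC),
x, y in projected metres.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CalvingEvent, FgmSample, Track


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "individual_id": t.individual_id,
                "timestamp": t.t.astype("datetime64[s]"),
                "x": t.x,
                "y": t.y,
            }
        )
        for t in tracks
    ]
    return pd.concat(frames, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    out = []
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp")
        out.append(
            Track(
                str(ind),
                grp["timestamp"].to_numpy().astype("datetime64[s]"),
                grp["x"].to_numpy(float),
                grp["y"].to_numpy(float),
            )
        )
    return out


def write_tracks(tracks: list[Track], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return frame_to_tracks(df)


def samples_to_frame(samples: list[FgmSample]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in samples])


def write_samples(samples: list[FgmSample], path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def read_samples(path) -> list[FgmSample]:
    df = pd.read_csv(path, parse_dates=["collection_time", "deposition_time"])
    out = []
    for _, r in df.iterrows():
        out.append(
            FgmSample(
                sample_id=str(r["sample_id"]),
                suspected_individual=str(r["suspected_individual"]),
                collection_time=np.datetime64(r["collection_time"], "s"),
                deposition_time=np.datetime64(r["deposition_time"], "s"),
                concentration=float(r["concentration"]),
                dna_identified=bool(r.get("dna_identified", False)),
                true_individual=(
                    str(r["true_individual"]) if pd.notna(r.get("true_individual")) else None
                ),
                x=float(r["x"]) if pd.notna(r.get("x")) else None,
                y=float(r["y"]) if pd.notna(r.get("y")) else None,
            )
        )
    return out


def write_events(events: list[CalvingEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": e.individual_id,
                "calving_date": e.calving_date.isoformat(),
                "confirmed": e.confirmed,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


def read_events(path) -> list[CalvingEvent]:
    df = pd.read_csv(path)
    return [
        CalvingEvent(
            str(r["individual_id"]),
            date.fromisoformat(str(r["calving_date"])),
            bool(r.get("confirmed", False)),
        )
        for _, r in df.iterrows()
    ]


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.datetime64, date)):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
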