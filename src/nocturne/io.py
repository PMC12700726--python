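"""Delimited-text I/O for the pipeline's inputs and outputs.

All interchange formats are plain CSV with ISO-8601 timestamps.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import AciWindow, HourlyAci
from .events import (
    BehaviorRecord,
    EventContext,
    HourlyCounts,
    RawCall,
    VocalEvent,
)
from .social import DaiMatrix, ProximityData

__all__ = [
    "read_calls_csv",
    "read_behaviors_csv",
    "write_events_csv",
    "write_contexts_csv",
    "write_hourly_counts_csv",
    "write_aci_windows_csv",
    "write_hourly_aci_csv",
    "read_proximity_csv",
    "read_agonistic_csv",
    "read_pedigree_csv",
    "write_dai_csv",
]


def read_calls_csv(path: str | Path) -> list[RawCall]:
    df = pd.read_csv(path, parse_dates=["time"])
    caller = df["caller_id"] if "caller_id" in df else pd.Series([None] * len(df))
    return [
        RawCall(time=t.to_pydatetime(), caller_id=None if pd.isna(c) else str(c))
        for t, c in zip(df["time"], caller)
    ]


def read_behaviors_csv(path: str | Path) -> list[BehaviorRecord]:
    df = pd.read_csv(path, parse_dates=["time"])
    return [
        BehaviorRecord(
            time=row.time.to_pydatetime(),
            individual_id=str(row.individual_id),
            behavior=str(row.behavior),
        )
        for row in df.itertuples()
    ]


def write_events_csv(path: str | Path, events: list[VocalEvent]) -> None:
    pd.DataFrame(
        {
            "event_id": range(len(events)),
            "start": [e.start.isoformat() for e in events],
            "end": [e.end.isoformat() for e in events],
            "n_calls": [e.n_calls for e in events],
            "caller_id": [e.caller_id for e in events],
        }
    ).to_csv(path, index=False)


def write_contexts_csv(path: str | Path, contexts: list[EventContext]) -> None:
    rows = []
    for eid, ctx in enumerate(contexts):
        for phase, records in (("pre", ctx.pre), ("post", ctx.post)):
            for rec in records:
                rows.append(
                    {
                        "event_id": eid,
                        "phase": phase,
                        "time": rec.time.isoformat(),
                        "individual_id": rec.individual_id,
                        "behavior": rec.behavior,
                        "category": rec.category,
                    }
                )
    pd.DataFrame(
        rows, columns=["event_id", "phase", "time", "individual_id", "behavior", "category"]
    ).to_csv(path, index=False)


def write_hourly_counts_csv(path: str | Path, counts: list[HourlyCounts]) -> None:
    pd.DataFrame({"hour": [c.hour for c in counts], "n_events": [c.n_events for c in counts]}).to_csv(
        path, index=False
    )


def write_aci_windows_csv(path: str | Path, windows: list[AciWindow]) -> None:
    pd.DataFrame(
        {
            "window_index": [w.window_index for w in windows],
            "start_time": [None if w.start_time is None else w.start_time.isoformat() for w in windows],
            "aci": [w.aci for w in windows],
        }
    ).to_csv(path, index=False)


def write_hourly_aci_csv(path: str | Path, hourly: list[HourlyAci]) -> None:
    pd.DataFrame(
        {
            "hour": [h.hour for h in hourly],
            "aci": [h.aci for h in hourly],
            "n_windows": [h.n_windows for h in hourly],
        }
    ).to_csv(path, index=False)


def read_proximity_csv(dyads_path: str | Path, focal_path: str | Path) -> ProximityData:
    """Build ProximityData from long dyad CSV (id_a,id_b,seconds) + focal CSV (id,seconds)."""
    dy = pd.read_csv(dyads_path)
    fo = pd.read_csv(focal_path)
    ids = list(fo["id"].astype(str))
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    mat = np.zeros((n, n))
    for row in dy.itertuples():
        i, j = index[str(row.id_a)], index[str(row.id_b)]
        mat[i, j] = mat[j, i] = float(row.seconds)
    return ProximityData(ids=ids, dyad_seconds=mat, focal_seconds=fo["seconds"].to_numpy(float))


def read_agonistic_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Win matrix from long CSV (winner, loser, count)."""
    df = pd.read_csv(path)
    ids = sorted(set(df["winner"].astype(str)) | set(df["loser"].astype(str)))
    index = {v: i for i, v in enumerate(ids)}
    wins = np.zeros((len(ids), len(ids)))
    for row in df.itertuples():
        wins[index[str(row.winner)], index[str(row.loser)]] += float(row.count)
    return wins, ids


def read_pedigree_csv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path)
    return [(str(r.parent), str(r.offspring)) for r in df.itertuples()]


def write_dai_csv(path: str | Path, m: DaiMatrix) -> None:
    pd.DataFrame(m.values, index=m.ids, columns=m.ids).to_csv(path, index_label="id")
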