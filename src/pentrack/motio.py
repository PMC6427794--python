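"""MOTChallenge-style CSV readers/writers and the structured event log.

File rows are ``frame,id,x,y,w,h,conf`` with 1-based integer frames and ids
and top-left box coordinates; internally frames are 0-based and coordinates
continuous.  Ground-truth files carry ``conf = -1``, hypothesis files
``conf = 1.0``.  The event log is JSON lines, one object per frame, and can
be replayed into the exact per-frame association events.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .association import AssociationEvents, StateLabel
from .geometry import Box
from .metrics import TrajectorySet

__all__ = ["read_mot", "write_mot", "write_event_log", "replay_events"]

_COLUMNS = ["frame", "id", "x", "y", "w", "h", "conf"]


def read_mot(path: str | Path) -> TrajectorySet:
    """Parse a MOT CSV into a trajectory set (frames converted to 0-based)."""
    path = Path(path)
    traj = TrajectorySet()
    try:
        df = pd.read_csv(path, header=None, usecols=range(7), names=_COLUMNS)
    except pd.errors.EmptyDataError:
        return traj
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            frame = int(row.frame)
            id_ = int(row.id)
            box = Box(float(row.x), float(row.y), float(row.w), float(row.h))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{row_no}: malformed row ({exc})") from None
        if frame < 1:
            raise ValueError(f"{path}:{row_no}: frame numbers are 1-based")
        try:
            traj.add(frame - 1, id_, box)
        except ValueError:
            raise ValueError(f"{path}:{row_no}: duplicate (frame={frame}, id={id_})") from None
    return traj


def write_mot(traj: TrajectorySet, path: str | Path, conf: float = 1.0) -> None:
    """Write a trajectory set as MOT CSV, sorted by frame then id, 2 decimals."""
    rows = []
    for t in sorted(traj.frames):
        for id_ in sorted(traj.frames[t]):
            b = traj.frames[t][id_]
            rows.append((t + 1, id_, round(b.x, 2), round(b.y, 2),
                         round(b.w, 2), round(b.h, 2), conf))
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{r[0]},{r[1]},{r[2]:.2f},{r[3]:.2f},{r[4]:.2f},{r[5]:.2f},{r[6]}\n")


def write_event_log(
    path: str | Path,
    per_frame: list[tuple[int, dict[int, StateLabel], AssociationEvents]],
) -> None:
    """Write one JSON object per frame: state labels plus event id lists."""
    with open(path, "w") as fh:
        for t, states, ev in per_frame:
            rec = {
                "frame": t,
                "states": {str(i): s.value for i, s in states.items()},
                "reinitialized": ev.reinitialized,
                "pended": ev.pended,
                "refined": ev.refined,
            }
            fh.write(json.dumps(rec) + "\n")


def replay_events(path: str | Path) -> list[tuple[int, dict[int, StateLabel], AssociationEvents]]:
    """Reconstruct the per-frame states and events from an event log."""
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            states = {int(i): StateLabel(v) for i, v in rec["states"].items()}
            ev = AssociationEvents(
                reinitialized=list(rec["reinitialized"]),
                pended=list(rec["pended"]),
                refined=list(rec["refined"]),
            )
            out.append((rec["frame"], states, ev))
    return out
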