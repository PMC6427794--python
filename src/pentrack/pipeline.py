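"""End-to-end tracking pipeline: detectors + per-animal trackers + association.

One tag-box tracker is initialized per first-frame bounding box (the manual
delineation step on real footage; the ground-truth first frame on synthetic
scenes).  Per subsequent frame, all trackers are stepped, the detection
stream for that frame is associated with the tag-boxes, and any
re-initializations requested by the association layer are executed by
re-seeding the affected tracker from its associated detection box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Mapping, Sequence

import numpy as np

from .association import (
    AssociationConfig,
    AssociationEvents,
    StateLabel,
    TrackSet,
    associate_frame,
)
from .dcf import TrackerConfig, TrackerState, init_tracker, step
from .detection import DetectionOutput
from .geometry import Box
from .metrics import TrajectorySet

__all__ = ["RunConfig", "TrackingResult", "run_tracking", "make_config"]


@dataclass
class TrackingResult:
    """Output trajectories plus the per-frame state/event log."""

    trajectories: TrajectorySet
    log: list[tuple[int, dict[int, StateLabel], AssociationEvents]]

    @property
    def events(self) -> list[AssociationEvents]:
        return [ev for _, _, ev in self.log]


@dataclass
class RunConfig:
    """Typed run configuration assembled from the YAML sections."""

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    score_threshold: float = 0.5
    seed: int = 0


def _from_section(cls, section: Mapping | None):
    section = dict(section or {})
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for key in ("scales",):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    return cls(**section)


def make_config(raw: Mapping) -> RunConfig:
    """Build a :class:`RunConfig` from a nested mapping, rejecting unknown keys."""
    known = {"tracker", "association", "detector", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    det = dict(raw.get("detector") or {})
    thr = det.pop("score_threshold", 0.5)
    return RunConfig(
        tracker=_from_section(TrackerConfig, raw.get("tracker")),
        association=_from_section(AssociationConfig, raw.get("association")),
        score_threshold=float(thr),
        seed=int(raw.get("seed", 0)),
    )


def _clip_box(b: Box, fw: int, fh: int) -> Box:
    x1 = float(np.clip(b.x, 0, fw - 4))
    y1 = float(np.clip(b.y, 0, fh - 4))
    x2 = float(np.clip(b.x2, x1 + 4, fw))
    y2 = float(np.clip(b.y2, y1 + 4, fh))
    return Box(x1, y1, x2 - x1, y2 - y1)


def run_tracking(
    frames: Sequence[np.ndarray] | Callable[[int], np.ndarray],
    n_frames: int | None,
    first_boxes: Mapping[int, Box],
    detections: Mapping[int, DetectionOutput] | Callable[[np.ndarray], DetectionOutput],
    config: RunConfig | None = None,
) -> TrackingResult:
    """Track all animals through a sequence.

    ``frames`` is an in-memory sequence or a callable ``t -> image``;
    ``detections`` is a per-frame precomputed stream (``{t: DetectionOutput}``)
    or a detector plug-in applied to each frame.  Frame 0 always emits the
    first-frame boxes themselves.
    """
    cfg = config or RunConfig()
    if callable(frames):
        if n_frames is None:
            raise ValueError("n_frames is required with a frame callable")
        get_frame = frames
    else:
        n_frames = len(frames) if n_frames is None else n_frames
        get_frame = frames.__getitem__
    if not first_boxes:
        raise ValueError("missing first-frame boxes")
    if isinstance(detections, Mapping):
        missing = [t for t in range(1, n_frames) if t not in detections]
        if missing:
            raise ValueError(f"detections missing for frames {missing[:5]}...")

    frame0 = get_frame(0)
    fh, fw = frame0.shape[:2]
    trackers: dict[int, TrackerState] = {
        i: init_tracker(frame0, _clip_box(b, fw, fh), cfg.tracker)
        for i, b in first_boxes.items()
    }
    trackset = TrackSet.from_initial_boxes(dict(first_boxes), t=0)
    traj = TrajectorySet()
    for i, b in first_boxes.items():
        traj.add(0, i, b)
    log: list[tuple[int, dict[int, StateLabel], AssociationEvents]] = []

    for t in range(1, n_frames):
        frame = get_frame(t)
        tag_boxes: dict[int, Box] = {}
        for i, tr in trackers.items():
            trackers[i], tb = step(tr, frame, t)
            tag_boxes[i] = tb
        if isinstance(detections, Mapping):
            det = detections[t]
        else:
            det = detections(frame)
        keep = [k for k, s in enumerate(det.scores) if s >= cfg.score_threshold]
        det_boxes = [det.boxes[k] for k in keep]
        outputs, states, events = associate_frame(det_boxes, tag_boxes, trackset, t, cfg.association)
        for i in events.reinitialized:
            box = _clip_box(events.reinit_boxes[i], fw, fh)
            trackers[i] = init_tracker(frame, box, cfg.tracker)
        for i, b in outputs.items():
            traj.add(t, i, b)
        log.append((t, states, events))
    return TrackingResult(traj, log)
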