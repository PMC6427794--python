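"""CLEAR-MOT style evaluation of multi-object trajectories.

Per frame, ground-truth and hypothesis boxes are matched one-to-one by
minimum total ``1 - IoU`` cost, keeping the previous frame's matches alive
whenever they still overlap at the acceptance threshold (the standard
continuation rule that makes identity switches meaningful).  The report
aggregates recall, precision, false alarms per frame, mostly/partially/mostly-
lost trajectory counts (80%/20% coverage), identity switches, fragmentations,
and MOTA = 1 - (FN + FP + IDs) / GT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Box, jaccard

__all__ = ["TrajectorySet", "MotEvents", "MetricsReport", "match_frames", "compute_report", "evaluate"]


@dataclass
class TrajectorySet:
    """Per-frame ``{id: Box}`` maps over a contiguous 0-based frame range."""

    frames: dict[int, dict[int, Box]] = field(default_factory=dict)

    def add(self, frame: int, id_: int, box: Box) -> None:
        fr = self.frames.setdefault(frame, {})
        if id_ in fr:
            raise ValueError(f"duplicate (frame={frame}, id={id_})")
        fr[id_] = box

    @property
    def frame_range(self) -> range:
        if not self.frames:
            return range(0)
        return range(min(self.frames), max(self.frames) + 1)

    @property
    def ids(self) -> set[int]:
        out: set[int] = set()
        for fr in self.frames.values():
            out.update(fr)
        return out

    def __len__(self) -> int:
        return sum(len(fr) for fr in self.frames.values())


@dataclass
class MotEvents:
    """Raw per-sequence tallies produced by frame matching."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    id_switches: int = 0
    fragmentations: int = 0
    n_frames: int = 0
    n_gt: int = 0
    # per-GT-trajectory: frames present and frames matched
    gt_presence: dict[int, int] = field(default_factory=dict)
    gt_tracked: dict[int, int] = field(default_factory=dict)


def match_frames(
    gt: TrajectorySet, hyp: TrajectorySet, iou_threshold: float = 0.5
) -> MotEvents:
    """Frame-by-frame matching with continuation preference.

    Identity switches are counted when a ground-truth object's matched
    hypothesis id differs from its last known match; a fragmentation is a
    tracked-to-untracked toggle after the first acquisition (resumed tracking
    does not remove it).
    """
    ev = MotEvents()
    frames = sorted(set(gt.frame_range) | set(hyp.frame_range))
    ev.n_frames = len(frames)
    prev_match: dict[int, int] = {}      # gt id -> hyp id matched in previous frame
    last_known: dict[int, int] = {}      # gt id -> last hyp id ever matched
    was_tracked: dict[int, bool] = {}    # gt id -> tracked status in previous frame
    seen: set[int] = set()               # gt ids acquired at least once
    for t in frames:
        g = gt.frames.get(t, {})
        h = hyp.frames.get(t, {})
        ev.n_gt += len(g)
        for gid in g:
            ev.gt_presence[gid] = ev.gt_presence.get(gid, 0) + 1
        matches: dict[int, int] = {}
        # continuation: keep last frame's pairs that still overlap
        free_h = set(h)
        for gid, hid in prev_match.items():
            if gid in g and hid in free_h and jaccard(g[gid], h[hid]) >= iou_threshold:
                matches[gid] = hid
                free_h.discard(hid)
        rem_g = [gid for gid in sorted(g) if gid not in matches]
        rem_h = sorted(free_h)
        if rem_g and rem_h:
            cost = np.ones((len(rem_g), len(rem_h)))
            for a, gid in enumerate(rem_g):
                for b, hid in enumerate(rem_h):
                    iou = jaccard(g[gid], h[hid])
                    if iou >= iou_threshold:
                        cost[a, b] = 1.0 - iou
            rows, cols = linear_sum_assignment(cost)
            for a, b in zip(rows, cols):
                if cost[a, b] < 1.0 - iou_threshold + 1e-12:
                    matches[rem_g[a]] = rem_h[b]
        ev.tp += len(matches)
        ev.fn += len(g) - len(matches)
        ev.fp += len(h) - len(matches)
        for gid, hid in matches.items():
            ev.gt_tracked[gid] = ev.gt_tracked.get(gid, 0) + 1
            if gid in last_known and last_known[gid] != hid:
                ev.id_switches += 1
            last_known[gid] = hid
        for gid in g:
            tracked_now = gid in matches
            if was_tracked.get(gid, False) and not tracked_now and gid in seen:
                ev.fragmentations += 1
            if tracked_now:
                seen.add(gid)
            was_tracked[gid] = tracked_now
        prev_match = matches
    return ev


@dataclass
class MetricsReport:
    """The evaluation table: percentages for recall/precision/MOTA, counts otherwise."""

    recall: float
    precision: float
    faf: float
    mt: int
    pt: int
    ml: int
    ids: int
    fra: int
    mota: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Recall": self.recall, "Precision": self.precision, "FAF": self.faf,
            "MT": self.mt, "PT": self.pt, "ML": self.ml,
            "IDs": self.ids, "FRA": self.fra, "MOTA": self.mota,
        }


def compute_report(ev: MotEvents, mt_threshold: float = 0.8, ml_threshold: float = 0.2) -> MetricsReport:
    """Aggregate raw matching events into the standard metric set."""
    if ev.n_gt == 0:
        raise ValueError("no ground-truth boxes: recall undefined")
    recall = 100.0 * ev.tp / ev.n_gt
    precision = 100.0 * ev.tp / max(ev.tp + ev.fp, 1)
    faf = ev.fp / max(ev.n_frames, 1)
    mota = 100.0 * (1.0 - (ev.fn + ev.fp + ev.id_switches) / ev.n_gt)
    mt = pt = ml = 0
    for gid, present in ev.gt_presence.items():
        cov = ev.gt_tracked.get(gid, 0) / present
        if cov >= mt_threshold:
            mt += 1
        elif cov < ml_threshold:
            ml += 1
        else:
            pt += 1
    return MetricsReport(recall, precision, faf, mt, pt, ml,
                         ev.id_switches, ev.fragmentations, mota)


def evaluate(gt: TrajectorySet, hyp: TrajectorySet, iou_threshold: float = 0.5) -> MetricsReport:
    """Convenience wrapper: match frames then aggregate the report."""
    return compute_report(match_frames(gt, hyp, iou_threshold))
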