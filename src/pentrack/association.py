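"""Hierarchical data association between detections and tracked tag-boxes.

The pen is closed and the camera fixed, so the number of animals ``N`` is
constant: every frame must emit exactly ``N`` boxes carrying the original
identities.  Each animal's per-frame condition is one of four states read off
the spatial relation between detection boxes ``Db`` and tag-boxes ``Tb``:

1. *tracked* — a detection contains exactly one tag-box (one-to-one match);
2. *tracking drift* — the tag-box lies outside every detection; a
   buffer-and-recover age counter accumulates and the tracker is
   re-initialized from the associated detection once the age exceeds ``T``;
3. *unstable detection* — the animal's default box (its last tracked box)
   matched no detection; the output is refined from the unassigned detections
   or falls back to the default box itself;
4. *tracking drift (multi)* — a detection contains more than one tag-box;
   the lower-confidence tag-box is *pended* (excluded from matching), which
   routes it through state 2 toward re-initialization.

Assignment minimizes a containment-overlap / centre-distance cost solved by
the Hungarian algorithm; zero-overlap pairs are infeasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Box, center_distance, diag, intersection_area

__all__ = [
    "StateLabel",
    "AssociationConfig",
    "Tracklet",
    "TrackSet",
    "AssociationEvents",
    "containment_overlap",
    "pair_cost",
    "hungarian_assign",
    "classify_states",
    "refine_unstable_detection",
    "update_age",
    "pend_tag_box",
    "associate_frame",
]

SENTINEL = 1e9


class StateLabel(Enum):
    TRACKED = "tracked"
    DRIFT_UNASSIGNED = "drift_unassigned"
    UNSTABLE_DETECTION = "unstable_detection"
    DRIFT_MULTI = "drift_multi"


@dataclass(frozen=True)
class AssociationConfig:
    """Parameters of the association layer (the ``association`` config section)."""

    delta: float = 1.0          # weight of the centre-distance term in the cost
    age_threshold: int = 20     # frames of sustained drift before re-initialization
    sentinel: float = SENTINEL  # cost marking an infeasible (zero-overlap) pair
    lag: int = 1                # tracklet lag used for the default box
    contain_threshold: float = 0.5  # tag-box fraction inside a detection to count as "contained"


@dataclass
class Tracklet:
    """One animal's identity-stable trajectory fragment."""

    id: int
    history: list[tuple[int, Box]] = field(default_factory=list)

    @property
    def last_box(self) -> Box | None:
        return self.history[-1][1] if self.history else None

    def append(self, t: int, box: Box) -> None:
        if self.history and t <= self.history[-1][0]:
            raise ValueError("history frame indices must be strictly increasing")
        self.history.append((t, box))


@dataclass
class TrackSet:
    """The fixed-identity track collection plus age counters and pending flags."""

    tracklets: dict[int, Tracklet]
    ages: dict[int, int] = field(default_factory=dict)
    pending: set[int] = field(default_factory=set)

    @classmethod
    def from_initial_boxes(cls, boxes: dict[int, Box], t: int = 0) -> "TrackSet":
        tracklets = {i: Tracklet(i, [(t, b)]) for i, b in boxes.items()}
        return cls(tracklets, ages={i: 0 for i in boxes})

    @property
    def ids(self) -> list[int]:
        return sorted(self.tracklets)

    @property
    def n(self) -> int:
        return len(self.tracklets)


@dataclass
class AssociationEvents:
    """Per-frame event lists emitted by the association layer."""

    reinitialized: list[int] = field(default_factory=list)
    pended: list[int] = field(default_factory=list)
    refined: list[int] = field(default_factory=list)
    reinit_boxes: dict[int, Box] = field(default_factory=dict)


def containment_overlap(db: Box, tb: Box) -> float:
    """Asymmetric overlap: intersection area over the tag-box's own area."""
    return intersection_area(db, tb) / tb.area


def pair_cost(db: Box, tb: Box, delta: float = 1.0, sentinel: float = SENTINEL) -> float:
    """Association cost between a detection and a tag-box (lower = closer).

    ``-log(overlap) + delta * centre_distance / diag(db)`` for positive
    containment overlap; zero overlap makes the pair infeasible (sentinel).
    """
    ov = containment_overlap(db, tb)
    if ov <= 0.0:
        return sentinel
    return -math.log(ov) + delta * center_distance(db, tb) / diag(db)


def hungarian_assign(cost: np.ndarray, sentinel: float = SENTINEL) -> list[tuple[int, int]]:
    """Minimum-cost one-to-one partial assignment.

    Pairs whose cost reaches the sentinel are reported unassigned.  Ties are
    broken deterministically toward lower row, then column, indices via an
    infinitesimal index perturbation.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return []
    n_r, n_c = cost.shape
    tie = np.arange(n_r * n_c, dtype=float).reshape(n_r, n_c)
    span = max(float(np.max(np.abs(cost[cost < sentinel]), initial=1.0)), 1.0)
    rows, cols = linear_sum_assignment(cost + tie * (1e-9 * span / (n_r * n_c)))
    return [(int(r), int(c)) for r, c in zip(rows, cols) if cost[r, c] < sentinel]


def _build_cost_matrix(
    detections: list[Box],
    tag_boxes: list[Box],
    pending_cols: set[int],
    cfg: AssociationConfig,
) -> np.ndarray:
    cost = np.full((len(detections), len(tag_boxes)), cfg.sentinel)
    for j, db in enumerate(detections):
        for i, tb in enumerate(tag_boxes):
            if i in pending_cols:
                continue
            cost[j, i] = pair_cost(db, tb, cfg.delta, cfg.sentinel)
    return cost


def classify_states(
    assignment: list[tuple[int, int]],
    detections: list[Box],
    tag_boxes: dict[int, Box],
    trackset: TrackSet,
    cfg: AssociationConfig | None = None,
) -> dict[int, StateLabel]:
    """Assign exactly one state label to every animal for this frame.

    ``assignment`` pairs detection indices with positions in the sorted id
    list.  Unassigned tag-boxes are split into: pending or fully detached
    (drift), contained in an already-assigned detection (multi-drift), or
    still covered by their own default box while the detection went missing
    (unstable detection).
    """
    cfg = cfg or AssociationConfig()
    ids = trackset.ids
    assigned_ids = {ids[c] for _, c in assignment}
    assigned_dets = [detections[r] for r, _ in assignment]
    states: dict[int, StateLabel] = {}
    for i in ids:
        if i in assigned_ids:
            states[i] = StateLabel.TRACKED
            continue
        tb = tag_boxes[i]
        if i not in trackset.pending and any(
            containment_overlap(db, tb) >= cfg.contain_threshold for db in assigned_dets
        ):
            states[i] = StateLabel.DRIFT_MULTI
            continue
        default = trackset.tracklets[i].last_box
        if (
            i not in trackset.pending
            and default is not None
            and containment_overlap(default, tb) > 0.0
        ):
            states[i] = StateLabel.UNSTABLE_DETECTION
        else:
            states[i] = StateLabel.DRIFT_UNASSIGNED
    return states


def refine_unstable_detection(
    id_: int,
    unassigned_dets: list[Box],
    trackset: TrackSet,
    tag_boxes: dict[int, Box] | None = None,
    cfg: AssociationConfig | None = None,
) -> tuple[Box, bool]:
    """Recover this frame's output box for an animal whose detection is missing.

    The default box is the tracklet's last tracked box (lag 1, no motion
    extrapolation).  Unassigned detections are matched to it with the pair
    cost; the best feasible match becomes the output, otherwise the default
    box itself is emitted.  Returns ``(box, from_detection)``.
    """
    cfg = cfg or AssociationConfig()
    default = trackset.tracklets[id_].last_box
    if default is None:
        # no history: fall back to a box centred on the current tag-box
        tb = tag_boxes[id_] if tag_boxes else None
        if tb is None:
            raise ValueError("no history and no tag-box to fall back on")
        default = tb
    best: tuple[float, int] | None = None
    for k, db in enumerate(unassigned_dets):
        c = pair_cost(db, default, cfg.delta, cfg.sentinel)
        if c < cfg.sentinel and (best is None or c < best[0]):
            best = (c, k)
    if best is not None:
        return unassigned_dets[best[1]], True
    return default, False


def update_age(
    trackset: TrackSet,
    states: dict[int, StateLabel],
    tag_boxes: dict[int, Box],
    cfg: AssociationConfig | None = None,
) -> list[int]:
    """Advance the buffer-and-recover age counters; return ids due for re-init.

    For every animal passing through the unassigned branch, the age rises by
    one if its default box no longer covers its tag-box (sustained drift) and
    falls by one (floored at zero) otherwise.  Ids whose age exceeds the
    threshold are returned; the caller resets the age when the
    re-initialization actually happens.
    """
    cfg = cfg or AssociationConfig()
    due: list[int] = []
    for i, st in states.items():
        if st is StateLabel.TRACKED:
            continue
        default = trackset.tracklets[i].last_box
        matched = (
            i not in trackset.pending
            and default is not None
            and containment_overlap(default, tag_boxes[i]) > 0.0
        )
        if matched:
            trackset.ages[i] = max(0, trackset.ages[i] - 1)
        else:
            trackset.ages[i] += 1
        if trackset.ages[i] > cfg.age_threshold:
            due.append(i)
    return due


def pend_tag_box(id_: int, trackset: TrackSet,
                 states: dict[int, StateLabel] | None = None) -> TrackSet:
    """Pend a multi-drift tag-box: exclude it from overlap with any detection.

    Pending is a flag rather than literal off-canvas coordinates; pended ids
    classify as drift in subsequent frames, feeding the age counter toward
    re-initialization.  Ids not in the multi-drift state are left unchanged.
    """
    if states is not None and states.get(id_) is not StateLabel.DRIFT_MULTI:
        return trackset
    trackset.pending.add(id_)
    return trackset


def associate_frame(
    detections: list[Box],
    tag_boxes: dict[int, Box],
    trackset: TrackSet,
    t: int,
    cfg: AssociationConfig | None = None,
) -> tuple[dict[int, Box], dict[int, StateLabel], AssociationEvents]:
    """Run the full hierarchical association for one frame.

    Primary association matches detections to tag-boxes; tracked animals emit
    their matched detection.  Every unassigned tag-box is then handled: its
    output is refined from the unassigned detections (or the default box),
    its age counter moves, re-initializations fire when the age passes the
    threshold and a detection-derived box is available, and multi-contained
    tag-boxes are pended.  Exactly ``N`` boxes with the fixed id set are
    returned and every tracklet grows by one frame.
    """
    cfg = cfg or AssociationConfig()
    ids = trackset.ids
    if len(tag_boxes) != trackset.n:
        raise ValueError("need one tag-box per tracked animal")
    tb_list = [tag_boxes[i] for i in ids]
    pending_cols = {ids.index(i) for i in trackset.pending}
    cost = _build_cost_matrix(detections, tb_list, pending_cols, cfg)
    assignment = hungarian_assign(cost, cfg.sentinel)
    states = classify_states(assignment, detections, tag_boxes, trackset, cfg)

    outputs: dict[int, Box] = {}
    from_detection: dict[int, bool] = {}
    assigned_det_idx = {r for r, _ in assignment}
    for r, c in assignment:
        outputs[ids[c]] = detections[r]
        from_detection[ids[c]] = True
    unassigned_dets = [d for k, d in enumerate(detections) if k not in assigned_det_idx]

    events = AssociationEvents()
    for i in ids:
        if states[i] is StateLabel.TRACKED:
            continue
        box, from_det = refine_unstable_detection(i, unassigned_dets, trackset, tag_boxes, cfg)
        if from_det:
            unassigned_dets.remove(box)
            events.refined.append(i)
        outputs[i] = box
        from_detection[i] = from_det

    due = update_age(trackset, states, tag_boxes, cfg)
    for i in due:
        # re-initialize only from a real detection; otherwise defer (the age
        # keeps growing, so the next detection-backed frame triggers it)
        if from_detection.get(i):
            events.reinitialized.append(i)
            events.reinit_boxes[i] = outputs[i]
            trackset.ages[i] = 0
            trackset.pending.discard(i)

    for i in ids:
        if states[i] is StateLabel.DRIFT_MULTI:
            pend_tag_box(i, trackset, states)
            events.pended.append(i)

    for i in ids:
        trackset.tracklets[i].append(t, outputs[i])
    return outputs, states, events
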