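"""Default-box (anchor) geometry and the two-class detection loss.

A one-stage detector tiles every feature map cell with ``k`` default boxes at
multiple scales and aspect ratios, labels them against ground truth with a
two-stage Jaccard matching rule, balances classes by 1:3 hard-negative mining,
and trains with a combined log-loss / smooth-L1 objective.  All of that
machinery is implemented here as pure functions so it is testable without a
trained network; actual per-frame detections enter the pipeline through the
pluggable :class:`Detector` contract (or a precomputed CSV stream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .geometry import Box, jaccard

__all__ = [
    "FeatureMapSpec",
    "DefaultBoxGrid",
    "MatchLabels",
    "DetectionOutput",
    "Detector",
    "default_box_scales",
    "generate_default_boxes",
    "standard_feature_maps",
    "match_default_boxes",
    "hard_negative_mine",
    "smooth_l1",
    "encode_box",
    "detection_loss",
    "register_detector",
    "get_detector",
]


@dataclass(frozen=True)
class FeatureMapSpec:
    """One prediction layer: an ``m x n`` grid with ``k`` boxes per cell.

    ``boxes_per_cell`` may exceed ``len(aspect_ratios)`` by one, in which case
    an extra unit-aspect box at the geometric-mean scale of this layer and the
    next is added (the conventional arrangement).
    """

    grid_rows: int
    grid_cols: int
    boxes_per_cell: int
    aspect_ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if min(self.grid_rows, self.grid_cols, self.boxes_per_cell) < 1:
            raise ValueError("grid dimensions and boxes_per_cell must be >= 1")
        if self.boxes_per_cell not in (len(self.aspect_ratios), len(self.aspect_ratios) + 1):
            raise ValueError(
                "boxes_per_cell must equal len(aspect_ratios) or len(aspect_ratios)+1"
            )


@dataclass
class DefaultBoxGrid:
    """The full multi-layer anchor lattice in normalized [0,1] coordinates.

    Boxes that extend past the image border are retained; ``clip`` only
    records whether the caller asked for clipping when decoding.
    """

    boxes: list[Box]
    layer_of_box: np.ndarray
    clip: bool = False

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass
class MatchLabels:
    """Per-default-box labels from ground-truth matching.

    ``gt_of_box[i]`` is the matched ground-truth index or -1 for negatives.
    ``regression_target[i]`` holds the 4-vector encoding of the matched GT
    relative to default box ``i`` (rows for negatives are zero and unused).
    """

    gt_of_box: np.ndarray
    regression_target: np.ndarray
    grid: DefaultBoxGrid

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.gt_of_box >= 0)

    @property
    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.gt_of_box < 0)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.gt_of_box >= 0))


@dataclass
class DetectionOutput:
    """Per-frame detector output: boxes with object-class probabilities."""

    boxes: list[Box]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.boxes) != len(self.scores):
            raise ValueError("boxes and scores must have equal length")
        if len(self.scores) and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.boxes)


class Detector(Protocol):
    """Plug-in contract: map an 8-bit image to detections in pixel coordinates."""

    def __call__(self, frame: np.ndarray) -> DetectionOutput: ...


_DETECTOR_REGISTRY: dict[str, Callable[..., Detector]] = {}


def register_detector(name: str) -> Callable:
    """Decorator registering a detector factory under ``name`` for configs."""

    def deco(factory: Callable[..., Detector]) -> Callable[..., Detector]:
        _DETECTOR_REGISTRY[name] = factory
        return factory

    return deco


def get_detector(name: str, **kwargs) -> Detector:
    try:
        factory = _DETECTOR_REGISTRY[name]
    except KeyError:
        raise KeyError(f"no detector registered under {name!r}") from None
    return factory(**kwargs)


def default_box_scales(s_min: float, s_max: float, f: int) -> np.ndarray:
    """Linearly spaced per-layer scales ``s_1..s_f`` between s_min and s_max.

    ``s_i = s_min + (s_max - s_min) (i-1)/(f-1)``; endpoints are exact.
    """
    if not (0 < s_min < s_max <= 1):
        raise ValueError("require 0 < s_min < s_max <= 1")
    if f < 2:
        raise ValueError("need at least two feature maps")
    return np.linspace(s_min, s_max, f)


def standard_feature_maps() -> list[FeatureMapSpec]:
    """The canonical six-layer arrangement (map sizes 38,19,10,5,3,1)."""
    full = (1.0, 2.0, 3.0, 0.5, 1.0 / 3.0)
    small = (1.0, 2.0, 0.5)
    sizes_k = [(38, 4, small), (19, 6, full), (10, 6, full), (5, 6, full), (3, 4, small), (1, 4, small)]
    return [FeatureMapSpec(s, s, k, ars) for s, k, ars in sizes_k]


def generate_default_boxes(
    specs: Sequence[FeatureMapSpec],
    scales: Sequence[float],
    clip: bool = False,
) -> DefaultBoxGrid:
    """Tile every feature-map cell with its default boxes.

    A box of scale ``s`` and aspect ratio ``ar`` has width ``s*sqrt(ar)`` and
    height ``s/sqrt(ar)``, centred at ``((col+0.5)/n, (row+0.5)/m)``.  When a
    layer carries one more box than aspect ratios, the extra box has unit
    aspect and scale ``sqrt(s_i * s_{i+1})`` (``s_{f+1} = 1``).
    """
    if len(specs) != len(scales):
        raise ValueError("specs and scales must have equal length")
    boxes: list[Box] = []
    layers: list[int] = []
    ext_scales = list(scales) + [1.0]
    for li, (spec, s) in enumerate(zip(specs, scales)):
        shapes = [(s * math.sqrt(ar), s / math.sqrt(ar)) for ar in spec.aspect_ratios]
        if spec.boxes_per_cell == len(spec.aspect_ratios) + 1:
            s_extra = math.sqrt(s * ext_scales[li + 1])
            shapes.append((s_extra, s_extra))
        m, n = spec.grid_rows, spec.grid_cols
        for row in range(m):
            cy = (row + 0.5) / m
            for col in range(n):
                cx = (col + 0.5) / n
                for bw, bh in shapes:
                    if clip:
                        x1 = max(0.0, cx - bw / 2)
                        y1 = max(0.0, cy - bh / 2)
                        x2 = min(1.0, cx + bw / 2)
                        y2 = min(1.0, cy + bh / 2)
                        boxes.append(Box(x1, y1, x2 - x1, y2 - y1))
                    else:
                        boxes.append(Box.from_center(cx, cy, bw, bh))
                    layers.append(li)
    return DefaultBoxGrid(boxes, np.asarray(layers), clip=clip)


def encode_box(gt: Box, default: Box) -> np.ndarray:
    """Regression target ``t`` of a ground-truth box relative to a default box:
    centre offsets normalized by the default box size plus log size ratios."""
    gcx, gcy = gt.center
    dcx, dcy = default.center
    return np.array(
        [
            (gcx - dcx) / default.w,
            (gcy - dcy) / default.h,
            math.log(gt.w / default.w),
            math.log(gt.h / default.h),
        ]
    )


def _jaccard_matrix(gt: Sequence[Box], boxes: Sequence[Box]) -> np.ndarray:
    def arr(bs: Sequence[Box]) -> np.ndarray:
        return np.array([[b.x, b.y, b.x2, b.y2, b.area] for b in bs])

    G, D = arr(gt), arr(boxes)
    iw = np.clip(np.minimum(G[:, None, 2], D[None, :, 2]) - np.maximum(G[:, None, 0], D[None, :, 0]), 0, None)
    ih = np.clip(np.minimum(G[:, None, 3], D[None, :, 3]) - np.maximum(G[:, None, 1], D[None, :, 1]), 0, None)
    inter = iw * ih
    return inter / (G[:, None, 4] + D[None, :, 4] - inter)


def match_default_boxes(
    gt: Sequence[Box], grid: DefaultBoxGrid, threshold: float = 0.5
) -> MatchLabels:
    """Two-stage many-to-one matching of default boxes to ground truth.

    Stage 1 gives each ground-truth box its best-overlap default box, so every
    GT has at least one positive even below threshold.  Stage 2 additionally
    marks every default box whose Jaccard overlap with some GT exceeds
    ``threshold`` as positive for that GT (ties resolved by higher overlap,
    then lower GT index).  Each default box matches at most one GT.
    """
    if len(grid) == 0:
        raise ValueError("empty default-box grid")
    n_box = len(grid)
    gt_of_box = np.full(n_box, -1, dtype=int)
    if len(gt) == 0:
        return MatchLabels(gt_of_box, np.zeros((n_box, 4)), grid)
    J = _jaccard_matrix(gt, grid.boxes)

    # Stage 1: arg-max default box per GT; a box already claimed by an earlier
    # GT is skipped so every GT keeps at least one positive of its own.
    claimed = np.zeros(n_box, dtype=bool)
    for g in range(len(gt)):
        order = np.argsort(-J[g], kind="stable")
        for b in order:
            if not claimed[b]:
                gt_of_box[b] = g
                claimed[b] = True
                break

    # Stage 2: threshold matching for the remaining boxes (higher overlap wins,
    # then lower GT index via stable argmax).
    best_gt = np.argmax(J, axis=0)
    best_ov = J[best_gt, np.arange(n_box)]
    extra = (~claimed) & (best_ov > threshold)
    gt_of_box[extra] = best_gt[extra]

    targets = np.zeros((n_box, 4))
    for b in np.flatnonzero(gt_of_box >= 0):
        targets[b] = encode_box(gt[gt_of_box[b]], grid.boxes[b])
    return MatchLabels(gt_of_box, targets, grid)


def hard_negative_mine(scores: np.ndarray, n_positive: int, ratio: float = 3.0) -> np.ndarray:
    """Select the highest-loss negatives, at most ``ratio * n_positive`` of them.

    ``scores`` are per-negative confidence losses.  Returns indices sorted by
    loss descending; ties broken by lower index.  Zero positives select none.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite confidence losses")
    if n_positive <= 0:
        return np.empty(0, dtype=int)
    k = min(int(ratio * n_positive), len(scores))
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[:k]


def smooth_l1(x: float | np.ndarray) -> float | np.ndarray:
    """Robust smooth-L1 loss: ``0.5 x^2`` for |x|<1, else ``|x| - 0.5``."""
    ax = np.abs(x)
    out = np.where(ax < 1, 0.5 * np.square(x), ax - 0.5)
    return float(out) if np.isscalar(x) else out


class NoMatchedBoxes(ValueError):
    """Raised when an image has no positive default boxes (skip the image)."""


def detection_loss(
    output: DetectionOutput,
    labels: MatchLabels,
    beta: float = 1.0,
    neg_pos_ratio: float = 3.0,
    eps: float = 1e-12,
) -> tuple[float, float, float]:
    """Two-class multi-task loss over mined default boxes.

    ``output`` must be aligned with the default-box grid of ``labels`` (one
    predicted box and object probability per default box).  The confidence
    term is binary log loss over the positives plus the hard-mined negatives;
    the localization term is smooth-L1 between the predicted offsets (encoded
    against each positive's default box) and the matched GT offsets, weighted
    by ``beta``.  Both are normalized by the number N of matched boxes.

    Returns ``(total, class_term, reg_term)``.
    """
    if len(output) != len(labels.grid):
        raise ValueError("output must be aligned with the default-box grid")
    pos = labels.positive_indices
    n = len(pos)
    if n == 0:
        raise NoMatchedBoxes("no matched default boxes in this image")
    neg = labels.negative_indices
    p = np.clip(output.scores, eps, 1 - eps)
    neg_losses = -np.log(1 - p[neg])
    mined_local = hard_negative_mine(neg_losses, n, neg_pos_ratio)
    mined = neg[mined_local]
    class_term = float(np.sum(-np.log(p[pos])) + np.sum(-np.log(1 - p[mined])))
    reg_term = 0.0
    for b in pos:
        t = encode_box(output.boxes[b], labels.grid.boxes[b])
        reg_term += float(np.sum(smooth_l1(t - labels.regression_target[b])))
    total = (class_term + beta * reg_term) / n
    return total, class_term / n, beta * reg_term / n
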