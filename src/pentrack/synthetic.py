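"""Synthetic pen-world generator for end-to-end testing without footage.

The generator emulates the statistical structure the tracking method assumes:
a fixed overhead camera over a closed pen, a constant number of
similar-looking textured agents that never leave the scene, agent-agent
occlusions, a transient dark foreground occluder (an "insect" crossing or
sitting on the lens), and illumination fluctuation.  Agents are speckled
ellipses whose texture moves rigidly with them, so gradient features are
informative; slow axis-ratio oscillation emulates body deformation.
Everything is reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .detection import DetectionOutput
from .geometry import Box, Point, jaccard, union_box
from .metrics import TrajectorySet

__all__ = [
    "OccluderSpec",
    "SceneSpec",
    "AgentState",
    "simulate_agents",
    "simulate_trajectories",
    "render_frame",
    "Scene",
    "corrupt_detections",
]


@dataclass(frozen=True)
class OccluderSpec:
    """A dark blob crossing (or holding on) the lens between two frames."""

    start: int
    end: int
    path: tuple[tuple[float, float], ...]  # waypoints; a single point = long stay
    radius: float = 40.0

    def position(self, t: int) -> tuple[float, float]:
        if len(self.path) == 1 or self.end <= self.start:
            return self.path[0]
        u = np.clip((t - self.start) / (self.end - self.start), 0.0, 1.0)
        seg = u * (len(self.path) - 1)
        k = min(int(seg), len(self.path) - 2)
        frac = seg - k
        (x0, y0), (x1, y1) = self.path[k], self.path[k + 1]
        return (x0 + frac * (x1 - x0), y0 + frac * (y1 - y0))


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic pen world."""

    pen_size: tuple[int, int] = (480, 360)  # (W, H) pixels
    n_agents: int = 9
    n_frames: int = 100
    speed_range: tuple[float, float] = (0.5, 2.0)  # px / frame
    turn_sigma: float = 0.08  # rad / frame heading diffusion (~1.6 rad/s at 20 fps)
    axes: tuple[float, float] = (22.0, 13.0)  # ellipse semi-axes (a, b)
    deform_amp: float = 0.08  # relative axis-ratio oscillation amplitude
    deform_period: float = 40.0  # frames
    occluders: tuple[OccluderSpec, ...] = ()
    illumination: tuple[tuple[float, float], ...] | None = None  # per-frame (gain, offset)
    mode: str = "day"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("need at least one agent")
        W, H = self.pen_size
        if self.n_agents * (3.0 * self.axes[0]) ** 2 > W * H:
            raise ValueError("pen too small for this many agents")
        for oc in self.occluders:
            if not (0 <= oc.start <= oc.end < self.n_frames):
                raise ValueError("occluder schedule outside the frame range")
        if self.illumination is not None and len(self.illumination) != self.n_frames:
            raise ValueError("illumination schedule must cover every frame")


@dataclass
class AgentState:
    """Pose of one agent: an oriented ellipse with a texture phase."""

    centre: Point
    heading: float
    axes: tuple[float, float]
    texture_phase: float = 0.0

    @property
    def bounding_box(self) -> Box:
        a, b = self.axes
        c, s = math.cos(self.heading), math.sin(self.heading)
        hx = math.hypot(a * c, b * s)
        hy = math.hypot(a * s, b * c)
        return Box(self.centre.cx - hx, self.centre.cy - hy, 2 * hx, 2 * hy)


def simulate_agents(spec: SceneSpec) -> list[list[AgentState]]:
    """Smooth bounded random walks with soft collision avoidance.

    Returns, per frame, the list of agent states.  Walls are reflective (an
    agent's ellipse always stays inside the pen) and agents within contact
    range push each other apart, so boxes overlap only transiently.
    """
    rng = np.random.default_rng(spec.seed)
    W, H = spec.pen_size
    a0, b0 = spec.axes
    margin = a0 + 2.0
    n = spec.n_agents
    # initial placement on a jittered grid to avoid overlaps
    cols = int(math.ceil(math.sqrt(n * W / H)))
    rows = int(math.ceil(n / cols))
    pos = []
    for i in range(n):
        r, c = divmod(i, cols)
        x = (c + 0.5) / cols * (W - 2 * margin) + margin
        y = (r + 0.5) / rows * (H - 2 * margin) + margin
        pos.append([x + rng.uniform(-4, 4), y + rng.uniform(-4, 4)])
    pos = np.array(pos)
    heading = rng.uniform(0, 2 * np.pi, size=n)
    speed = rng.uniform(*spec.speed_range, size=n)
    phase = rng.uniform(0, 2 * np.pi, size=n)

    frames: list[list[AgentState]] = []
    for t in range(spec.n_frames):
        heading = heading + rng.normal(0, spec.turn_sigma, size=n)
        speed = np.clip(speed + rng.normal(0, 0.1, size=n), *spec.speed_range)
        pos = pos + np.stack([speed * np.cos(heading), speed * np.sin(heading)], axis=1)
        # soft collision avoidance: push contacting pairs apart
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                dist = float(np.hypot(*d))
                contact = 1.6 * b0 + 0.4 * a0
                if dist < contact and dist > 1e-9:
                    push = 0.5 * (contact - dist) * d / dist
                    pos[i] += push
                    pos[j] -= push
        # reflective walls
        for i in range(n):
            for k, lim in ((0, W), (1, H)):
                if pos[i, k] < margin:
                    pos[i, k] = 2 * margin - pos[i, k]
                    heading[i] = math.pi - heading[i] if k == 0 else -heading[i]
                elif pos[i, k] > lim - margin:
                    pos[i, k] = 2 * (lim - margin) - pos[i, k]
                    heading[i] = math.pi - heading[i] if k == 0 else -heading[i]
            pos[i] = np.clip(pos[i], margin, [W - margin, H - margin])
        states = []
        for i in range(n):
            wob = 1.0 + spec.deform_amp * math.sin(2 * np.pi * t / spec.deform_period + phase[i])
            states.append(
                AgentState(
                    Point(float(pos[i, 0]), float(pos[i, 1])),
                    float(heading[i]),
                    (a0 * wob, b0 / wob),
                    texture_phase=float(phase[i]),
                )
            )
        frames.append(states)
    return frames


def simulate_trajectories(spec: SceneSpec) -> TrajectorySet:
    """Ground-truth bounding-box trajectories: every id present in every frame."""
    traj = TrajectorySet()
    for t, states in enumerate(simulate_agents(spec)):
        for i, st in enumerate(states):
            traj.add(t, i + 1, st.bounding_box)
    return traj


def _textures(spec: SceneSpec, tile: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic background texture and per-agent speckle tiles."""
    rng = np.random.default_rng(spec.seed + 1_000_003)
    W, H = spec.pen_size
    bg = gaussian_filter(rng.standard_normal((H, W)), 6.0)
    bg = bg / max(np.abs(bg).max(), 1e-9)
    tiles = []
    for _ in range(spec.n_agents):
        tl = gaussian_filter(rng.standard_normal((tile, tile)), 1.5)
        tiles.append(tl / max(np.abs(tl).max(), 1e-9))
    return bg, np.stack(tiles)


def render_frame(agents: list[AgentState], spec: SceneSpec, t: int) -> np.ndarray:
    """Rasterize one frame: floor, textured agents, occluders, illumination.

    Day mode returns ``(H, W, 3)`` uint8, night mode single-channel uint8.
    Agent texture is sampled in agent-local coordinates so it translates and
    rotates rigidly with the body.
    """
    W, H = spec.pen_size
    bg, tiles = _textures(spec)
    img = 0.30 + 0.05 * bg  # floor
    if spec.mode == "day":
        img = np.stack([img * 1.05, img * 0.95, img * 0.9], axis=2)
    base_colour = np.array([0.78, 0.58, 0.50])  # pinkish body tone
    tile_n = tiles.shape[1]
    for i, ag in enumerate(agents):
        a, b = ag.axes
        cx, cy = ag.centre
        x0, x1 = max(0, int(cx - a - 2)), min(W, int(cx + a + 3))
        y0, y1 = max(0, int(cy - a - 2)), min(H, int(cy + a + 3))
        if x0 >= x1 or y0 >= y1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx, dy = xs + 0.5 - cx, ys + 0.5 - cy
        c, s = math.cos(ag.heading), math.sin(ag.heading)
        u = (dx * c + dy * s) / a
        v = (-dx * s + dy * c) / b
        mask = u**2 + v**2 <= 1.0
        if not mask.any():
            continue
        tu = (u[mask] * 0.5 + 0.5) * (tile_n - 1)
        tv = (v[mask] * 0.5 + 0.5) * (tile_n - 1)
        tex = map_coordinates(tiles[i % len(tiles)], [tv, tu], order=1, mode="reflect")
        shade = np.clip(1.0 + 0.45 * tex, 0.3, 1.7)
        if spec.mode == "day":
            patch = img[y0:y1, x0:x1]
            patch[mask] = base_colour[None, :] * shade[:, None]
        else:
            img[y0:y1, x0:x1][mask] = 0.55 * shade
    for oc in spec.occluders:
        if oc.start <= t <= oc.end:
            ox, oy = oc.position(t)
            ys, xs = np.mgrid[0:H, 0:W]
            dist = np.hypot(xs + 0.5 - ox, ys + 0.5 - oy)
            alpha = np.clip((oc.radius - dist) / 3.0, 0.0, 1.0)
            if spec.mode == "day":
                img = img * (1 - alpha[:, :, None]) + 0.06 * alpha[:, :, None]
            else:
                img = img * (1 - alpha) + 0.06 * alpha
    if spec.illumination is not None:
        gain, offset = spec.illumination[t]
        img = img * gain + offset
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


@dataclass
class Scene:
    """A fully generated scene: agent states, ground truth, and frames on demand."""

    spec: SceneSpec
    agents: list[list[AgentState]]
    gt: TrajectorySet

    @classmethod
    def generate(cls, spec: SceneSpec) -> "Scene":
        agents = simulate_agents(spec)
        traj = TrajectorySet()
        for t, states in enumerate(agents):
            for i, st in enumerate(states):
                traj.add(t, i + 1, st.bounding_box)
        return cls(spec, agents, traj)

    def frame(self, t: int) -> np.ndarray:
        return render_frame(self.agents[t], self.spec, t)


def corrupt_detections(
    gt: TrajectorySet,
    p_fn: float = 0.0,
    p_fp: float = 0.0,
    jitter_sigma: float = 0.0,
    merge_iou: float = 2.0,
    seed: int = 0,
    pen_size: tuple[int, int] | None = None,
    fp_size_range: tuple[float, float] = (20.0, 60.0),
) -> dict[int, DetectionOutput]:
    """Turn ground truth into an imperfect detection stream.

    Per frame: ground-truth pairs with IoU at or above ``merge_iou`` are
    replaced by their union box (the classic overlapping-animals failure),
    each remaining box is dropped independently with probability ``p_fn`` and
    jittered with Gaussian noise on ``(x, y, w, h)``, and spurious boxes
    arrive at a Poisson rate of ``p_fp`` per frame.  Deterministic given the
    seed.
    """
    for p in (p_fn, p_fp if p_fp <= 1 else 1.0):
        if not 0.0 <= p:
            raise ValueError("probabilities must be non-negative")
    rng = np.random.default_rng(seed)
    if pen_size is None:
        xs = [b.x2 for fr in gt.frames.values() for b in fr.values()]
        ys = [b.y2 for fr in gt.frames.values() for b in fr.values()]
        pen_size = (int(max(xs, default=100)), int(max(ys, default=100)))
    out: dict[int, DetectionOutput] = {}
    for t in sorted(gt.frames):
        boxes = [gt.frames[t][i] for i in sorted(gt.frames[t])]
        merged: list[Box] = []
        used = set()
        for i in range(len(boxes)):
            if i in used:
                continue
            cur = boxes[i]
            for j in range(i + 1, len(boxes)):
                if j in used:
                    continue
                if jaccard(cur, boxes[j]) >= merge_iou:
                    cur = union_box(cur, boxes[j])
                    used.add(j)
            merged.append(cur)
        kept: list[Box] = []
        for b in merged:
            if rng.uniform() < p_fn:
                continue
            if jitter_sigma > 0:
                jx, jy, jw, jh = rng.normal(0, jitter_sigma, size=4)
                b = Box(b.x + jx, b.y + jy, max(b.w + jw, 4.0), max(b.h + jh, 4.0))
            kept.append(b)
        scores = list(rng.uniform(0.85, 1.0, size=len(kept)))
        for _ in range(rng.poisson(p_fp)):
            fw = rng.uniform(*fp_size_range)
            fh = rng.uniform(*fp_size_range)
            fx = rng.uniform(0, max(pen_size[0] - fw, 1))
            fy = rng.uniform(0, max(pen_size[1] - fh, 1))
            kept.append(Box(fx, fy, fw, fh))
            scores.append(rng.uniform(0.5, 0.85))
        out[t] = DetectionOutput(kept, np.array(scores))
    return out
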