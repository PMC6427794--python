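"""Shared fixtures: a deterministic translating-target sequence and a small pen scene."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pentrack.geometry import Box


class TranslatingTarget:
    """A speckle-textured rectangle moving rigidly over a textured floor."""

    def __init__(self, velocity=(2.0, 0.0), size=(48, 60), start=(30, 60),
                 frame_size=(240, 180), seed=0, colour=True):
        rng = np.random.default_rng(seed)
        W, H = frame_size
        self.velocity = velocity
        self.size = size  # (w, h)
        self.start = start
        bg = 0.3 + 0.03 * gaussian_filter(rng.standard_normal((H, W)), 5)
        self.bg = np.stack([bg * 1.05, bg * 0.95, bg * 0.9], axis=2)
        tex = gaussian_filter(rng.standard_normal((size[1], size[0])), 1.5)
        tex = 1 + 0.45 * tex / np.abs(tex).max()
        tone = (0.78, 0.58, 0.50) if colour else (0.6, 0.6, 0.6)
        self.tex = np.stack([c * tex for c in tone], axis=2)

    def box(self, t: int) -> Box:
        x = self.start[0] + self.velocity[0] * t
        y = self.start[1] + self.velocity[1] * t
        return Box(x, y, self.size[0], self.size[1])

    def frame(self, t: int) -> np.ndarray:
        img = self.bg.copy()
        b = self.box(t)
        x, y = int(round(b.x)), int(round(b.y))
        img[y:y + self.size[1], x:x + self.size[0]] = self.tex
        return (np.clip(img, 0, 1) * 255).astype(np.uint8)


@pytest.fixture
def translating_target():
    return TranslatingTarget()


@pytest.fixture
def static_target():
    return TranslatingTarget(velocity=(0.0, 0.0))


@pytest.fixture(scope="session")
def small_scene():
    from pentrack.synthetic import Scene, SceneSpec

    spec = SceneSpec(pen_size=(360, 280), n_agents=4, n_frames=25, seed=11)
    return Scene.generate(spec)
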