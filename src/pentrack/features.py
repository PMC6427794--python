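"""Appearance features for the correlation-filter tracker.

Two cell-based descriptors are used: a 9-orientation histogram-of-oriented-
gradients descriptor at a 6-pixel cell (day and night) and an 11-channel
colour-name descriptor at a 4-pixel cell (day only; infrared footage is
grayscale, so colour is skipped at night or whenever the input has no colour
channel).  Each descriptor keeps its native cell resolution; the tracker
fuses them onto a common grid later.

Both descriptors are built to vary *smoothly* under sub-pixel image shifts —
gradient magnitudes are soft-assigned across neighbouring orientation bins
and spatial pooling is Gaussian rather than hard cell binning — because the
correlation response is interpolated between grid nodes and a shift-variant
descriptor would bias the sub-pixel peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["FeatureBlock", "FeatureStack", "extract_features", "COLOR_NAME_PROTOTYPES"]

log = logging.getLogger(__name__)

# Representative sRGB values (in [0,1]) of the 11 basic colour terms.  Pixels
# are softly assigned to these prototypes and pooled over cells; this is a
# prototype-based stand-in for a learned colour-name mapping, adequate for the
# synthetic scenes this package ships with.
COLOR_NAME_PROTOTYPES = np.array(
    [
        [0.0, 0.0, 0.0],  # black
        [0.0, 0.0, 1.0],  # blue
        [0.55, 0.27, 0.07],  # brown
        [0.5, 0.5, 0.5],  # grey
        [0.0, 0.5, 0.0],  # green
        [1.0, 0.65, 0.0],  # orange
        [1.0, 0.75, 0.80],  # pink
        [0.5, 0.0, 0.5],  # purple
        [1.0, 0.0, 0.0],  # red
        [1.0, 1.0, 1.0],  # white
        [1.0, 1.0, 0.0],  # yellow
    ]
)


@dataclass
class FeatureBlock:
    """One descriptor's channel grid at its native cell resolution."""

    data: np.ndarray  # (rows, cols, channels)
    cell_size: int


@dataclass
class FeatureStack:
    """All descriptor blocks extracted from one image patch."""

    blocks: list[FeatureBlock]
    patch_shape: tuple[int, int]  # (H, W) pixels of the source patch

    @property
    def n_channels(self) -> int:
        return sum(b.data.shape[2] for b in self.blocks)


def _to_float(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch)
    if patch.dtype == np.uint8:
        return patch.astype(float) / 255.0
    return patch.astype(float)


def _pool_cells(channels: np.ndarray, cell: int) -> np.ndarray:
    """Gaussian low-pass then sample at cell centres (anti-aliased pooling)."""
    sm = gaussian_filter(channels, (cell / 2.0, cell / 2.0, 0.0))
    return sm[cell // 2 :: cell, cell // 2 :: cell]


def _hog_channels(gray: np.ndarray, cell: int, n_bins: int = 9, eps: float = 5e-3) -> np.ndarray:
    """Soft-binned unsigned oriented-gradient histogram channels."""
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ang = np.mod(np.arctan2(gy, gx), np.pi)
    b = ang / np.pi * n_bins
    b0 = np.floor(b).astype(int) % n_bins
    frac = b - np.floor(b)
    ch = np.zeros(gray.shape + (n_bins,))
    np.put_along_axis(ch, b0[..., None], (mag * (1 - frac))[..., None], axis=2)
    hi = np.zeros_like(ch)
    np.put_along_axis(hi, ((b0 + 1) % n_bins)[..., None], (mag * frac)[..., None], axis=2)
    ch += hi
    pooled = _pool_cells(ch, cell)
    norm = np.sqrt(np.sum(pooled**2, axis=2, keepdims=True)) + eps
    return pooled / norm


def _colour_name_channels(rgb: np.ndarray, cell: int, tau: float = 0.35) -> np.ndarray:
    """Soft assignment of each pixel to the 11 colour prototypes, cell-pooled."""
    d2 = np.sum((rgb[:, :, None, :] - COLOR_NAME_PROTOTYPES[None, None, :, :]) ** 2, axis=-1)
    w = np.exp(-d2 / (2 * tau**2))
    w /= np.maximum(w.sum(axis=-1, keepdims=True), 1e-12)
    return _pool_cells(w, cell)


def extract_features(
    patch: np.ndarray,
    mode: str = "day",
    hog_cell: int = 6,
    cn_cell: int = 4,
) -> FeatureStack:
    """Extract the tracker's feature channels from an image patch.

    ``patch`` is ``(H, W)`` grayscale or ``(H, W, 3)`` colour, 8-bit or float
    in [0, 1], with ``H`` and ``W`` multiples of every cell size in use.
    Day mode on a grayscale input degrades to HOG only with a logged notice.
    """
    patch = _to_float(patch)
    is_colour = patch.ndim == 3 and patch.shape[2] == 3
    gray = patch.mean(axis=2) if is_colour else patch
    H, W = gray.shape
    use_cn = mode == "day" and is_colour
    if mode == "day" and not is_colour:
        log.info("day mode on a grayscale patch: colour-name channels skipped")
    cells = [hog_cell] + ([cn_cell] if use_cn else [])
    if min(H, W) < max(cells):
        raise ValueError(f"patch {H}x{W} smaller than one {max(cells)}-px cell")
    for c in cells:
        if H % c or W % c:
            raise ValueError(f"patch {H}x{W} not a multiple of cell size {c}")

    blocks = [FeatureBlock(_hog_channels(gray, hog_cell), hog_cell)]
    if use_cn:
        blocks.append(FeatureBlock(_colour_name_channels(patch, cn_cell), cn_cell))
    return FeatureStack(blocks, (H, W))
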