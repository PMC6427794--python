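"""Discriminative correlation-filter tracking of a per-animal *tag-box*.

Instead of tracking the full animal bounding box, a small tag-box covering a
portion of the body is tracked: local features are more discriminative among
similar-looking animals and far cheaper to correlate.  The machinery follows
the factored-convolution DCF family:

* multi-resolution feature channels are fused onto one common grid by Fourier
  (trigonometric) interpolation;
* channels are compressed ``D -> C`` by an energy-maximizing orthonormal
  projection learned from the first frame;
* the training set is a Gaussian-mixture sample model of at most ``L``
  components, updated with a fixed learning rate and closest-pair merging;
* filters minimize a spatially regularized least-squares objective

  .. math:: \\sum_l \\pi_l \\| \\sum_c f^c * \\mu_l^c - y^* \\|^2
            + \\sum_c \\| w \\cdot f^c \\|^2

  by conjugate gradients, with products evaluated per-frequency via the FFT;
* the response surface is band-limited, so its arg-max is refined to
  sub-pixel precision by Newton iterations on the trigonometric interpolant;
* filters and samples are refreshed only every ``update_interval`` frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .features import FeatureStack, extract_features
from .geometry import Box

__all__ = [
    "TrackerConfig",
    "ProjectionMatrix",
    "FilterBank",
    "SampleModel",
    "TrackerState",
    "UntrackableResponse",
    "fourier_resize",
    "fuse_stack",
    "gaussian_label",
    "learn_projection",
    "train_filters",
    "compute_response",
    "localize_subpixel",
    "update_sample_model",
    "init_tracker",
    "step",
]


class UntrackableResponse(RuntimeError):
    """Raised when a response surface carries no localisable peak."""


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable tracker hyper-parameters (the ``tracker`` config section)."""

    hog_cell: int = 6
    cn_cell: int = 4
    learning_rate: float = 0.09
    n_components: int = 30
    update_interval: int = 2
    tag_fraction: float = 0.4
    search_factor: float = 4.0
    scales: tuple[float, ...] = (0.98, 1.0, 1.02)
    scale_penalty: float = 0.985
    cg_first: int = 120
    cg_update: int = 5
    projection_dim: int = 8
    stride: int = 2          # common-grid resolution in patch pixels
    sigma_factor: float = 0.1  # label sigma relative to tag-box diagonal (cells)
    motion_radius: float = 6.0  # px; per-frame displacement with no penalty
    motion_sigma: float = 6.0   # px; prior fall-off beyond the radius
    reg_min: float = 0.15    # regularization weight at the target centre
    reg_slope: float = 3.0   # added weight at the tag-box border, growing outward
    mode: str = "day"


# ---------------------------------------------------------------------------
# Fourier-domain plumbing


def _upsample_axis(F: np.ndarray, axis: int, N: int) -> np.ndarray:
    """Zero-pad an FFT spectrum along ``axis`` to length ``N`` (trig interp).

    For even input lengths the Nyquist bin is split symmetrically so the
    upsampled signal stays real and even-symmetric.
    """
    F = np.moveaxis(F, axis, 0)
    n = F.shape[0]
    if N == n:
        return np.moveaxis(F, 0, axis)
    if N < n:
        raise ValueError("only upsampling is supported")
    out = np.zeros((N,) + F.shape[1:], dtype=complex)
    if n % 2 == 1:
        p = (n + 1) // 2
        out[:p] = F[:p]
        out[N - (n - p):] = F[p:]
    else:
        half = n // 2
        out[:half] = F[:half]
        if half > 1:
            out[N - (half - 1):] = F[half + 1:]
        out[half] += 0.5 * F[half]
        out[N - half] += 0.5 * F[half]
    return np.moveaxis(out, 0, axis)


def fourier_resize(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resample a (possibly multi-channel) grid to ``shape`` by trig interpolation."""
    h, w = a.shape[:2]
    H, W = shape
    if (H, W) == (h, w):
        return np.asarray(a, dtype=float)
    F = np.fft.fft2(a, axes=(0, 1))
    F = _upsample_axis(F, 0, H)
    F = _upsample_axis(F, 1, W)
    return np.fft.ifft2(F, axes=(0, 1)).real * (H * W) / (h * w)


def fuse_stack(stack: FeatureStack, grid_shape: tuple[int, int]) -> np.ndarray:
    """Fuse all descriptor blocks onto one ``grid_shape`` grid -> (H, W, D).

    The fused grid is rolled so the patch centre sits at index (0, 0),
    matching the label convention (Gaussian peak at the origin).
    """
    H, W = grid_shape
    parts = [fourier_resize(b.data, grid_shape) for b in stack.blocks]
    fused = np.concatenate(parts, axis=2)
    return np.roll(fused, (-(H // 2), -(W // 2)), axis=(0, 1))


def gaussian_label(grid_shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Circularly wrapped Gaussian with unit peak at the grid origin."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    m, n = grid_shape
    di = np.minimum(np.arange(m), m - np.arange(m)).astype(float)
    dj = np.minimum(np.arange(n), n - np.arange(n)).astype(float)
    return np.exp(-(di[:, None] ** 2 + dj[None, :] ** 2) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# Projection and sample model


@dataclass
class ProjectionMatrix:
    """Orthonormal ``D x C`` channel compression matrix."""

    P: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.P, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("projection columns must have unit norm")

    @property
    def D(self) -> int:
        return self.P.shape[0]

    @property
    def C(self) -> int:
        return self.P.shape[1]

    def apply(self, fused: np.ndarray) -> np.ndarray:
        return fused @ self.P


def learn_projection(first_sample: np.ndarray, C: int) -> ProjectionMatrix:
    """Energy-maximizing orthonormal ``D -> C`` projection from one sample.

    Columns are the top eigenvectors of the channel Gram matrix, so the
    retained energy for any ``C`` equals the sum of the top-``C`` eigenvalues.
    """
    D = first_sample.shape[2]
    if C > D:
        raise ValueError(f"cannot project {D} channels up to {C}")
    X = first_sample.reshape(-1, D)
    gram = X.T @ X
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    return ProjectionMatrix(evecs[:, order[:C]])


@dataclass
class SampleModel:
    """Gaussian-mixture training-sample model with at most ``capacity`` components."""

    capacity: int
    learning_rate: float
    label: np.ndarray
    weights: list[float] = field(default_factory=list)
    means: list[np.ndarray] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.means)


def update_sample_model(model: SampleModel, new_sample: np.ndarray) -> SampleModel:
    """Insert a sample at the learning-rate weight; merge the closest pair at capacity.

    The first sample enters with weight 1.  Later samples enter with weight
    equal to the learning rate while existing weights shrink by ``1 - rate``;
    when capacity is exceeded the two closest components (L2 distance between
    means) are merged into their weighted mean.  Weights are renormalized to
    sum to 1 after every update.
    """
    if model.means and new_sample.shape != model.means[0].shape:
        raise ValueError("sample shape inconsistent with model")
    if not model.means:
        model.weights = [1.0]
        model.means = [new_sample.astype(float)]
        return model
    lr = model.learning_rate
    model.weights = [w * (1.0 - lr) for w in model.weights] + [lr]
    model.means.append(new_sample.astype(float))
    if len(model.means) > model.capacity:
        flat = np.stack([m.ravel() for m in model.means])
        sq = np.sum(flat**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (flat @ flat.T)
        np.fill_diagonal(d2, np.inf)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        i, j = (i, j) if i < j else (j, i)
        wi, wj = model.weights[i], model.weights[j]
        merged = (wi * model.means[i] + wj * model.means[j]) / (wi + wj)
        model.means[i] = merged
        model.weights[i] = wi + wj
        del model.means[j], model.weights[j]
    total = sum(model.weights)
    model.weights = [w / total for w in model.weights]
    return model


# ---------------------------------------------------------------------------
# Filter training (conjugate gradients on the Fourier-domain normal equations)


@dataclass
class FilterBank:
    """Spatial-domain filters (one per projected channel) plus regularization."""

    filters: np.ndarray  # (H, W, C)
    reg_weights: np.ndarray  # (H, W)


def _objective(Zhat: np.ndarray, pis: np.ndarray, f: np.ndarray,
               y: np.ndarray, w: np.ndarray) -> float:
    H, W = y.shape
    Fh = np.fft.fft2(f, axes=(0, 1))
    Rh = np.einsum("lhwc,hwc->lhw", Zhat, Fh)
    resid = np.fft.ifft2(Rh, axes=(1, 2)).real - y[None]
    data = float(np.sum(pis * np.sum(resid**2, axis=(1, 2))))
    reg = float(np.sum((w[:, :, None] * f) ** 2))
    return data + reg


def train_filters(
    model: SampleModel,
    projection: ProjectionMatrix,
    reg_weights: np.ndarray,
    n_iter: int,
    init: FilterBank | None = None,
    tol: float = 1e-26,
) -> FilterBank:
    """Minimize the regularized mixture objective by conjugate gradients.

    The quadratic system is ``A f = b`` with
    ``A f = sum_l pi_l Z_l^H Z_l f + w^2 f`` (per-frequency products for the
    data term, spatial multiplication for the regularizer) and
    ``b = sum_l pi_l Z_l^H y``.  CG decreases the objective monotonically;
    the best iterate is returned.
    """
    if not model.means:
        raise ValueError("sample model is empty")
    y = model.label
    H, W = y.shape
    pis = np.asarray(model.weights)
    Z = np.stack([projection.apply(m) for m in model.means])  # (L,H,W,C)
    Zhat = np.fft.fft2(Z, axes=(1, 2))
    C = Zhat.shape[3]
    yhat = np.fft.fft2(y)
    w2 = reg_weights**2

    bhat = np.einsum("l,lhwc,hw->hwc", pis, np.conj(Zhat), yhat)
    b = np.fft.ifft2(bhat, axes=(0, 1)).real

    def matvec(f: np.ndarray) -> np.ndarray:
        Fh = np.fft.fft2(f, axes=(0, 1))
        Rh = np.einsum("lhwc,hwc->lhw", Zhat, Fh)
        Gh = np.einsum("l,lhw,lhwc->hwc", pis, Rh, np.conj(Zhat))
        return np.fft.ifft2(Gh, axes=(0, 1)).real + w2[:, :, None] * f

    f = np.zeros((H, W, C)) if init is None else init.filters.copy()
    r = b - matvec(f)
    p = r.copy()
    rs = float(np.sum(r * r))
    rs_stop = tol * max(float(np.sum(b * b)), 1e-300)  # relative residual target
    best_f, best_J = f.copy(), _objective(Zhat, pis, f, y, reg_weights)
    for _ in range(n_iter):
        if rs < rs_stop:
            break
        Ap = matvec(p)
        denom = float(np.sum(p * Ap))
        if denom <= 0:
            break
        alpha = rs / denom
        f = f + alpha * p
        r = r - alpha * Ap
        rs_new = float(np.sum(r * r))
        J = _objective(Zhat, pis, f, y, reg_weights)
        if J <= best_J:
            best_J, best_f = J, f.copy()
        p = r + (rs_new / rs) * p
        rs = rs_new
    return FilterBank(best_f, reg_weights)


def compute_response(
    bank: FilterBank, projection: ProjectionMatrix, fused: np.ndarray
) -> np.ndarray:
    """Correlation response ``R = sum_c f^c * z^c`` on the common grid.

    ``fused`` is the (H, W, D) fused feature grid (already rolled to the
    origin convention); the projection compresses it to C channels first.
    """
    z = projection.apply(fused)
    if z.shape != bank.filters.shape:
        raise ValueError("feature/filter shape mismatch")
    Zh = np.fft.fft2(z, axes=(0, 1))
    Fh = np.fft.fft2(bank.filters, axes=(0, 1))
    return np.fft.ifft2(np.sum(Zh * Fh, axis=2)).real


def localize_subpixel(
    response: np.ndarray, n_newton: int = 10
) -> tuple[float, float, float]:
    """Continuous arg-max of a periodic response surface.

    Starts from the grid arg-max (circular coordinates centred on the origin)
    and refines with Newton iterations on the trigonometric interpolant.
    Returns ``(dx, dy, peak)`` with offsets in grid cells.  A constant
    surface raises :class:`UntrackableResponse`.
    """
    H, W = response.shape
    span = float(response.max() - response.min())
    if span <= 1e-12 * max(1.0, abs(float(response.max()))):
        raise UntrackableResponse("flat response surface")
    Rh = np.fft.fft2(response)
    ky = 2 * np.pi * np.fft.fftfreq(H)
    kx = 2 * np.pi * np.fft.fftfreq(W)
    KY, KX = np.meshgrid(ky, kx, indexing="ij")

    def value_grad_hess(py: float, px: float):
        E = Rh * np.exp(1j * (KY * py + KX * px)) / (H * W)
        v = float(np.sum(E).real)
        gy = float(np.sum(1j * KY * E).real)
        gx = float(np.sum(1j * KX * E).real)
        hyy = float(np.sum(-(KY**2) * E).real)
        hxx = float(np.sum(-(KX**2) * E).real)
        hxy = float(np.sum(-(KY * KX) * E).real)
        return v, np.array([gy, gx]), np.array([[hyy, hxy], [hxy, hxx]])

    i0, j0 = np.unravel_index(int(np.argmax(response)), response.shape)
    py = float(i0 if i0 <= H / 2 else i0 - H)
    px = float(j0 if j0 <= W / 2 else j0 - W)
    best_v = float(response[i0, j0])
    best = (py, px)
    for _ in range(n_newton):
        v, g, Hm = value_grad_hess(py, px)
        det = Hm[0, 0] * Hm[1, 1] - Hm[0, 1] ** 2
        if det <= 0 or Hm[0, 0] >= 0:  # not a local max: stop refining
            break
        step_ = np.linalg.solve(Hm, -g)
        step_ = np.clip(step_, -0.5, 0.5)
        py, px = py + step_[0], px + step_[1]
        v_new, _, _ = value_grad_hess(py, px)
        if v_new > best_v:
            best_v, best = v_new, (py, px)
        if np.max(np.abs(step_)) < 1e-6:
            break
    return best[1], best[0], best_v


# ---------------------------------------------------------------------------
# Tracker state and per-frame stepping


@dataclass
class TrackerState:
    """One animal's tag-box tracker: geometry, models and update bookkeeping."""

    center: tuple[float, float]
    tag_size: tuple[float, float]  # (w, h) current, scales with `scale`
    init_tag_size: tuple[float, float]
    scale: float
    patch_shape: tuple[int, int]  # canonical (H, W) pixels
    base_extent: tuple[float, float]  # (h, w) pixels at scale 1
    grid_shape: tuple[int, int]
    projection: ProjectionMatrix
    filter_bank: FilterBank
    sample_model: SampleModel
    config: TrackerConfig
    frames_since_update: int = 0
    flagged: bool = False

    @property
    def tag_box(self) -> Box:
        return Box.from_center(self.center[0], self.center[1], *self.tag_size)

    @property
    def search_area(self) -> Box:
        eh, ew = self.base_extent
        return Box.from_center(self.center[0], self.center[1], ew * self.scale, eh * self.scale)


def _crop_patch(
    frame: np.ndarray,
    center: tuple[float, float],
    extent: tuple[float, float],
    out_shape: tuple[int, int],
) -> np.ndarray:
    """Sub-pixel crop of ``extent`` (h, w) pixels around ``center`` resampled
    to ``out_shape`` by bilinear interpolation with edge replication."""
    cx, cy = center
    eh, ew = extent
    H, W = out_shape
    ys = cy + ((np.arange(H) + 0.5) / H - 0.5) * eh
    xs = cx + ((np.arange(W) + 0.5) / W - 0.5) * ew
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    if frame.ndim == 2:
        return map_coordinates(frame.astype(float), [Y, X], order=1, mode="nearest")
    chans = [
        map_coordinates(frame[:, :, c].astype(float), [Y, X], order=1, mode="nearest")
        for c in range(frame.shape[2])
    ]
    return np.stack(chans, axis=2)


def _round_to_multiple(v: float, m: int, minimum: int) -> int:
    return max(minimum, int(round(v / m)) * m)


def _extract_fused(
    frame: np.ndarray,
    center: tuple[float, float],
    extent: tuple[float, float],
    state_shape: tuple[int, int],
    grid_shape: tuple[int, int],
    cfg: TrackerConfig,
) -> np.ndarray:
    patch = _crop_patch(frame, center, extent, state_shape)
    stack = extract_features(patch, mode=cfg.mode, hog_cell=cfg.hog_cell, cn_cell=cfg.cn_cell)
    return fuse_stack(stack, grid_shape)


def _make_reg_bowl(grid_shape: tuple[int, int], tag_cells: tuple[float, float],
                   cfg: TrackerConfig) -> np.ndarray:
    """Quadratic regularization bowl: small over the target, large at borders.

    Distances are circular (origin convention), normalized by the tag-box
    half-size in cells, so the weight reaches ``reg_min + reg_slope`` at the
    tag-box border and keeps growing outside it.
    """
    m, n = grid_shape
    th, tw = max(tag_cells[0] / 2.0, 1.0), max(tag_cells[1] / 2.0, 1.0)
    di = np.minimum(np.arange(m), m - np.arange(m)).astype(float)
    dj = np.minimum(np.arange(n), n - np.arange(n)).astype(float)
    d2 = (di[:, None] / th) ** 2 + (dj[None, :] / tw) ** 2
    return cfg.reg_min + cfg.reg_slope * d2


def init_tracker(
    frame: np.ndarray,
    bounding_box: Box,
    config: TrackerConfig | None = None,
    fraction: float | None = None,
) -> TrackerState:
    """Initialize a tag-box tracker from a full-animal bounding box.

    The tag-box is the centred sub-box with dimensions ``fraction * (w, h)``;
    the search area pads it by the search factor.  The channel projection is
    learned from the first-frame sample, the filters are trained with the
    first-frame CG budget, and the sample model is seeded with one component.
    """
    cfg = config or TrackerConfig()
    frac = cfg.tag_fraction if fraction is None else fraction
    fh, fw = frame.shape[:2]
    b = bounding_box
    if b.x < 0 or b.y < 0 or b.x2 > fw or b.y2 > fh:
        raise ValueError("bounding box lies outside the frame")
    cx, cy = b.center
    tag_w, tag_h = b.w * frac, b.h * frac
    # square search area scaled by the tag-box area: elongated targets get the
    # same spatial context on both axes (a per-axis factor starves the narrow
    # dimension and lets boundary content dominate the response)
    ext = cfg.search_factor * math.sqrt(tag_w * tag_h)
    ext_h = ext_w = ext
    cell_lcm = math.lcm(cfg.hog_cell, cfg.cn_cell, cfg.stride)
    patch_shape = (
        _round_to_multiple(ext_h, cell_lcm, 2 * cell_lcm),
        _round_to_multiple(ext_w, cell_lcm, 2 * cell_lcm),
    )
    grid_shape = (patch_shape[0] // cfg.stride, patch_shape[1] // cfg.stride)
    base_extent = (float(patch_shape[0]), float(patch_shape[1]))

    fused = _extract_fused(frame, (cx, cy), base_extent, patch_shape, grid_shape, cfg)
    D = fused.shape[2]
    projection = learn_projection(fused, min(cfg.projection_dim, D))
    tag_cells = (tag_h / cfg.stride, tag_w / cfg.stride)
    sigma = max(1.0, cfg.sigma_factor * math.hypot(*tag_cells))
    label = gaussian_label(grid_shape, sigma)
    model = SampleModel(cfg.n_components, cfg.learning_rate, label)
    update_sample_model(model, fused)
    reg = _make_reg_bowl(grid_shape, tag_cells, cfg)
    bank = train_filters(model, projection, reg, cfg.cg_first)
    return TrackerState(
        center=(cx, cy),
        tag_size=(tag_w, tag_h),
        init_tag_size=(tag_w, tag_h),
        scale=1.0,
        patch_shape=patch_shape,
        base_extent=base_extent,
        grid_shape=grid_shape,
        projection=projection,
        filter_bank=bank,
        sample_model=model,
        config=cfg,
    )


def step(state: TrackerState, frame: np.ndarray, t: int | None = None) -> tuple[TrackerState, Box]:
    """Advance the tracker by one frame.

    The response is evaluated over the scale pyramid, the tag-box moves to the
    sub-pixel arg-max of the best scale (non-unit scales carry a small
    penalty), the search area is re-centred, and the sample model plus filters
    are refreshed only when ``frames_since_update`` reaches the interval.
    An untrackable (flat) response leaves the box in place and sets
    ``state.flagged`` for the association layer.
    """
    cfg = state.config
    fh, fw = frame.shape[:2]
    best = None
    for s in cfg.scales:
        eh = state.base_extent[0] * state.scale * s
        ew = state.base_extent[1] * state.scale * s
        fused = _extract_fused(frame, state.center, (eh, ew), state.patch_shape,
                               state.grid_shape, cfg)
        resp = compute_response(state.filter_bank, state.projection, fused)
        # flat-topped motion prior: inter-frame motion is limited in a
        # fixed-camera pen, so response peaks beyond a plausible displacement
        # radius are discounted; inside the radius the response is untouched
        # (a peaked prior would bias the sub-pixel estimate toward zero)
        m, n = state.grid_shape
        di = np.minimum(np.arange(m), m - np.arange(m)) * eh / m
        dj = np.minimum(np.arange(n), n - np.arange(n)) * ew / n
        dist = np.hypot(di[:, None], dj[None, :])  # px in the frame
        excess = np.maximum(dist - cfg.motion_radius, 0.0) / cfg.motion_sigma
        resp = resp * np.exp(-0.5 * excess**2)
        try:
            dx, dy, peak = localize_subpixel(resp)
        except UntrackableResponse:
            continue
        score = peak * (1.0 if s == 1.0 else cfg.scale_penalty)
        if best is None or score > best[0]:
            best = (score, s, dx, dy, eh, ew)
    if best is None:
        state.flagged = True
        return state, state.tag_box

    _, s, dx, dy, eh, ew = best
    state.flagged = False
    # offsets are in common-grid cells; one cell spans extent/grid pixels
    move_x = dx * ew / state.grid_shape[1]
    move_y = dy * eh / state.grid_shape[0]
    cx = float(np.clip(state.center[0] + move_x, 0.0, fw - 1.0))
    cy = float(np.clip(state.center[1] + move_y, 0.0, fh - 1.0))
    state.center = (cx, cy)
    state.scale = float(np.clip(state.scale * s, 0.5, 2.0))
    state.tag_size = (state.init_tag_size[0] * state.scale,
                      state.init_tag_size[1] * state.scale)

    state.frames_since_update += 1
    if state.frames_since_update >= cfg.update_interval:
        eh = state.base_extent[0] * state.scale
        ew = state.base_extent[1] * state.scale
        fused = _extract_fused(frame, state.center, (eh, ew), state.patch_shape,
                               state.grid_shape, cfg)
        update_sample_model(state.sample_model, fused)
        state.filter_bank = train_filters(
            state.sample_model, state.projection, state.filter_bank.reg_weights,
            cfg.cg_update, init=state.filter_bank,
        )
        state.frames_since_update = 0
    return state, state.tag_box
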