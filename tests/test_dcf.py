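import numpy as np
import pytest

from pentrack.dcf import (
    FilterBank,
    ProjectionMatrix,
    SampleModel,
    TrackerConfig,
    UntrackableResponse,
    compute_response,
    fourier_resize,
    gaussian_label,
    init_tracker,
    learn_projection,
    localize_subpixel,
    step,
    train_filters,
    update_sample_model,
)
from pentrack.geometry import Box


def _smooth(shape, seed, channels=1):
    """Band-limited random grid (smooth enough for trig interpolation)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(shape + ((channels,) if channels else ()))
    F = np.fft.fft2(a, axes=(0, 1))
    ky = np.abs(np.fft.fftfreq(shape[0]))
    kx = np.abs(np.fft.fftfreq(shape[1]))
    lp = (ky[:, None] < 0.3) & (kx[None, :] < 0.3)
    F *= lp[:, :, None] if a.ndim == 3 else lp
    return np.fft.ifft2(F, axes=(0, 1)).real


def _spatial_objective(means, weights, f, y, w):
    """Test-local recomputation of the training objective."""
    data = 0.0
    for pi, z in zip(weights, means):
        resp = np.zeros(y.shape)
        for c in range(f.shape[2]):
            resp += np.fft.ifft2(np.fft.fft2(z[:, :, c]) * np.fft.fft2(f[:, :, c])).real
        data += pi * np.sum((resp - y) ** 2)
    return data + np.sum((w[:, :, None] * f) ** 2)


class TestGaussianLabel:
    def test_peak_is_one_at_origin(self):
        y = gaussian_label((12, 16), 2.0)
        assert y[0, 0] == 1.0
        assert y.max() == 1.0

    def test_even_symmetry_under_wrap(self):
        y = gaussian_label((12, 16), 2.5)
        for i, j in [(1, 3), (5, 2), (11, 15)]:
            assert y[i, j] == pytest.approx(y[-i % 12, -j % 16])

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_label((8, 8), 0.0)


class TestFourierResize:
    def test_preserves_constant(self):
        a = np.full((6, 8), 3.0)
        assert np.allclose(fourier_resize(a, (12, 16)), 3.0)

    def test_exact_on_bandlimited(self):
        # a pure low-frequency cosine is reproduced exactly at the new nodes
        n = 8
        i = np.arange(n)
        a = np.cos(2 * np.pi * i[:, None] / n) + np.sin(2 * np.pi * 2 * i[None, :] / n)
        up = fourier_resize(a, (16, 16))
        assert np.allclose(up[::2, ::2], a, atol=1e-10)


class TestProjection:
    def test_full_projection_preserves_energy(self):
        x = _smooth((10, 10), 0, channels=4)
        p = learn_projection(x, 4)
        assert np.linalg.norm(x @ p.P) == pytest.approx(np.linalg.norm(x))

    def test_single_active_channel_indicator(self):
        x = np.zeros((6, 6, 3))
        x[:, :, 1] = _smooth((6, 6), 1)[:, :, 0]
        p = learn_projection(x, 1)
        assert np.abs(p.P[1, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_retained_energy_equals_top_eigenvalues(self):
        x = _smooth((12, 12), 2, channels=5)
        p = learn_projection(x, 2)
        retained = np.linalg.norm(x.reshape(-1, 5) @ p.P) ** 2
        gram = x.reshape(-1, 5).T @ x.reshape(-1, 5)
        evals = np.sort(np.linalg.eigvalsh(gram))[::-1]  # dense eigendecomposition oracle
        assert retained == pytest.approx(evals[:2].sum())

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            learn_projection(np.zeros((4, 4, 2)), 3)


def _one_component_model(z, y):
    m = SampleModel(capacity=5, learning_rate=0.1, label=y)
    update_sample_model(m, z)
    return m


class TestTrainFilters:
    def test_single_channel_matches_fourier_ridge(self):
        """CG solution equals conj(X)Y/(|X|^2 + lam) per frequency (closed form)."""
        shape = (16, 16)
        z = _smooth(shape, 0, channels=1)
        y = gaussian_label(shape, 2.0)
        lam = 0.05
        w = np.full(shape, np.sqrt(lam))
        model = _one_component_model(z, y)
        proj = ProjectionMatrix(np.eye(1))
        bank = train_filters(model, proj, w, n_iter=400)
        X = np.fft.fft2(z[:, :, 0])
        expected = np.conj(X) * np.fft.fft2(y) / (np.abs(X) ** 2 + lam)
        got = np.fft.fft2(bank.filters[:, :, 0])
        assert np.max(np.abs(got - expected)) < 1e-8

    def test_sample_equal_to_label_reproduces_label(self):
        # band-limit the label exactly so the unregularized system is solvable
        # on its range (the raw Gaussian's ~1e-8 tail frequencies would make
        # the lam=0 problem numerically singular)
        shape = (16, 16)
        Y = np.fft.fft2(gaussian_label(shape, 2.0))
        Y[np.abs(Y) < 1e-3] = 0.0
        y = np.fft.ifft2(Y).real
        model = _one_component_model(y[:, :, None], y)
        proj = ProjectionMatrix(np.eye(1))
        bank = train_filters(model, proj, np.zeros(shape), n_iter=400)
        resp = compute_response(bank, proj, y[:, :, None])
        assert np.allclose(resp, y, atol=1e-9)

    def test_multichannel_cg_matches_dense_solve(self):
        """CG equals an independently built dense normal-equations solve."""
        shape, C = (8, 8), 2
        y = gaussian_label(shape, 1.5)
        rng_seeds = [3, 4]
        means = [_smooth(shape, s, channels=C) for s in rng_seeds]
        weights = [0.7, 0.3]
        w = 0.3 + 0.5 * gaussian_label(shape, 3.0)
        model = SampleModel(capacity=5, learning_rate=0.3, label=y)
        for z in means:
            update_sample_model(model, z)
        weights = model.weights  # actual mixture weights after updates
        proj = ProjectionMatrix(np.eye(C))
        bank = train_filters(model, proj, w, n_iter=300)

        # dense oracle: explicit circulant convolution matrices
        n = shape[0] * shape[1]
        A = np.zeros((n * C, n * C))
        b = np.zeros(n * C)
        yv = y.ravel()
        for pi, z in zip(weights, model.means):
            M = np.zeros((n, n * C))
            for c in range(C):
                for q in range(n):
                    qi, qj = divmod(q, shape[1])
                    M[:, c * n + q] = np.roll(z[:, :, c], (qi, qj), axis=(0, 1)).ravel()
            A += pi * (M.T @ M)
            b += pi * (M.T @ yv)
        A += np.diag(np.tile((w**2).ravel(), C))
        fv = np.linalg.solve(A, b)
        dense = np.stack([fv[c * n:(c + 1) * n].reshape(shape) for c in range(C)], axis=2)
        assert np.max(np.abs(bank.filters - dense)) < 1e-6

    def test_objective_nonincreasing_in_iterations(self):
        shape = (12, 12)
        y = gaussian_label(shape, 2.0)
        z1, z2 = _smooth(shape, 5, 3), _smooth(shape, 6, 3)
        w = 0.2 + gaussian_label(shape, 4.0)
        model = SampleModel(capacity=5, learning_rate=0.2, label=y)
        update_sample_model(model, z1)
        update_sample_model(model, z2)
        proj = ProjectionMatrix(np.eye(3))
        objs = []
        for k in range(0, 9):
            bank = train_filters(model, proj, w, n_iter=k)
            objs.append(_spatial_objective(model.means, model.weights, bank.filters, y, w))
        assert all(a >= b - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_empty_model_rejected(self):
        m = SampleModel(capacity=3, learning_rate=0.1, label=np.ones((4, 4)))
        with pytest.raises(ValueError):
            train_filters(m, ProjectionMatrix(np.eye(1)), np.ones((4, 4)), 5)


class TestResponse:
    def test_zero_features_zero_response(self):
        bank = FilterBank(np.ones((8, 8, 2)), np.ones((8, 8)))
        resp = compute_response(bank, ProjectionMatrix(np.eye(2)), np.zeros((8, 8, 2)))
        assert np.allclose(resp, 0.0)

    def test_trained_sample_peaks_at_origin(self):
        shape = (16, 16)
        z = _smooth(shape, 7, channels=2)
        y = gaussian_label(shape, 2.0)
        model = _one_component_model(z, y)
        proj = ProjectionMatrix(np.eye(2))
        bank = train_filters(model, proj, np.full(shape, 0.1), n_iter=200)
        resp = compute_response(bank, proj, z)
        assert np.unravel_index(np.argmax(resp), shape) == (0, 0)

    def test_shift_equivariance(self):
        """Circularly shifting the features shifts the response identically."""
        shape = (16, 16)
        z = _smooth(shape, 8, channels=2)
        y = gaussian_label(shape, 2.0)
        model = _one_component_model(z, y)
        proj = ProjectionMatrix(np.eye(2))
        bank = train_filters(model, proj, np.full(shape, 0.2), n_iter=100)
        r0 = compute_response(bank, proj, z)
        shifted = np.roll(z, (3, 5), axis=(0, 1))
        r1 = compute_response(bank, proj, shifted)
        assert np.allclose(r1, np.roll(r0, (3, 5), axis=(0, 1)), atol=1e-10)

    def test_shape_mismatch_rejected(self):
        bank = FilterBank(np.ones((8, 8, 2)), np.ones((8, 8)))
        with pytest.raises(ValueError):
            compute_response(bank, ProjectionMatrix(np.eye(2)), np.zeros((6, 6, 2)))


class TestLocalize:
    def test_peak_on_node(self):
        resp = gaussian_label((16, 16), 2.0)
        dx, dy, peak = localize_subpixel(resp)
        assert (dx, dy) == pytest.approx((0.0, 0.0), abs=1e-6)
        assert peak == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("cy,cx", [(0.3, -0.2), (-1.4, 2.6), (3.25, -3.75)])
    def test_recovers_offgrid_gaussian_centre(self, cy, cx):
        n = 16
        iy = ((np.arange(n) - cy + n / 2) % n) - n / 2
        ix = ((np.arange(n) - cx + n / 2) % n) - n / 2
        resp = np.exp(-(iy[:, None] ** 2 + ix[None, :] ** 2) / (2 * 2.0**2))
        dx, dy, _ = localize_subpixel(resp)
        assert dx == pytest.approx(cx, abs=0.05)
        assert dy == pytest.approx(cy, abs=0.05)

    def test_flat_surface_untrackable(self):
        with pytest.raises(UntrackableResponse):
            localize_subpixel(np.full((8, 8), 0.7))


class TestSampleModel:
    def test_first_sample_weight_one(self):
        m = SampleModel(capacity=3, learning_rate=0.09, label=np.ones((4, 4)))
        update_sample_model(m, np.ones((4, 4, 2)))
        assert m.weights == [1.0]

    def test_weights_always_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = SampleModel(capacity=4, learning_rate=0.09, label=np.ones((4, 4)))
        for _ in range(12):
            update_sample_model(m, rng.standard_normal((4, 4, 2)))
            assert sum(m.weights) == pytest.approx(1.0)
            assert len(m) <= 4
            assert all(w >= 0 for w in m.weights)

    def test_closest_pair_merged_with_weighted_mean(self):
        m = SampleModel(capacity=2, learning_rate=0.09, label=np.ones((2, 2)))
        s1 = np.zeros((2, 2, 1))
        s2 = np.ones((2, 2, 1))
        s3 = np.full((2, 2, 1), 1.1)
        update_sample_model(m, s1)
        update_sample_model(m, s2)
        update_sample_model(m, s3)
        # s2 (weight 0.0819) and s3 (weight 0.09) are closest; exhaustive
        # pairwise distances confirm: d(s1,s2)=2, d(s1,s3)=2.2, d(s2,s3)=0.2
        w2, w3 = 0.91 * 0.09, 0.09
        expected_mean = (w2 * 1.0 + w3 * 1.1) / (w2 + w3)
        assert len(m) == 2
        merged = [mu for mu in m.means if not np.allclose(mu, 0)][0]
        assert np.allclose(merged, expected_mean)
        assert sum(m.weights) == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        m = SampleModel(capacity=2, learning_rate=0.09, label=np.ones((2, 2)))
        update_sample_model(m, np.zeros((2, 2, 1)))
        with pytest.raises(ValueError):
            update_sample_model(m, np.zeros((3, 3, 1)))


class TestInitTracker:
    def _frame(self, seed=0, size=(240, 260)):
        rng = np.random.default_rng(seed)
        return (rng.uniform(0.2, 0.8, size=size + (3,)) * 255).astype(np.uint8)

    def test_tag_box_arithmetic(self):
        st = init_tracker(self._frame(), Box(100, 100, 80, 60), fraction=0.4)
        tb = st.tag_box
        assert (tb.x, tb.y, tb.w, tb.h) == pytest.approx((124, 118, 32, 24))
        assert tb.center == pytest.approx((140, 130))

    def test_fraction_one_keeps_box(self):
        b = Box(60, 60, 48, 36)
        st = init_tracker(self._frame(), b, fraction=1.0)
        tb = st.tag_box
        assert (tb.x, tb.y, tb.w, tb.h) == pytest.approx((b.x, b.y, b.w, b.h))

    @pytest.mark.parametrize("fraction", [0.3, 0.5, 0.8])
    def test_centres_coincide_for_any_fraction(self, fraction):
        b = Box(90, 80, 70, 50)
        st = init_tracker(self._frame(), b, fraction=fraction)
        assert st.tag_box.center == pytest.approx(b.center)

    def test_tag_box_inside_search_area(self):
        st = init_tracker(self._frame(), Box(100, 100, 80, 60))
        sa, tb = st.search_area, st.tag_box
        assert sa.x <= tb.x and sa.y <= tb.y and sa.x2 >= tb.x2 and sa.y2 >= tb.y2

    def test_box_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            init_tracker(self._frame(), Box(250, 100, 80, 60))

    def test_sample_model_seeded_with_one_component(self):
        st = init_tracker(self._frame(), Box(100, 100, 80, 60))
        assert len(st.sample_model) == 1
        assert st.sample_model.weights == [1.0]


class TestStep:
    def test_static_target_no_drift(self, static_target):
        st = init_tracker(static_target.frame(0), static_target.box(0))
        c0 = st.center
        for t in range(1, 51):
            st, _ = step(st, static_target.frame(t), t)
        drift = np.hypot(st.center[0] - c0[0], st.center[1] - c0[1])
        assert drift < 0.5

    def test_translating_target_displacement_recovery(self, translating_target):
        st = init_tracker(translating_target.frame(0), translating_target.box(0))
        prev = st.center[0]
        errs = []
        for t in range(1, 31):
            st, _ = step(st, translating_target.frame(t), t)
            errs.append(abs((st.center[0] - prev) - 2.0))
            prev = st.center[0]
        assert np.mean(errs) < 0.25

    def test_filters_frozen_between_updates(self, static_target):
        cfg = TrackerConfig(update_interval=2)
        st = init_tracker(static_target.frame(0), static_target.box(0), cfg)
        st, _ = step(st, static_target.frame(1), 1)   # no update yet
        st, _ = step(st, static_target.frame(2), 2)   # update frame
        after_update = st.filter_bank.filters.copy()
        st, _ = step(st, static_target.frame(3), 3)   # following non-update frame
        assert np.array_equal(st.filter_bank.filters, after_update)

    def test_flat_frame_flags_untrackable(self):
        frame = np.full((200, 200, 3), 128, dtype=np.uint8)
        st = init_tracker(frame, Box(60, 60, 60, 60))
        box_before = st.tag_box
        st, tb = step(st, frame, 1)
        assert st.flagged
        assert (tb.x, tb.y, tb.w, tb.h) == (box_before.x, box_before.y, box_before.w, box_before.h)
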