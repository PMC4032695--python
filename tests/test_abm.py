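import numpy as np
import pytest

from biomotion import abm
from biomotion.abm import (PerturbationBounds, TemplateElement,
                           local_max_pool, match_template, response_stack,
                           saturate, train_shared_sketch)
from biomotion.gabor import build_dictionary
from biomotion.synth import BarSpec, gen_bar_images


def exhaustive_selection_oracle(frames, dictionary, bounds, saturation=6.0):
    """Score every placement by its location-pooled response summed over
    frames; return the winning (row, col, ori, scale) with the
    deterministic tie-break. Independent loop-based implementation."""
    stacks = [response_stack(f, dictionary, saturation) for f in frames]
    H, W = np.asarray(frames[0]).shape
    b = bounds.location
    best = (-np.inf, None)
    for si in range(1, dictionary.n_scales + 1):
        for oi in range(dictionary.n_orientations):
            for row in range(H):
                for col in range(W):
                    total = 0.0
                    for st in stacks:
                        m = st[(si, oi)]
                        win = m[max(0, row - b):row + b + 1,
                                max(0, col - b):col + b + 1]
                        total += float(win.max())
                    key = (row, col, oi, si)
                    if total > best[0] or (total == best[0]
                                           and key < best[1]):
                        best = (total, key)
    return best[1]


class TestSaturate:
    def test_zero_fixed_point(self):
        assert np.all(saturate(np.zeros((8, 8)), 6.0) == 0)

    def test_monotone_with_shared_normalizer(self):
        rng = np.random.default_rng(0)
        r1 = rng.random((16, 16))
        r2 = r1 + rng.random((16, 16))
        norm = float((r2 * r2).mean())
        assert np.all(saturate(r1, 6.0, normalizer=norm)
                      <= saturate(r2, 6.0, normalizer=norm))

    def test_bounded_on_grid(self):
        # grid-evaluation oracle: 1e6 points spanning a huge dynamic range
        grid = np.linspace(0.0, 1e4, 1_000_000)
        out = saturate(grid, 6.0, normalizer=1.0)
        assert out.max() <= 6.0

    def test_invalid_saturation(self):
        with pytest.raises(ValueError):
            saturate(np.ones((2, 2)), 0.0)


class TestLocalMaxPool:
    def test_zero_bounds_returns_nominal(self, dictionary8):
        rng = np.random.default_rng(1)
        stack = response_stack(rng.random((32, 32)), dictionary8)
        p = TemplateElement(10, 12, 3, 1)
        val, arg = local_max_pool(stack, p, PerturbationBounds(0, 0),
                                  dictionary8.n_orientations)
        assert val == stack[(1, 3)][10, 12]
        assert (arg.row, arg.col, arg.orientation_index) == (10, 12, 3)

    def test_pooled_at_least_nominal(self, dictionary8):
        rng = np.random.default_rng(2)
        stack = response_stack(rng.random((32, 32)), dictionary8)
        for _ in range(20):
            r, c = rng.integers(0, 32, 2)
            oi = int(rng.integers(0, 8))
            p = TemplateElement(int(r), int(c), oi, 1)
            val, _ = local_max_pool(stack, p, PerturbationBounds(2, 1), 8)
            assert val >= stack[(1, oi)][r, c]

    def test_recovers_displaced_bar(self, dictionary8):
        """Exhaustive-search oracle over the perturbation window."""
        frames, _ = gen_bar_images(BarSpec(
            shape=(48, 48), seed=5, noise_sigma=0.0, n_images=1,
            center_jitter=0.0, orientation=np.pi / 2))
        stack = response_stack(frames[0], dictionary8)
        # nominal 2 px off the bar center (24, 24)
        nominal = TemplateElement(24, 22, 4, 1)
        bounds = PerturbationBounds(2, 1)
        val, arg = local_max_pool(stack, nominal, bounds, 8)
        # oracle: scan the window explicitly
        best = (-np.inf, None)
        for dr in range(-2, 3):
            for dc in range(-2, 3):
                for do in (-1, 0, 1):
                    r, c, o = 24 + dr, 22 + dc, (4 + do) % 8
                    v = stack[(1, o)][r, c]
                    if v > best[0]:
                        best = (v, (r, c, o))
        assert val == best[0]
        assert (arg.row, arg.col, arg.orientation_index) == best[1]


class TestTrainSharedSketch:
    def test_empty_selection(self, dictionary8, vertical_bar_frames):
        tpl = train_shared_sketch(vertical_bar_frames[0], 0, dictionary8)
        assert tpl.n_elements == 0

    def test_empty_training_set_rejected(self, dictionary8):
        with pytest.raises(ValueError):
            train_shared_sketch([], 3, dictionary8)

    def test_mismatched_shapes_rejected(self, dictionary8):
        with pytest.raises(ValueError):
            train_shared_sketch([np.zeros((32, 32)), np.zeros((30, 32))],
                                2, dictionary8)

    def test_first_element_matches_exhaustive_oracle(
            self, dictionary8, vertical_bar_frames):
        frames, _ = vertical_bar_frames
        bounds = PerturbationBounds(2, 1)
        tpl = train_shared_sketch(frames, 1, dictionary8,
                                  inhibition_radius=5, bounds=bounds)
        oracle = exhaustive_selection_oracle(frames, dictionary8, bounds)
        el = tpl.elements[0]
        assert (el.row, el.col, el.orientation_index, el.scale_index) == oracle
        # nearest dictionary orientation to pi/2 is index 4
        assert el.orientation_index == 4

    def test_inhibition_spacing(self, dictionary8, vertical_bar_frames):
        frames, _ = vertical_bar_frames
        radius = 5
        tpl = train_shared_sketch(frames, 6, dictionary8,
                                  inhibition_radius=radius)
        els = tpl.elements
        for i, a in enumerate(els):
            for b in els[i + 1:]:
                assert max(abs(a.row - b.row), abs(a.col - b.col)) >= radius

    def test_selection_gains_non_increasing(self, dictionary8,
                                            vertical_bar_frames):
        tpl = train_shared_sketch(vertical_bar_frames[0], 6, dictionary8,
                                  inhibition_radius=5)
        assert np.all(np.diff(tpl.deltas) <= 1e-9)

    def test_weights_finite_nonnegative(self, dictionary8,
                                        vertical_bar_frames):
        tpl = train_shared_sketch(vertical_bar_frames[0], 6, dictionary8,
                                  inhibition_radius=5)
        assert np.all(np.isfinite(tpl.weights))
        assert np.all(tpl.weights >= 0)

    def test_exhausted_placements_warns_and_truncates(self, dictionary8,
                                                      caplog):
        frames, _ = gen_bar_images(BarSpec(shape=(32, 32), seed=3,
                                           noise_sigma=0.0, n_images=2,
                                           center_jitter=0.0))
        with caplog.at_level("WARNING", logger="biomotion.abm"):
            tpl = train_shared_sketch(frames, 500, dictionary8,
                                      inhibition_radius=16)
        assert tpl.n_elements < 500
        assert any("stopped early" in r.message for r in caplog.records)

    def test_roi_restricts_centers(self, dictionary8, vertical_bar_frames):
        frames, _ = vertical_bar_frames
        roi = np.zeros((48, 48), dtype=bool)
        roi[:20, :] = True
        tpl = train_shared_sketch(frames, 4, dictionary8,
                                  inhibition_radius=4, roi=roi)
        assert all(e.row < 20 for e in tpl.elements)

    def test_zero_inhibition_degenerates_gracefully(self, small_dictionary):
        rng = np.random.default_rng(0)
        frames = [rng.random((12, 12)) for _ in range(2)]
        tpl = train_shared_sketch(frames, 20, small_dictionary,
                                  inhibition_radius=0)
        assert tpl.n_elements <= 20  # no crash; documented behavior


@pytest.fixture(scope="module")
def bar_template(dictionary8, vertical_bar_frames):
    return train_shared_sketch(vertical_bar_frames[0], 6, dictionary8,
                               inhibition_radius=5)


class TestMatchTemplate:
    def test_empty_template_degenerate(self, dictionary8):
        tpl = train_shared_sketch([np.random.default_rng(0).random((16, 16))],
                                  0, dictionary8)
        res = match_template(np.ones((16, 16)), tpl)
        assert res.score == 0.0
        assert res.location == (0, 0)
        assert res.degenerate

    def test_training_frame_beats_noise(self, bar_template,
                                        vertical_bar_frames):
        frames, _ = vertical_bar_frames
        rng = np.random.default_rng(11)
        wins = 0
        trials = 40
        for t in range(trials):
            f = frames[t % len(frames)]
            noise = rng.normal(f.mean(), f.std(), f.shape)
            wins += (match_template(f, bar_template).score
                     > match_template(noise, bar_template).score)
        assert wins >= int(0.95 * trials)

    def test_translated_bar_localized(self, bar_template,
                                      vertical_bar_frames):
        frames, _ = vertical_bar_frames
        shifted = np.roll(frames[0], (3, 5), axis=(0, 1))
        res = match_template(shifted, bar_template)
        # saturated bar responses plateau over the bar width, so the
        # argmax offset is determined up to bound + half bar width
        tol = bar_template.bounds.location + 2
        assert abs(res.offset[0] - 3) <= tol
        assert abs(res.offset[1] - 5) <= tol

    def test_matches_exhaustive_lattice_oracle(self, dictionary8):
        """Brute-force scan over all offsets on a small frame."""
        frames, _ = gen_bar_images(BarSpec(shape=(24, 24), seed=9,
                                           noise_sigma=0.05, n_images=2))
        tpl = train_shared_sketch(frames, 3, dictionary8,
                                  inhibition_radius=4)
        rng = np.random.default_rng(1)
        frame = frames[0] + 0.01 * rng.standard_normal(frames[0].shape)
        res = match_template(frame, tpl)
        H, W = frame.shape
        stack = response_stack(frame, tpl.dictionary, tpl.saturation)
        best = (-np.inf, None)
        for dy in range(-(H - 1), H):
            for dx in range(-(W - 1), W):
                s = -float(np.sum(tpl.log_normalizers))
                for el, lam in zip(tpl.elements, tpl.weights):
                    r, c = el.row + dy, el.col + dx
                    if 0 <= r < H and 0 <= c < W:
                        v, _ = local_max_pool(
                            stack, TemplateElement(r, c, el.orientation_index,
                                                   el.scale_index),
                            tpl.bounds, tpl.dictionary.n_orientations)
                        s += lam * v
                if s > best[0]:
                    best = (s, (dy, dx))
        assert res.score == pytest.approx(best[0], abs=1e-9)

    def test_score_constant_invariance(self, bar_template,
                                       vertical_bar_frames):
        f = vertical_bar_frames[0][0]
        s1 = match_template(f, bar_template).score
        s2 = match_template(f + 3.25, bar_template).score
        assert abs(s1 - s2) < 1e-6
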