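"""Binning, ring-ROI selection, detrending, and frame splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dxblink.preprocess import (
    PixelTrace,
    RingROI,
    bin_pixels,
    detrend_matrix,
    detrend_trace,
    select_ring_pixels,
    split_frames,
)
from dxblink.stack_io import DetectorGeometry, FrameStack

from .conftest import make_trace


def stack_from(counts):
    return FrameStack(np.asarray(counts, dtype=np.uint32), frame_interval=0.05)


class TestBinning:
    def test_ones_sum_to_block_area(self):
        stack = stack_from(np.ones((2, 6, 6)))
        out = bin_pixels(stack, 3)
        assert out.frame_shape == (2, 2)
        assert np.all(out.counts == 9)

    def test_identity_at_b1(self, tiny_stack):
        assert bin_pixels(tiny_stack, 1) is tiny_stack

    def test_trailing_pixels_dropped(self):
        counts = np.arange(7 * 7, dtype=np.uint32).reshape(1, 7, 7)
        out = bin_pixels(stack_from(counts), 2)
        assert out.frame_shape == (3, 3)
        # brute-force block sums over the covered 6x6 region
        expected = counts[0, :6, :6].reshape(3, 2, 3, 2).sum(axis=(1, 3))
        assert np.array_equal(out.counts[0], expected)
        assert out.counts.sum() == counts[0, :6, :6].sum()

    def test_binned_validity_requires_all_constituents(self):
        stack = stack_from(np.ones((1, 4, 4)))
        stack.mask[0, 0] = False
        out = bin_pixels(stack, 2)
        assert not out.mask[0, 0] and out.mask[0, 1] and out.mask[1, 0]

    def test_invalid_bin_size(self, tiny_stack):
        with pytest.raises(ValueError):
            bin_pixels(tiny_stack, 4)

    @given(st.integers(2, 3), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_count_conservation_over_covered_region(self, b, seed):
        counts = np.random.default_rng(seed).integers(0, 50, (3, 7, 9)).astype(np.uint32)
        out = bin_pixels(stack_from(counts), b)
        rows, cols = (7 // b) * b, (9 // b) * b
        for f in range(3):
            assert out.counts[f].sum() == counts[f, :rows, :cols].sum()

    def test_binning_commutes_with_frame_splitting(self):
        counts = np.random.default_rng(1).integers(0, 9, (10, 6, 6)).astype(np.uint32)
        stack = stack_from(counts)
        a = [bin_pixels(s, 2) for s in split_frames(stack, 2)]
        b = split_frames(bin_pixels(stack, 2), 2)
        for x, y in zip(a, b):
            assert np.array_equal(x.counts, y.counts)


class TestRingSelection:
    geom = DetectorGeometry(wavelength=1.54, distance=60.0, pixel_pitch=172.0,
                            beam_center=(0.0, 0.0))

    def test_selected_radii_inside_annulus(self):
        mask = np.ones((120, 120), bool)
        roi = RingROI(two_theta_center=12.59, two_theta_halfwidth=0.3)
        sel = select_ring_pixels(self.geom, roi, mask)
        assert len(sel)
        r = np.hypot(sel[:, 0], sel[:, 1])
        r_lo = self.geom.ring_radius_px(12.29)
        r_hi = self.geom.ring_radius_px(12.89)
        assert np.all((r >= r_lo) & (r <= r_hi))
        # ring radius ~ 77.9 px at this geometry
        assert abs(np.median(r) - 77.9) < 2.0

    def test_monotone_in_halfwidth(self):
        mask = np.ones((120, 120), bool)
        small = select_ring_pixels(self.geom, RingROI(12.59, 0.2), mask)
        large = select_ring_pixels(self.geom, RingROI(12.59, 0.6), mask)
        small_set = {tuple(p) for p in small}
        large_set = {tuple(p) for p in large}
        assert small_set <= large_set

    def test_off_detector_warns_empty(self):
        mask = np.ones((10, 10), bool)
        geom = DetectorGeometry(wavelength=1.54, distance=60.0, pixel_pitch=172.0,
                                beam_center=(-500.0, -500.0))
        with pytest.warns(UserWarning):
            sel = select_ring_pixels(geom, RingROI(12.59, 0.1), mask)
        assert len(sel) == 0

    def test_masked_pixels_excluded(self):
        mask = np.ones((120, 120), bool)
        roi = RingROI(12.59, 0.3)
        sel_all = select_ring_pixels(self.geom, roi, mask)
        mask[sel_all[0][0], sel_all[0][1]] = False
        sel = select_ring_pixels(self.geom, roi, mask)
        assert len(sel) == len(sel_all) - 1


class TestDetrend:
    def test_exact_ramp_flattens_to_mean(self):
        y = 5.0 + 0.3 * np.arange(50)
        out = detrend_trace(make_trace(y), policy="always")
        assert np.allclose(out.intensities, y.mean())
        assert out.detrended

    def test_flat_series_unchanged(self):
        y = np.full(30, 7.0)
        for policy in ("always", "auto", "never"):
            out = detrend_trace(make_trace(y), policy=policy)
            assert np.array_equal(out.intensities, y)

    def test_auto_skips_insignificant_slope(self, rng):
        y = rng.poisson(20, 200).astype(float)
        out = detrend_trace(make_trace(y), policy="auto")
        # pure noise: no significant slope at 5% for this seed
        assert not out.detrended

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_preserved_to_machine_precision(self, seed):
        r = np.random.default_rng(seed)
        y = r.normal(50, 5, 100) + r.uniform(-0.2, 0.2) * np.arange(100)
        out = detrend_trace(make_trace(y), policy="always")
        assert out.intensities.mean() == pytest.approx(y.mean(), abs=1e-9)

    def test_matrix_matches_per_trace(self, rng):
        Y = rng.normal(30, 3, (20, 80)) + rng.uniform(-0.1, 0.1, (20, 1)) * np.arange(80)
        for policy in ("always", "auto"):
            M = detrend_matrix(Y, policy=policy)
            for i in range(20):
                single = detrend_trace(make_trace(Y[i]), policy=policy).intensities
                assert np.allclose(M[i], single, atol=1e-10)

    def test_gamma_recovery_survives_linear_drift(self):
        # telegraph + ramp: after detrending, the ensemble decay constant
        # matches the one fitted on the ramp-free traces
        from dxblink.blinking_acf import classify_and_fit
        from dxblink.simulate import simulate_telegraph_states

        states = simulate_telegraph_states(0.5, 0.5, 2000, 0.05, 40, seed=42)
        ramp = 0.01 * np.arange(2000)
        g_base, g_ramp = [], []
        for s in states:
            base = 20.0 * s + 10.0
            fb = classify_and_fit(make_trace(base))
            fr = classify_and_fit(detrend_trace(make_trace(base + ramp), policy="always"))
            if fb.accepted and fr.accepted:
                g_base.append(fb.gamma)
                g_ramp.append(fr.gamma)
        assert len(g_base) > 20
        assert np.median(g_ramp) == pytest.approx(np.median(g_base), rel=0.10)


class TestSplitFrames:
    def test_even_split_2000_by_10(self):
        stack = stack_from(np.zeros((2000, 2, 2)))
        subs = split_frames(stack, 10)
        assert len(subs) == 10 and all(s.n_frames == 200 for s in subs)

    def test_k1_is_original(self, tiny_stack):
        (only,) = split_frames(tiny_stack, 1)
        assert np.array_equal(only.counts, tiny_stack.counts)

    def test_remainder_dropped_from_tail(self):
        counts = np.arange(2001)[:, None, None] * np.ones((1, 2, 2))
        stack = stack_from(counts)
        subs = split_frames(stack, 2)
        assert [s.n_frames for s in subs] == [1000, 1000]
        assert subs[1].counts[-1, 0, 0] == 1999  # frame 2000 dropped

    def test_k_too_large(self, tiny_stack):
        with pytest.raises(ValueError):
            split_frames(tiny_stack, 3)


def test_pixel_trace_validation():
    with pytest.raises(ValueError):
        PixelTrace(np.array([1.0]), 0, 0)
    with pytest.raises(ValueError):
        PixelTrace(np.array([1.0, np.nan, 2.0]), 0, 0)
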