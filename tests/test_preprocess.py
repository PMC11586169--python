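"""Preprocessing identities: truncation, averaging, GF, SNV, MSC and dispatch."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirselect import SimulationConfig, generate, preprocess
from nirselect.preprocess import (PreprocessConfig, average_frames, gaussian_filter,
                                  gaussian_kernel, msc, snv, truncate_edge_frames)


# -- edge-frame truncation ----------------------------------------------

def _frames_with_totals(totals):
    """Constant frames whose row sums equal the given totals (4 points each)."""
    return np.array([[t / 4.0] * 4 for t in totals])


class TestTruncation:
    def test_bright_edges_dropped(self):
        # totals [10,3,3,3,9], factor 1.5 -> median 3, threshold 4.5 -> keep middle 3
        frames = _frames_with_totals([10, 3, 3, 3, 9])
        kept = truncate_edge_frames(frames, 1.5)
        np.testing.assert_array_equal(kept, frames[1:4])

    def test_equal_totals_all_kept(self):
        frames = _frames_with_totals([5, 5, 5, 5])
        np.testing.assert_array_equal(truncate_edge_frames(frames, 1.5), frames)

    def test_single_frame_kept(self):
        frames = _frames_with_totals([7])
        np.testing.assert_array_equal(truncate_edge_frames(frames, 1.5), frames)

    def test_interior_bright_frame_survives(self):
        # contiguity: only leading/trailing bright frames are removed
        frames = _frames_with_totals([10, 3, 30, 3, 3])
        np.testing.assert_array_equal(truncate_edge_frames(frames, 1.5), frames[1:])

    def test_invalid_factor_rejected(self):
        # the threshold is factor * median, so factor must exceed 1
        with pytest.raises(ValueError, match="truncate_factor"):
            truncate_edge_frames(_frames_with_totals([10, 3, 9]), 1.0)


class TestAveraging:
    def test_identical_frames(self):
        f = np.tile([1.0, 2.0, 3.0], (4, 1))
        np.testing.assert_array_equal(average_frames(f), f[0])

    def test_two_frames(self):
        np.testing.assert_array_equal(
            average_frames(np.array([[1.0, 3.0], [3.0, 5.0]])), [2.0, 4.0])

    def test_matches_independent_column_means(self, rng):
        f = rng.normal(size=(5, 20))
        expected = np.array([f[:, j].sum() / 5 for j in range(20)])
        np.testing.assert_allclose(average_frames(f), expected, atol=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            average_frames(np.empty((0, 4)))


# -- Gaussian filter ------------------------------------------------------

class TestGaussianFilter:
    def test_kernel_normalized(self):
        for window, sigma in [(3, 0.5), (11, 2.2), (25, 5.0)]:
            assert gaussian_kernel(window, sigma).sum() == pytest.approx(1.0, abs=1e-12)

    def test_constant_preserved(self):
        x = np.full(50, 3.7)
        np.testing.assert_allclose(gaussian_filter(x, 11), x, atol=1e-12)

    def test_impulse_response_is_kernel(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = gaussian_filter(x, 11, 2.0)
        k = gaussian_kernel(11, 2.0)
        np.testing.assert_allclose(out[45:56], k, atol=1e-12)
        assert np.all(out[:45] == 0) and np.all(out[56:] == 0)

    def test_linearity(self, rng):
        x, y = rng.normal(size=(2, 64))
        lhs = gaussian_filter(2.5 * x - 1.3 * y, 9)
        rhs = 2.5 * gaussian_filter(x, 9) - 1.3 * gaussian_filter(y, 9)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_reduces_white_noise_variance(self):
        # variance strictly reduced in every one of 100 seeded trials
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=200)
            assert gaussian_filter(x, 11).var() < x.var()

    @pytest.mark.parametrize("window", [2, 4, 10])
    def test_even_window_rejected(self, window):
        with pytest.raises(ValueError):
            gaussian_filter(np.ones(50), window)

    def test_window_longer_than_spectrum_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            gaussian_filter(np.ones(9), 11)


# -- SNV ------------------------------------------------------------------

class TestSNV:
    def test_three_point_example(self):
        # mean 2, sample sd 1 -> [-1, 0, 1]
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1, 0, 1], atol=1e-12)

    def test_output_standardized(self, rng):
        out = snv(rng.normal(2.0, 5.0, size=(10, 40)))
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.1, 100), b=st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        x = np.sin(np.linspace(0, 7, 60)) + np.linspace(0, 1, 60)
        np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)

    def test_idempotent(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-10)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(np.full(20, 2.0))


# -- MSC ------------------------------------------------------------------

class TestMSC:
    def test_reference_maps_to_itself(self, rng):
        r = rng.normal(size=64) + np.linspace(0, 3, 64)
        out = msc(r[None, :], reference=r)
        np.testing.assert_allclose(out[0], r, atol=1e-10)

    def test_exact_affine_scatter_inverted(self, rng):
        r = np.sin(np.linspace(0, 5, 80)) + 2
        s = 2.0 * r + 5.0
        np.testing.assert_allclose(msc(s[None, :], reference=r)[0], r, atol=1e-10)

    def test_corrected_set_regresses_to_identity(self, rng):
        """Independent least-squares refit of corrected spectra on the reference
        must give slope 1, intercept 0."""
        r = np.cos(np.linspace(0, 6, 100)) + 3
        a = rng.uniform(0.5, 2.0, size=12)
        b = rng.normal(0, 2, size=12)
        X = a[:, None] * r[None, :] + b[:, None]
        out = msc(X, reference=r)
        D = np.column_stack([r, np.ones_like(r)])
        for row in out:
            slope, intercept = np.linalg.lstsq(D, row, rcond=None)[0]
            assert slope == pytest.approx(1.0, abs=1e-8)
            assert intercept == pytest.approx(0.0, abs=1e-8)

    def test_idempotent_with_fixed_reference(self, rng):
        r = np.linspace(1, 4, 50) + np.sin(np.linspace(0, 9, 50))
        X = rng.uniform(0.5, 2, size=(6, 1)) * r + rng.normal(size=(6, 1))
        once = msc(X, reference=r)
        np.testing.assert_allclose(msc(once, reference=r), once, atol=1e-10)

    def test_generator_scatter_roundtrip(self):
        """MSC recovers the scatter-free spectrum from simulated a*r+b scatter."""
        base = SimulationConfig(n_samples=12, n_wavelengths=128, noise_sd=0.0,
                                scatter_mult_sd=0.0, scatter_add_sd=0.0,
                                path_length_sd=0.0, conc_sd=0.0, seed=3)
        clean, _, _ = generate(base)
        noisy, _, _ = generate(dataclasses.replace(base, scatter_mult_sd=0.2,
                                                   scatter_add_sd=400.0))
        out = msc(noisy.intensities, reference=clean.intensities[0])
        np.testing.assert_allclose(out, clean.intensities, rtol=1e-6)

    def test_mean_reference_needs_two_spectra(self):
        with pytest.raises(ValueError, match="at least 2"):
            msc(np.ones((1, 10)) * np.arange(10.0))


# -- dispatch -------------------------------------------------------------

class TestApply:
    def test_raw_appends_history_only(self, small_dataset):
        sset, _, _ = small_dataset
        out = preprocess.apply(sset, PreprocessConfig(method="raw"))
        np.testing.assert_array_equal(out.intensities, sset.intensities)
        assert out.history[-1] == "raw"
        assert len(out.history) == len(sset.history) + 1

    def test_gf_msc_is_composition(self, small_dataset):
        sset, _, _ = small_dataset
        combo = preprocess.apply(sset, PreprocessConfig(method="gf+msc"))
        smooth = preprocess.apply(sset, PreprocessConfig(method="gf"))
        two_step = preprocess.apply(smooth, PreprocessConfig(method="msc"))
        np.testing.assert_allclose(combo.intensities, two_step.intensities, atol=1e-12)

    def test_snv_and_msc_agree_on_scatter_removal(self, small_absorbance):
        """Both corrections remove offset/scale; per-spectrum correlation > 0.999."""
        sset, _, _ = small_absorbance
        a = preprocess.apply(sset, PreprocessConfig(method="snv"))
        b = preprocess.apply(sset, PreprocessConfig(method="msc"))
        for u, v in zip(a.intensities, b.intensities):
            assert np.corrcoef(u, v)[0, 1] > 0.999

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            PreprocessConfig(method="savgol")

    def test_explicit_msc_reference_used_for_prediction_set(self, small_absorbance):
        sset, _, _ = small_absorbance
        cfg = PreprocessConfig(method="msc")
        ref_spec = preprocess.fit_reference(sset, cfg)
        out1 = preprocess.apply(sset, dataclasses.replace(cfg, msc_reference=ref_spec))
        out2 = preprocess.apply(sset, cfg)
        np.testing.assert_allclose(out1.intensities, out2.intensities, atol=1e-12)
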