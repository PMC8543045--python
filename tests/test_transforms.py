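"""SPAR attractor and Morse scalogram contracts and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgnoise import (
    ECGRecord,
    MorphologyParams,
    ScalogramConfig,
    SPARConfig,
    TransformImage,
    cwt_scalogram,
    delay_embed,
    density_image,
    generate_record,
    resize_for_network,
    spar_attractor,
    spar_project,
)
from ecgnoise.transforms import PROJECTION, morse_cwt

FS = 500.0


class TestDelayEmbed:
    def test_point_count(self):
        pts = delay_embed(np.arange(100.0), 10)
        assert pts.shape == (80, 3)

    def test_coordinate_convention(self):
        x = np.arange(50.0)
        pts = delay_embed(x, 5)
        np.testing.assert_array_equal(pts[0], [10.0, 5.0, 0.0])

    def test_constant_signal_on_diagonal(self):
        pts = delay_embed(np.full(40, 2.5), 4)
        np.testing.assert_array_equal(pts, np.full((32, 3), 2.5))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="short"):
            delay_embed(np.arange(20.0), 10)

    def test_sine_at_third_period_gives_constant_radius(self):
        period_s = 1.0
        tau = int(FS * period_s / 3)
        sig = np.sin(2 * np.pi * np.arange(0, 10, 1 / FS) / period_s)
        vw = spar_project(delay_embed(sig, tau))
        radius = np.hypot(vw[:, 0], vw[:, 1])
        assert radius.std() / radius.mean() < 0.01


class TestSparProject:
    def test_diagonal_maps_to_origin(self):
        for c in (-3.0, 0.0, 7.7):
            np.testing.assert_allclose(spar_project([[c, c, c]]), 0.0, atol=1e-12)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3))
        np.testing.assert_allclose(
            spar_project(pts), spar_project(pts + 4.2), atol=1e-12
        )

    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(200, 3))
        oracle = pts @ PROJECTION.T
        np.testing.assert_allclose(spar_project(pts), oracle, atol=1e-12)

    def test_basis_is_orthonormal_and_kills_diagonal(self):
        np.testing.assert_allclose(PROJECTION @ PROJECTION.T, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(PROJECTION @ np.ones(3), 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_projection_contracts_distances(self, seed):
        """Projection onto a plane never increases pairwise distances, with
        equality when the difference vector lies in the plane."""
        rng = np.random.default_rng(seed)
        p, q = rng.normal(size=3), rng.normal(size=3)
        d3 = np.linalg.norm(p - q)
        pv, qv = spar_project([p, q])
        d2 = np.linalg.norm(pv - qv)
        assert d2 <= d3 + 1e-9
        in_plane = (p - q) - np.mean(p - q)  # subtract the (1,1,1) component
        pv2, qv2 = spar_project([in_plane, np.zeros(3)])
        assert np.linalg.norm(pv2 - qv2) == pytest.approx(
            np.linalg.norm(in_plane), abs=1e-9
        )


class TestDensityImage:
    def test_identical_points_single_pixel(self):
        img = density_image(np.tile([[0.3, -0.1]], (25, 1)))
        assert img.pixels.shape == (150, 150)
        assert np.count_nonzero(img.pixels) == 1
        assert img.pixels.max() == 1.0

    def test_histogram_conservation(self):
        rng = np.random.default_rng(2)
        vw = rng.normal(size=(500, 2))
        cfg = SPARConfig(density_scaling="linear")
        img = density_image(vw, cfg)
        # un-normalize: peak bin count recovers total mass
        r = img.meta["bound"]
        counts, _, _ = np.histogram2d(vw[:, 1], vw[:, 0], bins=150, range=[[-r, r], [-r, r]])
        assert counts.sum() == 500
        np.testing.assert_allclose(img.pixels, counts[::-1] / counts.max(), atol=1e-12)

    def test_matches_brute_force_binning_oracle(self):
        rng = np.random.default_rng(3)
        vw = rng.uniform(-1, 1, size=(300, 2))
        cfg = SPARConfig(grid=10, density_scaling="linear")
        img = density_image(vw, cfg)
        r = float(np.max(np.abs(vw)))
        oracle = np.zeros((10, 10))
        width = 2 * r / 10
        for v, w in vw:
            j = min(int((v + r) / width), 9)
            i = min(int((w + r) / width), 9)
            oracle[9 - i, j] += 1
        np.testing.assert_allclose(img.pixels * oracle.max(), oracle, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            density_image(np.empty((0, 2)))


class TestSparAttractor:
    def test_default_size_150(self, normal_record):
        img = spar_attractor(normal_record)
        assert img.pixels.shape == (150, 150)
        assert img.kind == "attractor"

    def test_exact_offset_invariance(self, normal_record):
        shifted = normal_record.with_signal(normal_record.signal + 0.5, "raw")
        a = spar_attractor(normal_record)
        b = spar_attractor(shifted)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_heart_rate_factored_out(self):
        """Same morphology at 60 vs 90 bpm: with tau locked to cycle/3 the
        attractors nearly coincide (mean absolute pixel error < 0.05)."""
        p60 = MorphologyParams(normal_hr_bpm=60, normal_rr_cv=0.0)
        p90 = MorphologyParams(normal_hr_bpm=90, normal_rr_cv=0.0)
        a = spar_attractor(generate_record("Normal", 30.0, FS, np.random.default_rng(11), p60))
        b = spar_attractor(generate_record("Normal", 30.0, FS, np.random.default_rng(11), p90))
        assert np.abs(a.pixels - b.pixels).mean() < 0.05

    def test_fallback_tau_on_constant_signal(self):
        rec = ECGRecord("flat", "Normal", FS, np.zeros(5000), 10.0, "raw")
        with pytest.warns(UserWarning, match="cycle"):
            img = spar_attractor(rec)
        assert img.pixels.shape == (150, 150)


class TestScalogram:
    def test_zero_signal_all_zero(self):
        rec = ECGRecord("z", "Normal", FS, np.zeros(5000), 10.0, "raw")
        img = cwt_scalogram(rec)
        np.testing.assert_array_equal(img.pixels, 0.0)

    def test_default_size_150(self, normal_record):
        img = cwt_scalogram(normal_record)
        assert img.pixels.shape == (150, 150)
        assert img.kind == "scalogram"
        assert 0.0 <= img.pixels.min() and img.pixels.max() <= 1.0

    def test_pure_tone_ridge_at_10hz(self):
        sig = np.sin(2 * np.pi * 10 * np.arange(0, 20, 1 / FS))
        rec = ECGRecord("tone", "Normal", FS, sig, 20.0, "raw")
        cfg = ScalogramConfig()
        img = cwt_scalogram(rec, cfg)
        _, freqs = morse_cwt(sig, FS, cfg)
        row = int(np.argmax(img.pixels.mean(axis=1)))
        f_row = freqs[int(round(np.interp(row, [0, 149], [0, len(freqs) - 1])))]
        assert 8.0 <= f_row <= 12.5

    def test_frequency_axis_monotone(self):
        _, freqs = morse_cwt(np.random.default_rng(4).normal(size=4000), FS)
        assert np.all(np.diff(freqs) < 0)  # descending top-to-bottom

    def test_voices_per_octave_spacing(self):
        _, freqs = morse_cwt(np.random.default_rng(5).normal(size=4000), FS)
        ratios = freqs[:-1] / freqs[1:]
        np.testing.assert_allclose(ratios, 2 ** (1 / 16), rtol=1e-9)

    def test_ridge_agrees_with_independent_cwt(self):
        """Cross-check the Morse filter bank against PyWavelets' complex
        Morlet CWT: both must locate a 7 Hz tone's ridge at 7 Hz."""
        pywt = pytest.importorskip("pywt")
        sig = np.sin(2 * np.pi * 7 * np.arange(0, 10, 1 / FS))
        mag, freqs = morse_cwt(sig, FS)
        ours = freqs[int(np.argmax(mag.mean(axis=1)))]
        scales = pywt.frequency2scale("cmor1.5-1.0", np.asarray(freqs) / FS)
        coef, pf = pywt.cwt(sig, scales, "cmor1.5-1.0", sampling_period=1 / FS)
        theirs = pf[int(np.argmax(np.abs(coef).mean(axis=1)))]
        assert ours == pytest.approx(7.0, rel=0.06)
        assert theirs == pytest.approx(ours, rel=0.06)


class TestResizeForNetwork:
    def test_resize_to_224(self, normal_record):
        img = spar_attractor(normal_record)
        out = resize_for_network(img, 224)
        assert out.shape == (224, 224)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_identity_resize_unchanged(self, normal_record):
        img = spar_attractor(normal_record)
        np.testing.assert_allclose(resize_for_network(img, 150), img.pixels, atol=1e-12)

    def test_constant_image_stays_constant(self):
        img = TransformImage(np.full((150, 150), 0.4), "attractor")
        out = resize_for_network(img, 227)
        np.testing.assert_allclose(out, 0.4, atol=1e-9)

    def test_unsupported_side_rejected(self, normal_record):
        img = spar_attractor(normal_record)
        with pytest.raises(ValueError, match="side"):
            resize_for_network(img, 100)
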