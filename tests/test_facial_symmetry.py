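import numpy as np
import pytest

from fearleak.errors import EmptyMask, LengthMismatch, MissingLandmarks, TooShort
from fearleak.facial_symmetry import (
    OMEGA0,
    CoherenceMap,
    cwt_morlet,
    distance_signals,
    mean_coherence,
    morlet_scales,
    wavelet_coherence,
)


def reference_cwt_direct(x: np.ndarray, dt: float, scale: float, omega0: float = OMEGA0):
    """Independent oracle: direct time-domain Morlet convolution.

    W(s, n) = sum_m x_m sqrt(dt/s) psi0*((m - n) dt / s), with the analytic
    Morlet psi0(eta) = pi^(-1/4) exp(i omega0 eta) exp(-eta^2 / 2).
    """
    x = x - x.mean()
    n = len(x)
    out = np.empty(n, dtype=complex)
    m = np.arange(n)
    for t in range(n):
        eta = (m - t) * dt / scale
        psi = np.pi ** (-0.25) * np.exp(1j * omega0 * eta) * np.exp(-0.5 * eta**2)
        out[t] = np.sum(x * np.conj(psi)) * np.sqrt(dt / scale)
    return out


class TestCwt:
    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(256)
        dt = 1 / 30
        scales = morlet_scales(256, dt)
        W = cwt_morlet(x, dt, scales)
        # mid scales: small scales alias the time-sampled oracle wavelet and
        # the largest scales feel the oracle's truncation at the array edges
        for idx in (10, 15, 20, 30):
            ref = reference_cwt_direct(x, dt, scales[idx])
            mid = slice(64, 192)
            np.testing.assert_allclose(W[idx][mid], ref[mid], rtol=1e-4, atol=1e-7)

    def test_peak_scale_tracks_sinusoid_frequency(self):
        dt = 1 / 30
        n = 1024
        freq = 1.5  # Hz
        t = np.arange(n) * dt
        x = np.cos(2 * np.pi * freq * t)
        scales = morlet_scales(n, dt)
        W = cwt_morlet(x, dt, scales)
        power = (np.abs(W[:, 256:768]) ** 2).mean(axis=1)
        # fourier period of the Morlet: lambda = 4 pi s / (w0 + sqrt(2 + w0^2))
        fourier_factor = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))
        peak_freq = 1.0 / (fourier_factor * scales[np.argmax(power)])
        assert peak_freq == pytest.approx(freq, rel=0.1)


class TestWaveletCoherence:
    def test_self_coherence_in_cone(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.standard_normal(512))
        cmap = wavelet_coherence(x, x, dt=1 / 30)
        assert cmap.coherence[cmap.coi_mask].min() >= 0.99

    def test_sinusoids_with_phase_lag(self):
        dt = 1 / 30
        n = 1024
        freq = 1.0
        t = np.arange(n) * dt
        rng = np.random.default_rng(2)
        x = np.cos(2 * np.pi * freq * t) + 0.05 * rng.standard_normal(n)
        y = np.cos(2 * np.pi * freq * t - np.pi / 4) + 0.05 * rng.standard_normal(n)
        cmap = wavelet_coherence(x, y, dt=dt)
        fourier_factor = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0**2))
        target_scale = 1.0 / (freq * fourier_factor)
        s_idx = int(np.argmin(np.abs(cmap.scales - target_scale)))
        in_cone = cmap.coi_mask[s_idx]
        assert cmap.coherence[s_idx][in_cone].mean() >= 0.9
        # x leads y by pi/4, so the relative phase of the cross-spectrum is +pi/4
        mean_phase = np.angle(np.exp(1j * cmap.phase[s_idx][in_cone]).mean())
        assert mean_phase == pytest.approx(np.pi / 4, abs=0.2)

    def test_independent_white_noise_low_coherence(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(3):
            cmap = wavelet_coherence(
                rng.standard_normal(2048), rng.standard_normal(2048), dt=1 / 30
            )
            vals.append(mean_coherence(cmap))
        assert np.mean(vals) < 0.5

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(256), rng.standard_normal(256)
        a = wavelet_coherence(x, y, dt=0.1)
        b = wavelet_coherence(y, x, dt=0.1)
        np.testing.assert_allclose(a.coherence, b.coherence, atol=1e-10)

    def test_amplitude_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(256), rng.standard_normal(256)
        a = wavelet_coherence(x, y, dt=0.1)
        b = wavelet_coherence(-2.5 * x + 7.0, y, dt=0.1)
        np.testing.assert_allclose(a.coherence, b.coherence, atol=1e-8)

    def test_values_within_unit_interval(self):
        rng = np.random.default_rng(6)
        cmap = wavelet_coherence(rng.standard_normal(128), rng.standard_normal(128), dt=1.0)
        assert cmap.coherence.min() >= 0.0
        assert cmap.coherence.max() <= 1.0

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            wavelet_coherence(np.ones(100), np.ones(101), dt=1.0)

    def test_too_short(self):
        with pytest.raises(TooShort):
            wavelet_coherence(np.ones(63), np.ones(63), dt=1.0)

    def test_nan_gaps_interpolated(self):
        rng = np.random.default_rng(7)
        x = np.cumsum(rng.standard_normal(256))
        y = x.copy()
        y[100:105] = np.nan
        cmap = wavelet_coherence(x, y, dt=1 / 30)
        assert np.isfinite(cmap.coherence).all()

    def test_coi_mask_excludes_edges_at_large_scales(self):
        rng = np.random.default_rng(8)
        cmap = wavelet_coherence(rng.standard_normal(256), rng.standard_normal(256), dt=1.0)
        assert not cmap.coi_mask[-1, 0]  # largest scale, first sample: outside
        assert cmap.coi_mask[0, 128]  # smallest scale, center: inside


def _uniform_map(value: float, n_scales: int = 4, n_times: int = 8) -> CoherenceMap:
    return CoherenceMap(
        coherence=np.full((n_scales, n_times), value),
        phase=np.zeros((n_scales, n_times)),
        scales=np.arange(1, n_scales + 1, dtype=float),
        times=np.arange(n_times, dtype=float),
        coi_mask=np.ones((n_scales, n_times), dtype=bool),
    )


class TestMeanCoherence:
    def test_all_ones(self):
        assert mean_coherence(_uniform_map(1.0)) == 1.0

    def test_all_zeros(self):
        assert mean_coherence(_uniform_map(0.0)) == 0.0

    def test_checkerboard(self):
        cmap = _uniform_map(0.0)
        board = np.indices(cmap.coherence.shape).sum(axis=0) % 2
        cmap = CoherenceMap(board.astype(float), cmap.phase, cmap.scales, cmap.times, cmap.coi_mask)
        assert mean_coherence(cmap) == 0.5

    def test_empty_mask_raises(self):
        cmap = _uniform_map(1.0)
        cmap.coi_mask[:] = False
        with pytest.raises(EmptyMask):
            mean_coherence(cmap)


class TestDistanceSignals:
    def test_three_four_five_triangle(self, make_clip):
        landmarks = np.zeros((2, 68, 2))
        landmarks[:, 40] = [3.0, 4.0]  # landmark 20 stays at the origin
        clip = make_clip(2, landmarks=landmarks)
        pair = distance_signals(clip)
        np.testing.assert_allclose(pair.ld1, 5.0)

    def test_coincident_landmarks(self, make_clip):
        clip = make_clip(2, landmarks=np.zeros((2, 68, 2)))
        pair = distance_signals(clip)
        np.testing.assert_allclose(pair.ld1, 0.0)
        np.testing.assert_allclose(pair.rd1, 0.0)

    def test_missing_landmark_columns(self, make_clip):
        clip = make_clip(2)
        clip.frames = clip.frames.drop(columns=["x_20"])
        with pytest.raises(MissingLandmarks):
            distance_signals(clip)

    def test_configurable_pairs(self, make_clip):
        landmarks = np.zeros((2, 68, 2))
        landmarks[:, 1] = [0.0, 2.0]
        clip = make_clip(2, landmarks=landmarks)
        pair = distance_signals(clip, left_pair=(0, 1), right_pair=(2, 3))
        np.testing.assert_allclose(pair.ld1, 2.0)
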