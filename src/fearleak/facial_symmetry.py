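"""Left/right eyebrow-eye distance signals and their wavelet coherence.

Facial symmetry is quantified by the magnitude-squared wavelet coherence of
two per-frame distance signals: ``ld1`` (landmarks 20-40, left eyebrow to
left eye) and ``rd1`` (landmarks 25-43, right side), using a 0-based
68-point landmark scheme.  Perfectly synchronized left/right movement gives
coherence 1; asynchrony or independent motion pulls it toward 0.

The transform is the analytic Morlet CWT (center frequency ``omega0 = 6``)
computed in the Fourier domain with zero padding.  Coherence follows the
standard recipe: the cross-spectrum and the two auto-spectra, each divided
by scale, are smoothed in time by a scale-matched Gaussian and across
scales by a boxcar spanning 0.6 of a scale decorrelation length; coherence
is |smoothed cross|^2 over the product of smoothed auto-spectra, clipped to
[0, 1].  The cone of influence marks the region free of edge effects
(e-folding time sqrt(2)*scale from either end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyMask, LengthMismatch, MissingLandmarks, TooShort
from .openface_io import ClipTimeSeries

OMEGA0 = 6.0
#: Landmark index pairs (eyebrow, eye) for the left and right signals, 0-based.
LEFT_PAIR = (20, 40)
RIGHT_PAIR = (25, 43)

_COHERENCE_OVERSHOOT_TOL = 1e-6


@dataclass(frozen=True)
class DistancePair:
    """Per-frame left/right eyebrow-eye Euclidean distances (pixels)."""

    ld1: np.ndarray
    rd1: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        if len(self.ld1) != len(self.rd1):
            raise LengthMismatch("ld1 and rd1 must have equal lengths")


@dataclass(frozen=True)
class CoherenceMap:
    """Magnitude-squared wavelet coherence over (scale x time)."""

    coherence: np.ndarray  # (n_scales, n_times), in [0, 1]
    phase: np.ndarray  # relative phase, radians
    scales: np.ndarray  # seconds
    times: np.ndarray  # seconds
    coi_mask: np.ndarray  # True where inside the cone of influence

    @property
    def mean_coherence(self) -> float:
        return mean_coherence(self)


def _interpolate_gaps(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN runs (the CWT needs gap-free input)."""
    x = np.asarray(x, dtype=float).copy()
    bad = ~np.isfinite(x)
    if bad.any():
        if bad.all():
            raise ValueError("signal contains no finite values")
        idx = np.arange(len(x))
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x


def distance_signals(clip: ClipTimeSeries, left_pair=LEFT_PAIR, right_pair=RIGHT_PAIR) -> DistancePair:
    """Per-frame Euclidean distances for the left and right landmark pairs."""
    try:
        la = clip.landmark_xy(left_pair[0])
        lb = clip.landmark_xy(left_pair[1])
        ra = clip.landmark_xy(right_pair[0])
        rb = clip.landmark_xy(right_pair[1])
    except KeyError as exc:
        raise MissingLandmarks(f"clip lacks landmark columns: {exc}") from exc
    ld1 = np.hypot(*(la - lb).T)
    rd1 = np.hypot(*(ra - rb).T)
    return DistancePair(ld1=ld1, rd1=rd1, frame_rate=clip.frame_rate)


def morlet_scales(n: int, dt: float, dj: float = 1.0 / 12.0) -> np.ndarray:
    """Dyadic scale grid: ``dj`` voices per octave from 2*dt up to n*dt/4."""
    s0 = 2.0 * dt
    s_max = n * dt / 4.0
    n_scales = int(np.floor(np.log2(s_max / s0) / dj)) + 1
    return s0 * 2.0 ** (dj * np.arange(max(n_scales, 1)))


def cwt_morlet(x: np.ndarray, dt: float, scales: np.ndarray, omega0: float = OMEGA0) -> np.ndarray:
    """Analytic Morlet continuous wavelet transform, shape (n_scales, n)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    x = x - x.mean()
    npad = int(2 ** np.ceil(np.log2(max(n, 2))))
    xhat = np.fft.fft(x, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    W = np.empty((len(scales), n), dtype=complex)
    norm_base = np.pi ** (-0.25)
    for i, s in enumerate(scales):
        psi_hat = norm_base * np.sqrt(2.0 * np.pi * s / dt) * np.exp(
            -0.5 * (s * omega - omega0) ** 2
        )
        psi_hat[omega <= 0] = 0.0
        W[i] = np.fft.ifft(xhat * psi_hat)[:n]
    return W


def _smooth_time(spectrum: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Per-scale Gaussian time smoothing with std equal to the scale."""
    n = spectrum.shape[1]
    npad = int(2 ** np.ceil(np.log2(max(n, 2))))
    omega = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    out = np.empty(spectrum.shape, dtype=complex)
    for i, s in enumerate(scales):
        kernel = np.exp(-0.5 * (s * omega) ** 2)
        out[i] = np.fft.ifft(np.fft.fft(spectrum[i], npad) * kernel)[:n]
    return out.real if np.isrealobj(spectrum) else out


def _smooth_scale(spectrum: np.ndarray, dj: float, dj0: float = 0.6) -> np.ndarray:
    """Boxcar smoothing across scales spanning ``dj0`` decorrelation lengths."""
    width = max(int(round(dj0 / dj)), 1)
    if width <= 1 or spectrum.shape[0] == 1:
        return spectrum.copy()
    kernel = np.ones(width) / width
    out = np.empty_like(spectrum)
    # normalize by the actually-overlapping kernel mass at the scale edges
    ones = np.convolve(np.ones(spectrum.shape[0]), kernel, mode="same")
    for j in range(spectrum.shape[1]):
        out[:, j] = np.convolve(spectrum[:, j], kernel, mode="same") / ones
    return out


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    dj: float = 1.0 / 12.0,
    omega0: float = OMEGA0,
) -> CoherenceMap:
    """Magnitude-squared wavelet coherence of two equal-length series."""
    x = _interpolate_gaps(x)
    y = _interpolate_gaps(y)
    if len(x) != len(y):
        raise LengthMismatch(f"series lengths differ: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 64:
        raise TooShort(f"need at least 64 samples, got {n}")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    scales = morlet_scales(n, dt, dj)
    Wx = cwt_morlet(x, dt, scales, omega0)
    Wy = cwt_morlet(y, dt, scales, omega0)
    inv_s = 1.0 / scales[:, None]

    def smooth(spec: np.ndarray) -> np.ndarray:
        return _smooth_scale(_smooth_time(spec, scales, dt), dj)

    s_xy = smooth(Wx * np.conj(Wy) * inv_s)
    s_xx = smooth(np.abs(Wx) ** 2 * inv_s)
    s_yy = smooth(np.abs(Wy) ** 2 * inv_s)
    denom = s_xx * s_yy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(s_xy) ** 2 / denom
    coh[~np.isfinite(coh)] = 0.0
    overshoot = coh.max(initial=0.0) - 1.0
    if overshoot > _COHERENCE_OVERSHOOT_TOL:
        # larger overshoot indicates a smoothing bug, not numerical noise
        raise AssertionError(f"coherence exceeds 1 by {overshoot:.2e}")
    coh = np.clip(coh, 0.0, 1.0)
    phase = np.angle(s_xy)

    times = np.arange(n) * dt
    edge_dist = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi_mask = np.sqrt(2.0) * scales[:, None] <= edge_dist[None, :]
    return CoherenceMap(coherence=coh, phase=phase, scales=scales, times=times, coi_mask=coi_mask)


def mean_coherence(cmap: CoherenceMap) -> float:
    """Arithmetic mean of coherence over in-cone entries."""
    if not cmap.coi_mask.any():
        raise EmptyMask("no entries inside the cone of influence")
    return float(cmap.coherence[cmap.coi_mask].mean())


def clip_mean_coherence(clip: ClipTimeSeries, **kwargs) -> float:
    """Per-clip symmetry summary: mean in-cone coherence of ld1 vs rd1."""
    pair = distance_signals(clip)
    cmap = wavelet_coherence(pair.ld1, pair.rd1, dt=1.0 / clip.frame_rate, **kwargs)
    return mean_coherence(cmap)
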