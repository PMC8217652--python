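"""Synthetic OpenFace-format cohorts with controllable group structure.

The generator emulates the statistical shape the downstream analysis
assumes, without any claim of visual realism:

* one truth clip and one lie clip per participant, with strongly unequal
  mean durations (defaults 105.5 s vs 7.8 s at 30 f/s);
* sparse AU episodes with a linear rise to a peak and a linear decay, the
  decay drawn from a group-specific gamma distribution (defaults centered
  on 11.35 frames for truth and 6.98 for lie);
* left/right eyebrow-eye distance signals with a group-specific lag and
  independent-noise mixing weight, embedded exactly into landmarks 20/40
  and 25/43 so the symmetry module reconstructs them.

Everything is reproducible from the spec seed.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidSpec, OutOfBounds
from .openface_io import (
    FEAR_AUS,
    LIE,
    N_LANDMARKS,
    TRUTH,
    ClipTimeSeries,
    write_frame_table,
    write_manifest,
)


@dataclass(frozen=True)
class GammaParams:
    """Gamma distribution parameterized by mean and shape (k)."""

    mean: float
    shape: float = 4.0

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.mean / self.shape, size=size)


@dataclass
class CohortSpec:
    n_participants: int = 16
    truth_clip_seconds: float = 105.5
    lie_clip_seconds: float = 7.8
    frame_rate: float = 30.0
    episode_rate: float = 24.0  # episodes per minute per AU
    rise_frames: GammaParams = field(default_factory=lambda: GammaParams(9.42))
    decay_frames_truth: GammaParams = field(default_factory=lambda: GammaParams(11.35))
    decay_frames_lie: GammaParams = field(default_factory=lambda: GammaParams(6.98))
    peak_intensity_low: float = 0.5
    peak_intensity_high: float = 4.5
    asym_lag_truth: float = 0.0  # mean left-right lag, frames
    asym_lag_lie: float = 3.0
    asym_noise_truth: float = 0.2  # independent-noise mixing weight
    asym_noise_lie: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise InvalidSpec("n_participants must be >= 1")
        for name in ("truth_clip_seconds", "lie_clip_seconds", "frame_rate", "episode_rate"):
            if getattr(self, name) <= 0:
                raise InvalidSpec(f"{name} must be > 0")
        for name in ("rise_frames", "decay_frames_truth", "decay_frames_lie"):
            p = getattr(self, name)
            if p.mean <= 0 or p.shape <= 0:
                raise InvalidSpec(f"{name} must have positive mean and shape")
        for name in ("asym_noise_truth", "asym_noise_lie"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidSpec(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.peak_intensity_low <= self.peak_intensity_high <= 5.0:
            raise InvalidSpec("peak intensity range must lie within [0, 5]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("rise_frames", "decay_frames_truth", "decay_frames_lie"):
            if key in d and isinstance(d[key], dict):
                d[key] = GammaParams(**d[key])
        return cls(**d)


def inject_episode(
    intensity: np.ndarray,
    presence: np.ndarray,
    onset: int,
    rise: int,
    decay: int,
    peak: float,
) -> None:
    """Write one AU episode into intensity/presence channels, in place.

    Presence is 1 exactly on ``[onset, onset + rise + decay - 1]``.
    Intensity climbs linearly over ``rise`` frames to ``peak`` (reached on
    the last rise frame) then falls linearly over ``decay`` frames, staying
    strictly positive on every presence frame.
    """
    if rise < 1 or decay < 1 or peak <= 0:
        raise ValueError("rise, decay must be >= 1 and peak > 0")
    length = rise + decay
    if onset < 0 or onset + length > len(intensity):
        raise OutOfBounds(
            f"episode [{onset}, {onset + length}) does not fit in series of length {len(intensity)}"
        )
    ramp_up = peak * np.arange(1, rise + 1) / rise
    ramp_down = peak * (1.0 - np.arange(1, decay + 1) / (decay + 1))
    intensity[onset : onset + length] = np.concatenate([ramp_up, ramp_down])
    presence[onset : onset + length] = 1


def _smooth_noise(n: int, rng: np.random.Generator, sigma_frames: float = 6.0) -> np.ndarray:
    """Unit-variance low-pass Gaussian noise (smooth pseudo-motion)."""
    raw = rng.standard_normal(n + 8 * int(sigma_frames))
    t = np.arange(-4 * sigma_frames, 4 * sigma_frames + 1)
    kernel = np.exp(-0.5 * (t / sigma_frames) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")[4 * int(sigma_frames) : 4 * int(sigma_frames) + n]
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_distance_signals(
    n_frames: int,
    lag: int = 0,
    noise_weight: float = 0.0,
    seed: int | None = None,
    baseline: float = 30.0,
    amplitude: float = 4.0,
    smoothness: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Coupled left/right distance series with a lag and noise mixing.

    The right series is the left series delayed by ``lag`` frames
    (circularly), mixed with an independent smooth-noise series at weight
    ``noise_weight`` (0 = identical up to lag, 1 = independent), then both
    are shifted/scaled into strictly positive pixel distances.
    """
    if n_frames <= 64:
        raise InvalidSpec("n_frames must be > 64")
    if not 0.0 <= noise_weight <= 1.0:
        raise InvalidSpec("noise_weight must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = _smooth_noise(n_frames, rng, smoothness)
    indep = _smooth_noise(n_frames, rng, smoothness)
    right_raw = (1.0 - noise_weight) * np.roll(base, int(lag)) + noise_weight * indep
    left = baseline + amplitude * base
    right = baseline + amplitude * right_raw
    return np.maximum(left, 0.1), np.maximum(right, 0.1)


def _template_face(rng: np.random.Generator, n_frames: int) -> tuple[np.ndarray, np.ndarray]:
    """Static ellipse-ish 68-point template plus small per-frame jitter."""
    theta = np.linspace(0.0, 2.0 * np.pi, N_LANDMARKS, endpoint=False)
    base_x = 250.0 + 100.0 * np.cos(theta)
    base_y = 250.0 + 130.0 * np.sin(theta)
    jitter = rng.normal(0.0, 0.1, size=(n_frames, N_LANDMARKS, 2))
    xs = base_x[None, :] + jitter[:, :, 0]
    ys = base_y[None, :] + jitter[:, :, 1]
    return xs, ys


def _embed_distances(xs, ys, ld1, rd1) -> None:
    """Place the four signal landmarks so eyebrow-eye distances equal ld1/rd1."""
    xs[:, 40], ys[:, 40] = 150.0, 200.0
    xs[:, 20], ys[:, 20] = 150.0, 200.0 - ld1
    xs[:, 43], ys[:, 43] = 350.0, 200.0
    xs[:, 25], ys[:, 25] = 350.0, 200.0 - rd1


def _place_episodes(
    n_frames: int,
    rate_per_min: float,
    frame_rate: float,
    rise_dist: GammaParams,
    decay_dist: GammaParams,
    peak_range: tuple[float, float],
    rng: np.random.Generator,
    max_tries: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """One AU channel: Poisson episode count, uniform non-overlapping placement."""
    intensity = np.zeros(n_frames)
    presence = np.zeros(n_frames, dtype=int)
    occupied = np.zeros(n_frames, dtype=bool)
    minutes = n_frames / frame_rate / 60.0
    n_episodes = rng.poisson(rate_per_min * minutes)
    for _ in range(n_episodes):
        rise = max(1, int(round(rise_dist.sample(rng))))
        decay = max(1, int(round(decay_dist.sample(rng))))
        length = rise + decay
        if length + 2 > n_frames:
            continue
        for _try in range(max_tries):
            onset = int(rng.integers(1, n_frames - length))
            # keep one clear frame on each side so adjacent runs never merge
            if not occupied[onset - 1 : onset + length + 1].any():
                peak = float(rng.uniform(*peak_range))
                inject_episode(intensity, presence, onset, rise, decay, peak)
                occupied[onset - 1 : onset + length + 1] = True
                break
    return np.clip(intensity, 0.0, 5.0), presence


def generate_clip(
    participant_id: str,
    condition: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> ClipTimeSeries:
    """One synthetic clip for a participant under one condition."""
    mean_seconds = spec.truth_clip_seconds if condition == TRUTH else spec.lie_clip_seconds
    n_frames = int(round(GammaParams(mean_seconds * spec.frame_rate, 8.0).sample(rng)))
    n_frames = max(n_frames, 70)  # symmetry analysis needs > 64 frames

    decay_dist = spec.decay_frames_truth if condition == TRUTH else spec.decay_frames_lie
    lag_mean = spec.asym_lag_truth if condition == TRUTH else spec.asym_lag_lie
    noise_w = spec.asym_noise_truth if condition == TRUTH else spec.asym_noise_lie

    xs, ys = _template_face(rng, n_frames)
    lag = int(round(rng.normal(lag_mean, 1.0)))
    ld1, rd1 = generate_distance_signals(
        n_frames, lag=lag, noise_weight=noise_w, seed=int(rng.integers(0, 2**31))
    )
    _embed_distances(xs, ys, ld1, rd1)

    data = {
        "frame": np.arange(1, n_frames + 1),
        "timestamp": np.arange(n_frames) / spec.frame_rate,
        "confidence": np.full(n_frames, 0.98),
        "success": np.ones(n_frames, dtype=int),
    }
    for i in range(N_LANDMARKS):
        data[f"x_{i}"] = xs[:, i]
    for i in range(N_LANDMARKS):
        data[f"y_{i}"] = ys[:, i]
    for au in FEAR_AUS:
        intensity, presence = _place_episodes(
            n_frames,
            spec.episode_rate,
            spec.frame_rate,
            spec.rise_frames,
            decay_dist,
            (spec.peak_intensity_low, spec.peak_intensity_high),
            rng,
        )
        data[f"{au}_r"] = intensity
        data[f"{au}_c"] = presence
    return ClipTimeSeries(
        participant_id=participant_id,
        condition=condition,
        frame_rate=spec.frame_rate,
        frames=pd.DataFrame(data),
    )


def generate_cohort(spec: CohortSpec) -> list[tuple[ClipTimeSeries, str]]:
    """Full cohort: one (truth, lie) clip pair per participant.

    Returns ``(clip, label)`` pairs where the label equals the condition.
    Bit-identical across calls with the same spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for p in range(1, spec.n_participants + 1):
        pid = f"P{p:02d}"
        for condition in (TRUTH, LIE):
            clip = generate_clip(pid, condition, spec, rng)
            cohort.append((clip, condition))
    return cohort


def write_cohort(cohort: list[tuple[ClipTimeSeries, str]], out_dir) -> str:
    """Write every clip as OpenFace-dialect CSV plus a manifest; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for clip, _label in cohort:
        name = f"{clip.participant_id}_{clip.condition}.csv"
        write_frame_table(clip, os.path.join(out_dir, name))
        rows.append(
            {
                "path": name,
                "participant_id": clip.participant_id,
                "condition": clip.condition,
                "frame_rate": clip.frame_rate,
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    write_manifest(rows, manifest)
    return manifest
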