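"""Segment AU activations into episodes and summarize their durations.

An episode is a maximal run of frames with score > 0.  Its apex is the
frame of maximum score (earliest on ties).  Phase durations follow the only
additive convention: onset-to-apex counts frames [onset..apex] inclusive,
apex-to-offset counts (apex..offset], so the two phases sum to the total.

Durations convert to milliseconds as frames / frame_rate * 1000; the
micro/macro expression thresholds (200 ms / 500 ms) convert to frame counts
by flooring, giving 6 and 15 frames at 30 f/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyEpisodeList, NonPositiveRate


@dataclass(frozen=True)
class AUEpisode:
    """One contiguous activation of an AU (frame positions are 0-based)."""

    au_id: str
    onset_frame: int
    apex_frame: int
    offset_frame: int
    peak_score: float

    def __post_init__(self) -> None:
        if not self.onset_frame <= self.apex_frame <= self.offset_frame:
            raise ValueError("need onset <= apex <= offset")
        if self.peak_score <= 0:
            raise ValueError("peak_score must be > 0")

    @property
    def total_frames(self) -> int:
        return self.offset_frame - self.onset_frame + 1

    @property
    def onset_to_apex_frames(self) -> int:
        return self.apex_frame - self.onset_frame + 1

    @property
    def apex_to_offset_frames(self) -> int:
        return self.offset_frame - self.apex_frame


@dataclass(frozen=True)
class DurationSummary:
    n_episodes: int
    mean_total_frames: float
    median_total_frames: float
    ci_low_frames: float
    ci_high_frames: float
    mean_apex_to_offset_frames: float
    n_micro: int  # episodes with total duration <= micro threshold
    n_macro: int  # episodes with total duration <= macro threshold
    micro_threshold_frames: int
    macro_threshold_frames: int


def segment_episodes(scores: np.ndarray, au_id: str = "AU20") -> list[AUEpisode]:
    """Maximal runs of score > 0, with apex at the earliest maximum.

    Returns an empty list for an all-zero series.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if np.any(scores < 0):
        raise ValueError("scores must be non-negative")
    active = scores > 0
    if not active.any():
        return []
    edges = np.diff(active.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1)
    if active[0]:
        onsets = np.concatenate([[0], onsets])
    if active[-1]:
        offsets = np.concatenate([offsets, [len(scores) - 1]])
    episodes = []
    for on, off in zip(onsets, offsets):
        run = scores[on : off + 1]
        apex = on + int(np.argmax(run))  # argmax takes the earliest tie
        episodes.append(
            AUEpisode(
                au_id=au_id,
                onset_frame=int(on),
                apex_frame=apex,
                offset_frame=int(off),
                peak_score=float(run.max()),
            )
        )
    return episodes


def frames_to_ms(frames: float, frame_rate: float) -> float:
    """Convert a frame count (possibly fractional) to milliseconds.

    Rounding to integer milliseconds is left to report time.
    """
    if frame_rate <= 0:
        raise NonPositiveRate(f"frame_rate must be > 0, got {frame_rate}")
    return frames / frame_rate * 1000.0


def ms_to_frames(ms: float, frame_rate: float) -> int:
    """Threshold conversion: floor(ms * rate / 1000); 200 ms @ 30 f/s -> 6."""
    if frame_rate <= 0:
        raise NonPositiveRate(f"frame_rate must be > 0, got {frame_rate}")
    return math.floor(ms * frame_rate / 1000.0)


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of ``values``."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot_means = values[idx].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(boot_means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def duration_summary(
    episodes: list[AUEpisode],
    frame_rate: float = 30.0,
    micro_ms: float = 200.0,
    macro_ms: float = 500.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> DurationSummary:
    """Summary statistics of episode total durations with micro/macro counts."""
    if not episodes:
        raise EmptyEpisodeList("duration summary needs at least one episode")
    totals = np.array([e.total_frames for e in episodes], dtype=float)
    decays = np.array([e.apex_to_offset_frames for e in episodes], dtype=float)
    micro_f = ms_to_frames(micro_ms, frame_rate)
    macro_f = ms_to_frames(macro_ms, frame_rate)
    lo, hi = bootstrap_mean_ci(totals, n_boot=n_boot, seed=seed)
    return DurationSummary(
        n_episodes=len(episodes),
        mean_total_frames=float(totals.mean()),
        median_total_frames=float(np.median(totals)),
        ci_low_frames=lo,
        ci_high_frames=hi,
        mean_apex_to_offset_frames=float(decays.mean()),
        n_micro=int((totals <= micro_f).sum()),
        n_macro=int((totals <= macro_f).sum()),
        micro_threshold_frames=micro_f,
        macro_threshold_frames=macro_f,
    )


def episodes_to_frame(
    episodes: list[AUEpisode],
    participant_id: str,
    condition: str,
    frame_rate: float = 30.0,
) -> pd.DataFrame:
    """Tidy episode table (one row per episode, durations in frames and ms)."""
    rows = [
        {
            "participant_id": participant_id,
            "condition": condition,
            "au": e.au_id,
            "onset": e.onset_frame,
            "apex": e.apex_frame,
            "offset": e.offset_frame,
            "total_frames": e.total_frames,
            "rise": e.onset_to_apex_frames,
            "decay": e.apex_to_offset_frames,
            "total_ms": frames_to_ms(e.total_frames, frame_rate),
        }
        for e in episodes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "condition",
            "au",
            "onset",
            "apex",
            "offset",
            "total_frames",
            "rise",
            "decay",
            "total_ms",
        ],
    )
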