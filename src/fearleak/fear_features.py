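"""Per-frame fear-AU scores and per-clip AU summaries.

The per-frame score of an AU is its presence flag multiplied by its
intensity, so an AU scores 0 whenever it is absent and at most its
intensity otherwise.  Clip summaries average these scores over all frames,
yielding one value per AU per participant per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyClip, MissingChannel, OutOfRange
from .openface_io import FEAR_AUS, ClipTimeSeries, FrameRecord

#: The six-AU variant (no AU07) used by some consumers; configurable.
SIX_AUS: tuple[str, ...] = ("AU01", "AU02", "AU04", "AU05", "AU20", "AU26")


@dataclass(frozen=True)
class FearVector:
    """Ordered per-frame scores for the seven fear AUs."""

    values: tuple[float, ...]
    aus: tuple[str, ...] = FEAR_AUS

    def __post_init__(self) -> None:
        if len(self.values) != len(self.aus):
            raise ValueError("one value per AU required")


@dataclass(frozen=True)
class ClipAUSummary:
    """Mean per-frame AU score for one clip, one entry per AU."""

    participant_id: str
    condition: str
    mean_score: dict[str, float]


def fear_score(presence: float, intensity: float) -> float:
    """Presence-gated intensity: ``presence * intensity``.

    ``presence`` must be 0 or 1 and ``intensity`` within [0, 5].
    """
    if presence not in (0, 1):
        raise OutOfRange(f"presence must be 0 or 1, got {presence!r}")
    if not 0.0 <= intensity <= 5.0:
        raise OutOfRange(f"intensity must be in [0, 5], got {intensity!r}")
    return presence * intensity


def frame_feature_vector(record: FrameRecord, aus: Sequence[str] = FEAR_AUS) -> FearVector:
    """Fear-score vector for one frame, in canonical AU order."""
    missing = [au for au in aus if au not in record.au_intensity or au not in record.au_presence]
    if missing:
        raise MissingChannel(f"record lacks AU channel(s): {', '.join(missing)}")
    return FearVector(
        values=tuple(fear_score(record.au_presence[au], record.au_intensity[au]) for au in aus),
        aus=tuple(aus),
    )


def clip_mean_aus(
    clip: ClipTimeSeries, aus: Sequence[str] = FEAR_AUS, drop_failed: bool = False
) -> ClipAUSummary:
    """Arithmetic mean of per-frame fear scores over all frames of a clip.

    With ``drop_failed=True``, frames whose detector success flag is 0 are
    excluded before averaging (off by default; the upstream analysis does
    not document such a filter).
    """
    frames = clip.frames
    if drop_failed:
        frames = frames[frames["success"] != 0]
    if len(frames) == 0:
        raise EmptyClip("cannot average AU scores over zero frames")
    means = {}
    for au in aus:
        score = frames[f"{au}_r"].to_numpy(dtype=float) * frames[f"{au}_c"].to_numpy(dtype=float)
        means[au] = float(score.mean())
    return ClipAUSummary(clip.participant_id, clip.condition, means)


def clip_feature_matrix(clip: ClipTimeSeries, aus: Sequence[str] = FEAR_AUS) -> np.ndarray:
    """Frame-by-AU score matrix for a whole clip, shape (n_frames, n_aus)."""
    return np.column_stack([clip.au_score(au) for au in aus])


def summaries_to_frame(summaries: Sequence[ClipAUSummary]) -> pd.DataFrame:
    """Tidy long-format table: participant, condition, au, mean."""
    rows = [
        {"participant_id": s.participant_id, "condition": s.condition, "au": au, "mean": m}
        for s in summaries
        for au, m in s.mean_score.items()
    ]
    return pd.DataFrame(rows, columns=["participant_id", "condition", "au", "mean"])
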