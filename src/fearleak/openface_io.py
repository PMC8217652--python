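"""Read, write and merge per-frame facial-feature tables (OpenFace 2.x CSV dialect).

The dialect is a comma-separated table with a header row whose names may be
padded with spaces (``frame, timestamp, ... AU01_r``).  Each data row holds a
1-based frame index, a timestamp in seconds, a detection success flag and
confidence, 68 two-dimensional landmark coordinates ``x_0..x_67`` /
``y_0..y_67``, AU intensities ``AUxx_r`` in [0, 5] and AU presences
``AUxx_c`` in {0, 1}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyTable, MalformedRow, MissingColumn, MixedIdentity

#: The seven fear-related action units, in canonical order.
FEAR_AUS: tuple[str, ...] = ("AU01", "AU02", "AU04", "AU05", "AU07", "AU20", "AU26")

N_LANDMARKS = 68

TRUTH = "truth"
LIE = "lie"


def landmark_columns() -> list[str]:
    """Column names for the 68 landmark pairs, x block then y block."""
    return [f"x_{i}" for i in range(N_LANDMARKS)] + [f"y_{i}" for i in range(N_LANDMARKS)]


def au_columns(aus: Sequence[str] = FEAR_AUS) -> list[str]:
    """Intensity and presence column names for the given AU ids."""
    return [f"{au}_r" for au in aus] + [f"{au}_c" for au in aus]


def required_columns() -> list[str]:
    return ["frame", "timestamp", "confidence", "success"] + landmark_columns() + au_columns()


@dataclass(frozen=True)
class FrameRecord:
    """One video frame: landmarks plus AU presence/intensity channels."""

    frame_index: int
    timestamp: float
    success: int
    confidence: float
    landmarks: np.ndarray  # shape (68, 2)
    au_intensity: dict[str, float]
    au_presence: dict[str, int]


@dataclass
class ClipTimeSeries:
    """Ordered per-frame records for one participant under one condition.

    Frames are stored columnar in :attr:`frames` (a DataFrame in the reader's
    standardized column layout); :attr:`records` materializes row-wise
    :class:`FrameRecord` views for convenience at small scale.
    """

    participant_id: str
    condition: str
    frame_rate: float
    frames: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.condition not in (TRUTH, LIE):
            raise ValueError(f"condition must be '{TRUTH}' or '{LIE}', got {self.condition!r}")
        idx = self.frames["frame"].to_numpy()
        if len(idx) and not np.all(np.diff(idx) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def landmark_xy(self, index: int) -> np.ndarray:
        """Per-frame (x, y) coordinates of one landmark, shape (n_frames, 2)."""
        return self.frames[[f"x_{index}", f"y_{index}"]].to_numpy(dtype=float)

    def au_score(self, au: str) -> np.ndarray:
        """Presence-gated intensity series for one AU (see fear_features)."""
        r = self.frames[f"{au}_r"].to_numpy(dtype=float)
        c = self.frames[f"{au}_c"].to_numpy(dtype=float)
        return r * c

    @property
    def records(self) -> list[FrameRecord]:
        return list(self.iter_records())

    def iter_records(self) -> Iterator[FrameRecord]:
        lm_cols = landmark_columns()
        xs = self.frames[lm_cols[:N_LANDMARKS]].to_numpy(dtype=float)
        ys = self.frames[lm_cols[N_LANDMARKS:]].to_numpy(dtype=float)
        intensities = {au: self.frames[f"{au}_r"].to_numpy(dtype=float) for au in FEAR_AUS}
        presences = {au: self.frames[f"{au}_c"].to_numpy(dtype=int) for au in FEAR_AUS}
        meta = self.frames[["frame", "timestamp", "success", "confidence"]].to_numpy(dtype=float)
        for i in range(len(self.frames)):
            yield FrameRecord(
                frame_index=int(meta[i, 0]),
                timestamp=float(meta[i, 1]),
                success=int(meta[i, 2]),
                confidence=float(meta[i, 3]),
                landmarks=np.column_stack([xs[i], ys[i]]),
                au_intensity={au: float(intensities[au][i]) for au in FEAR_AUS},
                au_presence={au: int(presences[au][i]) for au in FEAR_AUS},
            )


def read_frame_table(
    source,
    participant_id: str,
    condition: str,
    frame_rate: float = 30.0,
    drop_failed: bool = False,
) -> ClipTimeSeries:
    """Parse an OpenFace-dialect CSV into a :class:`ClipTimeSeries`.

    Header names are matched after stripping surrounding whitespace (the
    upstream tool pads them).  Extra columns are ignored; missing required
    columns raise :class:`MissingColumn`; non-numeric cells raise
    :class:`MalformedRow`; a data-free table raises :class:`EmptyTable`.

    ``drop_failed=True`` removes frames with ``success == 0`` (the source
    study does not document such a filter, so the default retains them).
    """
    df = pd.read_csv(source, skipinitialspace=True, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required_columns() if c not in df.columns]
    if missing:
        raise MissingColumn(f"missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise EmptyTable("frame table has a header but no data rows")
    df = df[required_columns()]
    try:
        df = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise MalformedRow(f"non-numeric cell in frame table: {exc}") from exc
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise MalformedRow(f"empty/NaN cells in column(s): {', '.join(bad)}")
    if drop_failed:
        df = df[df["success"] != 0].reset_index(drop=True)
        if len(df) == 0:
            raise EmptyTable("no frames left after dropping success=0 rows")
    return ClipTimeSeries(
        participant_id=participant_id,
        condition=condition,
        frame_rate=frame_rate,
        frames=df.reset_index(drop=True),
    )


def write_frame_table(clip: ClipTimeSeries, destination) -> None:
    """Write a clip back to the OpenFace CSV dialect.

    Numeric content round-trips through :func:`read_frame_table` at full
    ``repr`` precision.
    """
    clip.frames[required_columns()].to_csv(destination, index=False)


def merge_clips(clips: Sequence[ClipTimeSeries]) -> ClipTimeSeries:
    """Concatenate same-identity clips, renumbering frames from 1.

    Timestamps are recomputed from the frame rate so the merged clip has a
    single consistent clock.
    """
    if not clips:
        raise ValueError("need at least one clip")
    head = clips[0]
    for c in clips[1:]:
        if (
            c.participant_id != head.participant_id
            or c.condition != head.condition
            or c.frame_rate != head.frame_rate
        ):
            raise MixedIdentity(
                "cannot merge clips with differing participant, condition or frame rate"
            )
    frames = pd.concat([c.frames for c in clips], ignore_index=True)
    n = len(frames)
    frames["frame"] = np.arange(1, n + 1)
    frames["timestamp"] = (frames["frame"] - 1) / head.frame_rate
    return ClipTimeSeries(head.participant_id, head.condition, head.frame_rate, frames)


# --- manifest ----------------------------------------------------------


def write_manifest(rows: Iterable[dict], destination) -> None:
    """Write a clip manifest: one row per clip (path, participant_id, condition, frame_rate)."""
    pd.DataFrame(list(rows), columns=["path", "participant_id", "condition", "frame_rate"]).to_csv(
        destination, index=False
    )


def load_cohort(manifest_path, drop_failed: bool = False) -> list[ClipTimeSeries]:
    """Load every clip listed in a manifest file (paths relative to the manifest)."""
    manifest = pd.read_csv(manifest_path, skipinitialspace=True)
    base = os.path.dirname(os.fspath(manifest_path))
    clips = []
    for row in manifest.itertuples(index=False):
        path = row.path if os.path.isabs(row.path) else os.path.join(base, row.path)
        clips.append(
            read_frame_table(
                path,
                participant_id=str(row.participant_id),
                condition=str(row.condition),
                frame_rate=float(row.frame_rate),
                drop_failed=drop_failed,
            )
        )
    return clips
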