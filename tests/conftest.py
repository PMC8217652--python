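import numpy as np
import pandas as pd
import pytest

from fearleak.openface_io import FEAR_AUS, N_LANDMARKS, ClipTimeSeries, required_columns


def build_frames(
    n_frames: int,
    au_intensity: dict[str, np.ndarray] | None = None,
    au_presence: dict[str, np.ndarray] | None = None,
    landmarks: np.ndarray | None = None,
    frame_rate: float = 30.0,
    success: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble a standardized frame table with sensible defaults."""
    data = {
        "frame": np.arange(1, n_frames + 1),
        "timestamp": np.arange(n_frames) / frame_rate,
        "confidence": np.full(n_frames, 0.95),
        "success": np.ones(n_frames, dtype=int) if success is None else success,
    }
    if landmarks is None:
        landmarks = np.tile(np.arange(N_LANDMARKS, dtype=float), (n_frames, 1))
        landmarks = np.stack([landmarks, landmarks + 100.0], axis=2)  # (n, 68, 2)
    for i in range(N_LANDMARKS):
        data[f"x_{i}"] = landmarks[:, i, 0]
    for i in range(N_LANDMARKS):
        data[f"y_{i}"] = landmarks[:, i, 1]
    for au in FEAR_AUS:
        data[f"{au}_r"] = (au_intensity or {}).get(au, np.zeros(n_frames))
        data[f"{au}_c"] = (au_presence or {}).get(au, np.zeros(n_frames, dtype=int))
    return pd.DataFrame(data)[required_columns()]


@pytest.fixture
def make_clip():
    """Factory for small in-memory clips."""

    def _make(
        n_frames: int = 3,
        participant_id: str = "P01",
        condition: str = "truth",
        frame_rate: float = 30.0,
        **kwargs,
    ) -> ClipTimeSeries:
        return ClipTimeSeries(
            participant_id=participant_id,
            condition=condition,
            frame_rate=frame_rate,
            frames=build_frames(n_frames, frame_rate=frame_rate, **kwargs),
        )

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by the slower analysis tests."""
    from fearleak.synthetic_cohort import CohortSpec, generate_cohort

    spec = CohortSpec(
        n_participants=8,
        truth_clip_seconds=40.0,
        lie_clip_seconds=8.0,
        seed=7,
    )
    return generate_cohort(spec)
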