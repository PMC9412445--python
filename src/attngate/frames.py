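"""In-memory containers for band-power frames and raw EEG segments."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, ELECTRODES, FEATURE_COLUMNS, N_BANDS, N_ELECTRODES

FRAME_RATE_HZ = 10.0
FRAME_PERIOD_S = 1.0 / FRAME_RATE_HZ


@dataclass
class FrameStream:
    """A stream of 10 Hz band-power frames.

    ``times`` are frame right-edge timestamps in seconds from session start
    (each frame summarises the half-open window [t-1 s, t)).
    ``powers`` has shape (n_frames, 4 electrodes, 5 bands) and holds
    log10 band power. ``labels`` holds per-frame ground truth in
    {"internal", "external", "none"}.
    """

    times: np.ndarray
    powers: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        self.labels = np.asarray(self.labels, dtype="<U8")
        n = len(self.times)
        if self.powers.shape != (n, N_ELECTRODES, N_BANDS):
            raise ValueError(
                f"powers shape {self.powers.shape} != ({n}, {N_ELECTRODES}, {N_BANDS})"
            )
        if self.labels.shape != (n,):
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def features(self) -> np.ndarray:
        """(n, 20) electrode-major feature matrix."""
        return self.powers.reshape(len(self), -1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(FEATURE_COLUMNS))
        df.insert(0, "timestamp_s", self.times)
        df["label"] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FrameStream":
        missing = [c for c in ("timestamp_s", *FEATURE_COLUMNS) if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
        powers = df[list(FEATURE_COLUMNS)].to_numpy(float).reshape(-1, N_ELECTRODES, N_BANDS)
        labels = (
            df["label"].to_numpy(str)
            if "label" in df.columns
            else np.full(len(df), "none", dtype="<U8")
        )
        return cls(df["timestamp_s"].to_numpy(float), powers, labels)

    def linear_powers(self) -> np.ndarray:
        """Band powers on the linear scale (10**logpower) — export option."""
        return 10.0 ** self.powers


@dataclass
class RawEegSegment:
    """Multichannel time-domain EEG: (n_channels, n_samples) at ``fs`` Hz."""

    data: np.ndarray
    fs: float = 256.0
    channels: tuple[str, ...] = ELECTRODES
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows for {len(self.channels)} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def sample_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.fs
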