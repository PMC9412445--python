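"""Spectral band-power feature extraction from raw 4-channel EEG.

Every 100 ms a 256-sample Hamming-tapered window (the most recent second
at 256 Hz) is Fourier transformed and the periodogram power is summed over
the bins of each of the five canonical bands, giving one 4 electrode x
5 band frame per step and a 20-dimensional feature vector after
electrode-major flattening. Consecutive windows overlap by 90%.

Conventions (all deliberate and mirrored by the synthetic generator):

* frames are scheduled on the 100 ms timestamp grid, so the realised hop
  alternates between 25 and 26 samples at 256 Hz;
* the first second of a recording is zero-padded on the left, so a
  T-second recording yields exactly 10*T frames (400 s -> 4000 vectors);
* the periodogram is window-power normalised (divided by the sum of
  squared taper values); band sums use every FFT bin whose centre
  frequency lies in the closed interval [low, high];
* linear powers below a small floor clamp to the floor before log10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bands import BandDefinition, DEFAULT_BANDS, N_BANDS, N_ELECTRODES
from .frames import FrameStream, RawEegSegment
from .plans import NONE, SessionPlan

__all__ = ["FeatureConfig", "compute_band_powers", "frames_to_features", "label_features"]


@dataclass
class FeatureConfig:
    """Extraction parameters; defaults give the 20-feature, 10 Hz stream."""

    window_samples: int = 256
    frame_rate: float = 10.0
    fs: float = 256.0
    taper: str = "hamming"
    pad_start: bool = True
    log_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise ValueError("window_samples must be >= 2")
        if self.taper not in ("hamming", "boxcar"):
            raise ValueError(f"unsupported taper {self.taper!r}")

    def taper_values(self) -> np.ndarray:
        if self.taper == "hamming":
            return np.hamming(self.window_samples)
        return np.ones(self.window_samples)


def _band_bin_masks(
    cfg: FeatureConfig, bands: tuple[BandDefinition, ...]
) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(cfg.window_samples, d=1.0 / cfg.fs)
    masks = np.stack([(freqs >= b.low) & (freqs <= b.high) for b in bands])
    return freqs, masks


def compute_band_powers(
    raw: RawEegSegment,
    cfg: FeatureConfig | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> FrameStream:
    """Extract the 10 Hz stream of log10 band-power frames from raw EEG.

    Returns a :class:`FrameStream` with unlabelled ("none") frames; use
    :func:`label_features` with a session plan to attach ground truth.
    A recording shorter than one window yields an empty stream with a
    warning; non-finite samples raise, naming the first offending index.
    """
    cfg = cfg or FeatureConfig()
    if raw.data.shape[0] != N_ELECTRODES:
        raise ValueError(f"expected {N_ELECTRODES} channels, got {raw.data.shape[0]}")
    bad = ~np.isfinite(raw.data)
    if bad.any():
        ch, idx = np.argwhere(bad)[0]
        raise ValueError(f"non-finite sample at channel {raw.channels[ch]}, index {idx}")
    n = raw.n_samples
    if n < cfg.window_samples and not cfg.pad_start:
        warnings.warn("signal shorter than one analysis window; returning empty stream")
        return FrameStream(np.empty(0), np.empty((0, N_ELECTRODES, N_BANDS)), np.empty(0, "<U8"))

    duration = n / raw.fs
    n_frames = int(np.floor(duration * cfg.frame_rate + 1e-9))
    if not cfg.pad_start:
        first = int(np.ceil(cfg.window_samples / raw.fs * cfg.frame_rate - 1e-9))
    else:
        first = 1
    ks = np.arange(first, n_frames + 1)
    if len(ks) == 0:
        warnings.warn("signal shorter than one analysis window; returning empty stream")
        return FrameStream(np.empty(0), np.empty((0, N_ELECTRODES, N_BANDS)), np.empty(0, "<U8"))
    times = ks / cfg.frame_rate

    w = cfg.taper_values()
    wnorm = float(np.sum(w**2))
    _, masks = _band_bin_masks(cfg, bands)

    ends = np.round(times * raw.fs).astype(int)
    ends = np.clip(ends, 0, n)
    starts = ends - cfg.window_samples
    # gather windows with left zero-padding where start < 0
    windows = np.zeros((len(ks), N_ELECTRODES, cfg.window_samples))
    for i, (s, e) in enumerate(zip(starts, ends)):
        lo = max(s, 0)
        windows[i, :, lo - s :] = raw.data[:, lo:e]
    spec = np.fft.rfft(windows * w, axis=-1)
    pxx = (spec.real**2 + spec.imag**2) / wnorm
    band_powers = np.einsum("feb,mb->fem", pxx, masks.astype(float))
    band_powers = np.maximum(band_powers, cfg.log_floor)
    labels = np.full(len(ks), NONE, dtype="<U8")
    return FrameStream(raw.start_time + times, np.log10(band_powers), labels)


def frames_to_features(stream: FrameStream) -> tuple[np.ndarray, np.ndarray]:
    """Flatten frames to (times, (n, 20) electrode-major feature matrix)."""
    return stream.times, stream.features


def label_features(
    stream: FrameStream, plan: SessionPlan
) -> tuple[FrameStream, int]:
    """Attach ground-truth labels to frames by the majority-coverage rule.

    Each frame's 1 s analysis window [t-1, t) is labelled by the phase
    covering its majority (ties -> external). Frames with no phase
    coverage are dropped; returns (labelled stream, n_dropped).
    """
    labels = np.array(
        [plan.label_for_window(t - 1.0, t) for t in stream.times], dtype="<U8"
    )
    keep = labels != NONE
    n_dropped = int((~keep).sum())
    out = FrameStream(stream.times[keep], stream.powers[keep], labels[keep])
    return out, n_dropped
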