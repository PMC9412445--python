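"""Synthetic labelled EEG sessions with the structure the classifier assumes.

Internal attention raises posterior alpha power, strongest over the right
temporoparietal site (TP10); the generator encodes that as an additive
log10 band-power shift on internally-attended frames. Two modes exist:

* band-power mode draws 10 Hz log-power frames directly from the normal
  model the linear classifier assumes;
* raw mode synthesises 256 Hz time-domain signal as a sum of band-limited
  Gaussian noise components whose variances hit the same band-power
  targets, exercising the spectral feature extractor end to end.

Stream corruption (missing samples, timestamp jitter, block delay) mimics
the imperfections of a consumer Bluetooth headset stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import child_rng
from .bands import BAND_NAMES, DEFAULT_BANDS, ELECTRODES, N_BANDS, N_ELECTRODES
from .frames import FRAME_RATE_HZ, FrameStream, RawEegSegment
from .plans import INTERNAL, SessionPlan

__all__ = [
    "GeneratorParams",
    "CorruptionParams",
    "synthesize_bandpower",
    "synthesize_raw",
    "corrupt_stream",
    "corrupt_frames",
    "frame_times",
]

# Baseline log10 band power per band (same across electrodes): a 1/f-like
# decay of power with frequency, in log10 units of the streamed absolute
# band-power values.
_BASELINE_BY_BAND = {"delta": 1.0, "theta": 0.7, "alpha": 0.6, "beta": 0.3, "gamma": 0.0}

# Internal-attention alpha shift per electrode, log10 units; largest at
# TP10 (right temporoparietal), smaller at TP9, smallest frontally.
_ALPHA_SHIFT_BY_ELECTRODE = {"TP9": 0.2, "AF7": 0.1, "AF8": 0.1, "TP10": 0.4}


def _default_baseline() -> np.ndarray:
    row = np.array([_BASELINE_BY_BAND[b] for b in BAND_NAMES])
    return np.tile(row, (N_ELECTRODES, 1))


def _default_shift() -> np.ndarray:
    shift = np.zeros((N_ELECTRODES, N_BANDS))
    a = BAND_NAMES.index("alpha")
    for e, v in _ALPHA_SHIFT_BY_ELECTRODE.items():
        shift[ELECTRODES.index(e), a] = v
    return shift


@dataclass
class GeneratorParams:
    """Statistical model of a synthetic session.

    ``baseline`` and ``internal_shift`` are (4 electrodes x 5 bands)
    matrices of log10 band power; a frame labelled internal has mean
    ``baseline + internal_shift``. ``noise_sd`` is the per-frame log-power
    SD. ``band_margin_hz`` narrows each band's raw-signal synthesis
    interval at both edges so leakage stays attributable to its own band.
    """

    baseline: np.ndarray = field(default_factory=_default_baseline)
    internal_shift: np.ndarray = field(default_factory=_default_shift)
    noise_sd: float = 0.25
    fs: float = 256.0
    band_margin_hz: float = 0.5
    crossfade_s: float = 0.05

    def __post_init__(self) -> None:
        self.baseline = np.broadcast_to(
            np.asarray(self.baseline, float), (N_ELECTRODES, N_BANDS)
        ).copy()
        self.internal_shift = np.broadcast_to(
            np.asarray(self.internal_shift, float), (N_ELECTRODES, N_BANDS)
        ).copy()
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        top = max(b.high for b in DEFAULT_BANDS)
        if self.fs <= 2 * top:
            raise ValueError(
                f"sampling rate {self.fs} Hz must exceed twice the top band edge ({top} Hz)"
            )

    @classmethod
    def null(cls, **kw) -> "GeneratorParams":
        """No attention effect: internal and external frames identically distributed."""
        return cls(internal_shift=np.zeros((N_ELECTRODES, N_BANDS)), **kw)

    def with_effect_scale(self, scale: float) -> "GeneratorParams":
        """Copy with the internal shift multiplied by ``scale``."""
        return replace(self, internal_shift=self.internal_shift * scale)

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.tolist(),
            "internal_shift": self.internal_shift.tolist(),
            "noise_sd": self.noise_sd,
            "fs": self.fs,
            "band_margin_hz": self.band_margin_hz,
            "crossfade_s": self.crossfade_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(
            baseline=np.asarray(d["baseline"]),
            internal_shift=np.asarray(d["internal_shift"]),
            noise_sd=float(d["noise_sd"]),
            fs=float(d["fs"]),
            band_margin_hz=float(d.get("band_margin_hz", 0.5)),
            crossfade_s=float(d.get("crossfade_s", 0.05)),
        )


@dataclass
class CorruptionParams:
    """Consumer-headset stream imperfections.

    Defaults follow the reported Muse/Bluetooth behaviour: ~0.01-0.05%
    missing samples and ~5 ms timestamp jitter, plus an optional constant
    block delay (20-40 ms reported).
    """

    missing_rate: float = 0.0003
    jitter_sd_s: float = 0.005
    block_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0, 1], got {self.missing_rate}")
        if self.jitter_sd_s < 0:
            raise ValueError(f"jitter_sd_s must be >= 0, got {self.jitter_sd_s}")


def frame_times(total_duration: float, frame_rate: float = FRAME_RATE_HZ) -> np.ndarray:
    """Right-edge frame timestamps: floor(duration x rate) frames, t = k/rate."""
    n = int(np.floor(total_duration * frame_rate + 1e-9))
    return (np.arange(1, n + 1)) / frame_rate


def _frame_labels(plan: SessionPlan, times: np.ndarray) -> np.ndarray:
    return np.array([plan.label_for_window(t - 1.0, t) for t in times], dtype="<U8")


def synthesize_bandpower(
    plan: SessionPlan,
    params: GeneratorParams | None = None,
    seed: int | None = None,
) -> FrameStream:
    """Draw labelled 10 Hz log-power frames directly from the normal model.

    One frame per 100 ms; each electrode x band log power is normal with
    mean ``baseline`` (+ ``internal_shift`` on internal frames) and SD
    ``noise_sd``. Labels follow the majority-coverage rule of the frame's
    1 s analysis window.
    """
    params = params or GeneratorParams()
    rng = child_rng(plan.seed if seed is None else seed, "signal")
    times = frame_times(plan.total_duration)
    labels = _frame_labels(plan, times)
    n = len(times)
    powers = params.baseline[None] + rng.normal(0.0, params.noise_sd, (n, N_ELECTRODES, N_BANDS))
    powers[labels == INTERNAL] += params.internal_shift[None]
    return FrameStream(times, powers, labels)


_TRANSFER_CACHE: dict[tuple, np.ndarray] = {}


def _bandpower_transfer_matrix(
    fs: float, window_samples: int, margin_hz: float, points_per_hz: int = 40
) -> np.ndarray:
    """Expected extracted band power per unit-variance band component.

    Entry (b, j): the value the window-power-normalised Hamming
    periodogram band-b sum takes, in expectation, for a unit-variance
    noise component flat over band j's synthesis interval. Because the
    canonical band definitions overlap (theta/alpha share 7.5-8 Hz) and
    window leakage crosses shared bin edges, this matrix is not diagonal;
    the generator solves M v = T so the *extracted* powers hit their
    targets exactly in expectation.
    """
    key = (fs, window_samples, margin_hz, points_per_hz)
    if key in _TRANSFER_CACHE:
        return _TRANSFER_CACHE[key]
    w = np.hamming(window_samples)
    wnorm = np.sum(w**2)
    n = np.arange(window_samples)

    def leak(delta: np.ndarray) -> np.ndarray:
        # |DTFT of taper at offset delta Hz|^2 / sum(w^2)
        ph = np.exp(-2j * np.pi * np.outer(delta, n) / fs)
        return np.abs(ph @ w) ** 2 / wnorm

    freqs = np.fft.rfftfreq(window_samples, d=1.0 / fs)
    nb = len(DEFAULT_BANDS)
    m = np.zeros((nb, nb))
    for j, band in enumerate(DEFAULT_BANDS):
        lo, hi = band.low + margin_hz, band.high - margin_hz
        npts = max(int((hi - lo) * points_per_hz), 8) + 1
        f = np.linspace(lo, hi, npts)
        for b, target in enumerate(DEFAULT_BANDS):
            bins = freqs[(freqs >= target.low) & (freqs <= target.high)]
            acc = np.zeros(npts)
            for fk in bins:
                # one-sided component: mirror-frequency term included
                acc += 0.5 * (leak(fk - f) + leak(fk + f))
            m[b, j] = np.trapezoid(acc, f) / (hi - lo)
    _TRANSFER_CACHE[key] = m
    return m


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [low, high] Hz via rfft masking."""
    z = rng.standard_normal(n)
    spec = np.fft.rfft(z)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < low) | (f > high)] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    if sd == 0.0:  # band narrower than one spectral bin
        return y
    return y / sd


def synthesize_raw(
    plan: SessionPlan,
    params: GeneratorParams | None = None,
    seed: int | None = None,
    window_samples: int = 256,
) -> RawEegSegment:
    """Synthesise 4-channel time-domain EEG realising the plan's band powers.

    Each phase segment is a per-channel sum over bands of band-limited
    Gaussian noise (FFT-masked, flat over the band interior). Component
    variances are chosen by inverting the exact expected band-power
    transfer matrix of the downstream Hamming periodogram, so the
    *extracted* band powers equal their log-power targets in expectation
    despite the overlapping band definitions and window leakage.
    Consecutive phases are joined with a short raised-cosine cross-fade
    to avoid boundary discontinuities.
    """
    params = params or GeneratorParams()
    rng = child_rng(plan.seed if seed is None else seed, "signal")
    fs = params.fs
    fade = int(round(params.crossfade_s * fs))
    intervals = plan.phase_intervals()
    lengths = [int(round((end - start) * fs)) for start, end, _ in intervals]
    total = sum(lengths)
    data = np.zeros((N_ELECTRODES, total))
    transfer = _bandpower_transfer_matrix(fs, window_samples, params.band_margin_hz)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, fade + 1) / (fade + 1)))
    pos = 0
    prev_tail: np.ndarray | None = None  # previous phase extended past its boundary
    for i, ((_, _, state), n) in enumerate(zip(intervals, lengths)):
        last = i == len(intervals) - 1
        ext = 0 if last else fade
        target_log = params.baseline + (params.internal_shift if state == INTERNAL else 0.0)
        seg = np.zeros((N_ELECTRODES, n + ext))
        for e in range(N_ELECTRODES):
            variances = np.linalg.solve(transfer, 10.0 ** target_log[e])
            if np.any(variances <= 0):
                warnings.warn("unrealisable band-power targets; clipping variances")
                variances = np.maximum(variances, 1e-12)
            for b, band in enumerate(DEFAULT_BANDS):
                lo = band.low + params.band_margin_hz
                hi = band.high - params.band_margin_hz
                seg[e] += np.sqrt(variances[b]) * _bandlimited_noise(rng, n + ext, fs, lo, hi)
        if prev_tail is not None:
            k = min(len(ramp), prev_tail.shape[1], seg.shape[1])
            seg[:, :k] = prev_tail[:, :k] * (1.0 - ramp[:k]) + seg[:, :k] * ramp[:k]
        data[:, pos : pos + n] = seg[:, :n]
        prev_tail = seg[:, n:] if ext else None
        pos += n
    return RawEegSegment(data=data, fs=fs, channels=ELECTRODES)


def corrupt_stream(
    times: np.ndarray,
    values: np.ndarray,
    params: CorruptionParams,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Apply headset-style corruption to a timestamped stream.

    Samples are dropped independently at ``missing_rate``; surviving
    timestamps get i.i.d. Gaussian jitter of SD ``jitter_sd_s`` plus the
    constant ``block_delay_s``; the stream is re-sorted by perturbed
    timestamp so ordering stays valid. Returns (times, values, n_dropped).
    """
    times = np.asarray(times, float)
    values = np.asarray(values)
    rng = child_rng(seed, "corruption")
    keep = rng.random(len(times)) >= params.missing_rate
    t = times[keep]
    v = values[keep]
    n_dropped = int(len(times) - keep.sum())
    if params.jitter_sd_s > 0:
        t = t + rng.normal(0.0, params.jitter_sd_s, len(t))
    t = t + params.block_delay_s
    order = np.argsort(t, kind="stable")
    return t[order], v[order], n_dropped


def corrupt_frames(
    stream: FrameStream, params: CorruptionParams, seed: int = 0
) -> tuple[FrameStream, int]:
    """Frame-level convenience wrapper around :func:`corrupt_stream`."""
    packed = np.concatenate(
        [stream.features, (stream.labels == INTERNAL)[:, None].astype(float)], axis=1
    )
    t, v, n_dropped = corrupt_stream(stream.times, packed, params, seed)
    labels = np.where(v[:, -1] > 0.5, "internal", "external").astype("<U8")
    # preserve 'none' labels through the packing
    if np.any(stream.labels == "none"):
        warnings.warn("'none' labels degrade to 'external' under corruption packing")
    powers = v[:, :-1].reshape(-1, N_ELECTRODES, N_BANDS)
    return FrameStream(t, powers, labels), n_dropped
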