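"""Streaming pause decisions from the 10 Hz attention prediction stream.

The interface pauses its updates only when sustained internal attention is
evident: at least 60% of the last 40 predictions (4 s at 10 Hz) must be
"internal". The threshold deliberately biases toward *not* pausing, since
a wrongful pause during reading is more disruptive than a missed pause
during thinking. Before the buffer fills, the state is "warming-up" and
recorded as unpaused.

By default the vote is re-evaluated on every new prediction (sliding 4 s
window), which permits pause blocks shorter than 4 s; a disjoint-block
mode (one decision per 4 s, held) is provided for comparison.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .frames import FRAME_PERIOD_S
from .plans import EXTERNAL, INTERNAL

__all__ = ["DeciderConfig", "PauseDecider", "PauseTimeline", "decide_batch"]

PAUSED = "paused"
UNPAUSED = "unpaused"
WARMING_UP = "warming-up"


@dataclass(frozen=True)
class DeciderConfig:
    """Majority-vote parameters: pause iff internal count >= ceil(threshold*n)."""

    n_predictions: int = 40
    internal_threshold: float = 0.60
    mode: str = "sliding"  # or "block"
    max_pause_s: float | None = None  # optional cap, off by default

    def __post_init__(self) -> None:
        if self.n_predictions < 1:
            raise ValueError("n_predictions must be >= 1")
        if not 0.0 < self.internal_threshold <= 1.0:
            raise ValueError("internal_threshold must be in (0, 1]")
        if self.mode not in ("sliding", "block"):
            raise ValueError(f"unknown decider mode {self.mode!r}")

    @property
    def min_internal(self) -> int:
        """Smallest internal count that pauses (24 of 40 at defaults)."""
        return math.ceil(self.internal_threshold * self.n_predictions - 1e-9)


@dataclass
class PauseTimeline:
    """One boolean pause decision per 10 Hz prediction."""

    times: np.ndarray
    paused: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.paused = np.asarray(self.paused, bool)
        if self.times.shape != self.paused.shape:
            raise ValueError("times/paused length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def paused_seconds(self, period: float = FRAME_PERIOD_S) -> float:
        return float(self.paused.sum()) * period


class PauseDecider:
    """Stateful ring-buffer vote over the most recent predictions."""

    def __init__(self, config: DeciderConfig | None = None):
        self.config = config or DeciderConfig()
        self._buffer: deque[bool] = deque(maxlen=self.config.n_predictions)
        self._held = UNPAUSED  # block mode: decision held between votes
        self._count_in_block = 0
        self._pause_run = 0

    def update(self, prediction: str) -> str:
        """Feed one prediction; returns paused/unpaused/warming-up."""
        if prediction not in (INTERNAL, EXTERNAL):
            raise ValueError(f"prediction must be internal or external, got {prediction!r}")
        cfg = self.config
        self._buffer.append(prediction == INTERNAL)
        if len(self._buffer) < cfg.n_predictions:
            return WARMING_UP
        if cfg.mode == "sliding":
            decision = PAUSED if sum(self._buffer) >= cfg.min_internal else UNPAUSED
        else:
            # vote once per disjoint block of n predictions, hold in between
            if self._count_in_block == 0:
                self._held = PAUSED if sum(self._buffer) >= cfg.min_internal else UNPAUSED
            self._count_in_block = (self._count_in_block + 1) % cfg.n_predictions
            decision = self._held
        if cfg.max_pause_s is not None:
            if decision == PAUSED:
                self._pause_run += 1
                if self._pause_run * FRAME_PERIOD_S > cfg.max_pause_s:
                    decision = UNPAUSED
            else:
                self._pause_run = 0
        return decision


def decide_batch(
    predictions: np.ndarray | list[str],
    times: np.ndarray | None = None,
    config: DeciderConfig | None = None,
) -> PauseTimeline:
    """Offline replay of :meth:`PauseDecider.update` over a sequence.

    Warm-up decisions are recorded as unpaused. The timeline has exactly
    one entry per prediction; times default to the 10 Hz grid.
    """
    predictions = list(predictions)
    config = config or DeciderConfig()
    if times is None:
        times = (np.arange(len(predictions)) + 1) * FRAME_PERIOD_S
    times = np.asarray(times, float)
    if len(times) != len(predictions):
        raise ValueError("times/predictions length mismatch")
    decider = PauseDecider(config)
    paused = np.zeros(len(predictions), bool)
    for i, p in enumerate(predictions):
        paused[i] = decider.update(p) == PAUSED
    return PauseTimeline(times, paused)
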