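"""Closed-loop simulation of the adaptive application's update scheduler.

Stands in for the AR translator's sticker-update loop: update events are
scheduled at random intervals between 0.3 and 3.0 s (the app's measured
sticker-creation cadence) and suspended while the attention-driven pause
signal is active. Updates that come due during a pause are deferred — not
dropped — and fire as soon as the pause ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng
from .classifier import AttentionModel
from .decider import DeciderConfig, PAUSED, PauseDecider, PauseTimeline
from .frames import FRAME_PERIOD_S, FrameStream

__all__ = ["UpdaterParams", "EventLog", "run_loop", "summarize_events"]

UPDATE = "update"
PAUSE_START = "pause_start"
PAUSE_END = "pause_end"


@dataclass(frozen=True)
class UpdaterParams:
    """Sticker-update cadence: intervals drawn uniformly from [low, high] s."""

    interval_low_s: float = 0.3
    interval_high_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.interval_low_s <= self.interval_high_s:
            raise ValueError("require 0 < low <= high update interval")


@dataclass
class EventLog:
    """Ordered (timestamp, kind) events plus the session duration."""

    events: list[tuple[float, str]]
    duration: float

    def __post_init__(self) -> None:
        ts = [t for t, _ in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("event timestamps must be non-decreasing")
        state = False
        for _, kind in self.events:
            if kind == PAUSE_START:
                if state:
                    raise ValueError("pause_start while already paused")
                state = True
            elif kind == PAUSE_END:
                if not state:
                    raise ValueError("pause_end while not paused")
                state = False

    def pause_intervals(self) -> list[tuple[float, float]]:
        """[start, end) pause intervals; an open pause closes at duration."""
        out, start = [], None
        for t, kind in self.events:
            if kind == PAUSE_START:
                start = t
            elif kind == PAUSE_END:
                out.append((start, t))
                start = None
        if start is not None:
            out.append((start, self.duration))
        return out

    def update_times(self) -> list[float]:
        return [t for t, k in self.events if k == UPDATE]


def run_loop(
    frames: FrameStream,
    model: AttentionModel,
    decider: DeciderConfig | None = None,
    updater: UpdaterParams | None = None,
    force_state: str | None = None,
) -> tuple[EventLog, PauseTimeline]:
    """Replay a frame stream through classify -> vote -> pause -> schedule.

    Predictions happen at each frame timestamp; the pause state holds for
    the following 100 ms. An update fires at its scheduled time if the
    state is then unpaused; otherwise it is deferred to the moment the
    pause ends. ``force_state`` ("paused"/"unpaused") bypasses the
    classifier+decider for testing the scheduler alone (warm-up still
    applies to "paused"). Deterministic given the updater seed.
    """
    decider_cfg = decider or DeciderConfig()
    updater = updater or UpdaterParams()
    rng = child_rng(updater.seed, "updater")

    predictions = model.predict_stream(frames) if force_state is None else None
    engine = PauseDecider(decider_cfg)
    times = frames.times
    n = len(times)
    paused_arr = np.zeros(n, bool)
    events: list[tuple[float, str]] = []
    duration = float(times[-1]) if n else 0.0

    def draw() -> float:
        return float(rng.uniform(updater.interval_low_s, updater.interval_high_s))

    next_update = draw()
    paused = False
    for i in range(n):
        t = float(times[i])
        if force_state is None:
            decision = engine.update(str(predictions[i]))
            now_paused = decision == PAUSED
        elif force_state == "paused":
            # honour warm-up: the first n-1 decisions stay unpaused
            now_paused = i >= decider_cfg.n_predictions - 1
        else:
            now_paused = False
        paused_arr[i] = now_paused
        if now_paused and not paused:
            events.append((t, PAUSE_START))
        elif paused and not now_paused:
            events.append((t, PAUSE_END))
            # deferred updates fire at the unpause instant
            while next_update <= t:
                events.append((t, UPDATE))
                next_update = t + draw()
        paused = now_paused
        # updates due within this (un)paused 100 ms step
        step_end = float(times[i + 1]) if i + 1 < n else duration + FRAME_PERIOD_S
        if not paused:
            while next_update < step_end and next_update <= duration:
                if next_update >= t:
                    events.append((max(next_update, t), UPDATE))
                    next_update = max(next_update, t) + draw()
                else:  # due before this step (e.g. during warm-up start)
                    events.append((t, UPDATE))
                    next_update = t + draw()
    events.sort(key=lambda e: e[0])
    log = EventLog(events=events, duration=duration)
    timeline = PauseTimeline(times, paused_arr)
    return log, timeline


def summarize_events(log: EventLog) -> dict:
    """Totals from an event log: update count, paused fraction, mean gap."""
    updates = log.update_times()
    pauses = log.pause_intervals()
    paused_time = float(sum(e - s for s, e in pauses))
    gaps = np.diff(updates)
    return {
        "update_count": len(updates),
        "paused_fraction": paused_time / log.duration if log.duration > 0 else 0.0,
        "mean_inter_update_gap_s": float(np.mean(gaps)) if len(gaps) else float("nan"),
        "pause_block_count": len(pauses),
        "duration_s": log.duration,
    }
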