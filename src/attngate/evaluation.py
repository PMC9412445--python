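"""Offline evaluation of attention classification and pause behaviour.

Implements the study-style analyses: per-phase (reading vs task)
classification accuracy against phase-derived ground truth; the 5-bin
ground-truth correction for task phases in which the participant re-read
the text (external attention intruding on a nominally internal phase);
run-length segmentation of the pause signal into blocks with length
categories (<3 s, 3-10 s, 10-30 s, >30 s); paused-time percentages; and
Pearson/Spearman correlation helpers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .decider import PauseTimeline
from .frames import FRAME_PERIOD_S
from .plans import EXTERNAL, INTERNAL

__all__ = [
    "TrialRecord",
    "EvalConfig",
    "PauseBlock",
    "trial_accuracy",
    "bin_correct",
    "segment_blocks",
    "block_share",
    "paused_percentage",
    "pearson_r",
    "spearman_r",
    "flag_rereading_trials",
]

BLOCK_CATEGORIES = ("<3s", "3-10s", "10-30s", ">30s")


@dataclass
class TrialRecord:
    """One reading+task trial with aligned predictions and ground truth."""

    trial_id: int
    reading: tuple[float, float]
    task: tuple[float, float]
    times: np.ndarray
    predictions: np.ndarray
    labels: np.ndarray
    rereading: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.predictions = np.asarray(self.predictions, dtype="<U8")
        self.labels = np.asarray(self.labels, dtype="<U8")
        if not self.reading[1] <= self.task[0]:
            raise ValueError("reading interval must precede the task interval")

    def _mask(self, interval: tuple[float, float]) -> np.ndarray:
        lo, hi = interval
        return (self.times > lo) & (self.times <= hi)


@dataclass(frozen=True)
class EvalConfig:
    """Bin-correction and block-category parameters."""

    n_bins: int = 5
    external_dominance: float = 0.5
    block_edges_s: tuple[float, ...] = (3.0, 10.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if list(self.block_edges_s) != sorted(set(self.block_edges_s)):
            raise ValueError("block edges must be strictly increasing")


@dataclass(frozen=True)
class PauseBlock:
    """A maximal run of constant pause state."""

    start: float
    end: float
    paused: bool
    category: str

    @property
    def length(self) -> float:
        return self.end - self.start


def _category(length: float, edges: tuple[float, ...] = (3.0, 10.0, 30.0)) -> str:
    i = int(np.searchsorted(np.asarray(edges), length, side="right"))
    return BLOCK_CATEGORIES[i]


def trial_accuracy(trial: TrialRecord) -> tuple[float, float, float]:
    """(reading accuracy, task accuracy, overall) against the phase labels."""
    rmask, tmask = trial._mask(trial.reading), trial._mask(trial.task)
    correct = trial.predictions == trial.labels
    both = rmask | tmask

    def frac(m: np.ndarray) -> float:
        return float(correct[m].mean()) if m.any() else float("nan")

    return frac(rmask), frac(tmask), frac(both)


def bin_correct(
    trial: TrialRecord, cfg: EvalConfig | None = None
) -> tuple[float, np.ndarray]:
    """Task accuracy after excluding externally-dominated bins.

    The task phase is split into ``n_bins`` equal-duration bins. For
    trials flagged as "thinking and rereading", bins whose fraction of
    external predictions exceeds ``external_dominance`` are excluded —
    the assumed internal ground truth is considered wrong there — and the
    corrected accuracy is computed over the remaining frames. Unflagged
    trials are returned unchanged (no bins excluded). Returns
    (corrected accuracy, boolean excluded-bin mask); accuracy is NaN with
    a warning when every bin is excluded.
    """
    cfg = cfg or EvalConfig()
    lo, hi = trial.task
    edges = np.linspace(lo, hi, cfg.n_bins + 1)
    excluded = np.zeros(cfg.n_bins, bool)
    tmask = trial._mask(trial.task)
    if trial.rereading:
        for i in range(cfg.n_bins):
            m = tmask & (trial.times > edges[i]) & (trial.times <= edges[i + 1])
            if m.any():
                ext_frac = float((trial.predictions[m] == EXTERNAL).mean())
                excluded[i] = ext_frac > cfg.external_dominance
    keep = tmask.copy()
    for i in range(cfg.n_bins):
        if excluded[i]:
            keep &= ~((trial.times > edges[i]) & (trial.times <= edges[i + 1]))
    if not keep.any():
        warnings.warn(f"trial {trial.trial_id}: all task bins excluded; accuracy undefined")
        return float("nan"), excluded
    acc = float((trial.predictions[keep] == trial.labels[keep]).mean())
    return acc, excluded


def flag_rereading_trials(task_durations_s: list[float]) -> list[bool]:
    """Optional heuristic: flag trials whose task ran longer than the median.

    Re-reading while thinking prolongs task solving, so unusually long
    task phases are the likeliest to contain external intrusions. Off by
    default everywhere; the flag is normally a caller-supplied input.
    """
    med = float(np.median(task_durations_s))
    return [d > med for d in task_durations_s]


def segment_blocks(
    timeline: PauseTimeline, cfg: EvalConfig | None = None
) -> list[PauseBlock]:
    """Run-length segmentation of the pause signal into maximal blocks.

    Each decision covers one frame period (0.1 s); a run of k equal
    decisions becomes one block of length k x 0.1 s starting at the first
    decision's window start.
    """
    cfg = cfg or EvalConfig()
    if len(timeline) == 0:
        raise ValueError("timeline is empty")
    p = timeline.paused
    change = np.flatnonzero(np.diff(p.astype(int))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(p)]])
    blocks = []
    for s, e in zip(starts, ends):
        t0 = timeline.times[s] - FRAME_PERIOD_S
        t1 = timeline.times[e - 1]
        blocks.append(
            PauseBlock(
                start=float(t0),
                end=float(t1),
                paused=bool(p[s]),
                category=_category(float(t1 - t0), cfg.block_edges_s),
            )
        )
    return blocks


def block_share(
    blocks_by_participant: dict | list,
    paused: bool | None = None,
    cfg: EvalConfig | None = None,
) -> np.ndarray:
    """Average per-participant block-length category distributions.

    Each participant's blocks (optionally filtered by pause state) are
    first normalised into a distribution over the four length categories;
    distributions are then averaged with equal participant weights, so a
    participant with many short blocks does not dominate one with a single
    long block. Participants with no qualifying blocks are skipped.
    """
    if isinstance(blocks_by_participant, dict):
        groups = list(blocks_by_participant.values())
    else:
        groups = list(blocks_by_participant)
    dists = []
    for blocks in groups:
        sel = [b for b in blocks if paused is None or b.paused == paused]
        if not sel:
            continue
        counts = np.array(
            [sum(b.category == c for b in sel) for c in BLOCK_CATEGORIES], float
        )
        dists.append(counts / counts.sum())
    if not dists:
        raise ValueError("no qualifying blocks in any participant")
    return np.mean(dists, axis=0)


def paused_percentage(
    timeline: PauseTimeline, interval: tuple[float, float] | None = None
) -> float:
    """Percentage of frames paused within [interval], 0-100."""
    if interval is None:
        mask = np.ones(len(timeline), bool)
    else:
        lo, hi = interval
        mask = (timeline.times > lo) & (timeline.times <= hi)
    if not mask.any():
        raise ValueError("interval contains no timeline frames")
    return 100.0 * float(timeline.paused[mask].mean())


def _check_corr_inputs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return x, y


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-test p-value."""
    x, y = _check_corr_inputs(x, y)
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def spearman_r(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p-value."""
    x, y = _check_corr_inputs(x, y)
    r = stats.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)
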