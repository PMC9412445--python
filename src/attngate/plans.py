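"""Session plans: the ground-truth schedule of attention phases.

A calibration/evaluation session alternates *external* attention (reading a
text) with *internal* attention (thinking about a question on that text).
One reading phase plus the following task phase form a trial. The canonical
calibration protocol is four trials of 50 s + 50 s, i.e. eight parts and
400 s of labelled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EXTERNAL = "external"
INTERNAL = "internal"
NONE = "none"

STATES = (EXTERNAL, INTERNAL)


@dataclass(frozen=True)
class Phase:
    state: str
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"phase state must be one of {STATES}, got {self.state!r}")
        if not self.duration > 0:
            raise ValueError(f"phase duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered attention phases plus the trial grouping and a seed.

    ``trial_bounds[i]`` is the index of the first phase of trial ``i``;
    within a trial the states run reading (external) then task (internal).
    """

    phases: tuple[Phase, ...]
    trial_bounds: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("plan needs at least one phase")
        for b in self.trial_bounds:
            if not 0 <= b < len(self.phases):
                raise ValueError(f"trial bound {b} outside phase range")

    @property
    def total_duration(self) -> float:
        return float(sum(p.duration for p in self.phases))

    @property
    def n_trials(self) -> int:
        return len(self.trial_bounds)

    def phase_intervals(self) -> list[tuple[float, float, str]]:
        """(start, end, state) for each phase, in session time."""
        out, t = [], 0.0
        for p in self.phases:
            out.append((t, t + p.duration, p.state))
            t += p.duration
        return out

    def state_at(self, t: float) -> str:
        """State of the phase containing time ``t`` (half-open intervals)."""
        for start, end, state in self.phase_intervals():
            if start <= t < end:
                return state
        return NONE

    def label_for_window(self, t0: float, t1: float) -> str:
        """Label a [t0, t1) analysis window by majority phase coverage.

        The window is clipped to the session extent (left-edge padding of
        the first second contributes no coverage). Ties, and windows with
        no phase coverage at all on one side, resolve toward external —
        consistent with the downstream bias against pausing.
        """
        cov = {EXTERNAL: 0.0, INTERNAL: 0.0}
        for start, end, state in self.phase_intervals():
            lo, hi = max(t0, start), min(t1, end)
            if hi > lo:
                cov[state] += hi - lo
        if cov[EXTERNAL] == 0.0 and cov[INTERNAL] == 0.0:
            return NONE
        return INTERNAL if cov[INTERNAL] > cov[EXTERNAL] else EXTERNAL

    def trial_intervals(self) -> list[tuple[float, float, float, float]]:
        """(reading_start, reading_end, task_start, task_end) per trial."""
        ivals = self.phase_intervals()
        out = []
        for i, b in enumerate(self.trial_bounds):
            last = self.trial_bounds[i + 1] if i + 1 < len(self.trial_bounds) else len(ivals)
            trial = ivals[b:last]
            ext = [iv for iv in trial if iv[2] == EXTERNAL]
            intr = [iv for iv in trial if iv[2] == INTERNAL]
            if not ext or not intr:
                continue
            out.append((ext[0][0], ext[0][1], intr[0][0], intr[0][1]))
        return out

    def to_dict(self) -> dict:
        return {
            "phases": [[p.state, p.duration] for p in self.phases],
            "trial_bounds": list(self.trial_bounds),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionPlan":
        return cls(
            phases=tuple(Phase(s, float(dur)) for s, dur in d["phases"]),
            trial_bounds=tuple(int(b) for b in d["trial_bounds"]),
            seed=int(d["seed"]),
        )


def make_session_plan(
    n_trials: int,
    reading_s: float = 50.0,
    task_s: float = 50.0,
    seed: int = 0,
) -> SessionPlan:
    """Build the alternating reading/thinking plan used for calibration.

    Each trial is one external reading phase of ``reading_s`` seconds
    followed by one internal task phase of ``task_s`` seconds. Four trials
    of 50 s + 50 s give the canonical 400 s calibration session.
    Deterministic: the same arguments always return the same plan.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if not (reading_s > 0 and task_s > 0):
        raise ValueError(f"phase durations must be positive, got {reading_s}, {task_s}")
    phases = []
    for _ in range(n_trials):
        phases.append(Phase(EXTERNAL, float(reading_s)))
        phases.append(Phase(INTERNAL, float(task_s)))
    return SessionPlan(
        phases=tuple(phases),
        trial_bounds=tuple(range(0, 2 * n_trials, 2)),
        seed=int(seed),
    )
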