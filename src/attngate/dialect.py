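"""Headset stream dialect: named stream paths -> internal frame fields.

Consumer headset bridges publish band powers and auxiliary channels over
OSC-style named paths. The exact path strings vary between bridge
versions, so the mapping ships as editable data rather than hard-coded
truth: the five absolute band-power paths are mandatory; auxiliary paths
(fit indicator, battery, motion, blink, jaw clench) are recognised but
unused; unknown paths are ignored and counted.
"""

from __future__ import annotations

import json
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .bands import BAND_NAMES, N_BANDS, N_ELECTRODES
from .frames import FrameStream
from .sessionio import read_session

__all__ = ["StreamDialect", "DEFAULT_DIALECT", "replay_stream"]

DIALECT_VERSION = 1

#: Default path table (editable data, not hard-coded truth).
DEFAULT_PATHS: dict[str, str] = {
    "/muse/elements/delta_absolute": "band:delta",
    "/muse/elements/theta_absolute": "band:theta",
    "/muse/elements/alpha_absolute": "band:alpha",
    "/muse/elements/beta_absolute": "band:beta",
    "/muse/elements/gamma_absolute": "band:gamma",
    "/muse/elements/horseshoe": "aux:fit",
    "/muse/batt": "aux:battery",
    "/muse/gyro": "aux:gyro",
    "/muse/acc": "aux:accelerometer",
    "/muse/elements/blink": "aux:blink",
    "/muse/elements/jaw_clench": "aux:jaw_clench",
}


@dataclass
class StreamDialect:
    """Mapping of stream paths to frame fields, with a version tag."""

    paths: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PATHS))
    version: int = DIALECT_VERSION

    def __post_init__(self) -> None:
        bands = {v.split(":", 1)[1] for v in self.paths.values() if v.startswith("band:")}
        missing = set(BAND_NAMES) - bands
        if missing:
            raise ValueError(f"dialect missing mandatory band paths: {sorted(missing)}")

    def band_of(self, path: str) -> str | None:
        v = self.paths.get(path)
        return v.split(":", 1)[1] if v and v.startswith("band:") else None

    @classmethod
    def from_json(cls, path: str | Path) -> "StreamDialect":
        d = json.loads(Path(path).read_text())
        return cls(paths=d["paths"], version=d.get("version", DIALECT_VERSION))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"version": self.version, "paths": self.paths}, indent=1)
        )

    def frames_from_messages(
        self, messages: Iterable[tuple[str, float, Iterable[float]]]
    ) -> tuple[FrameStream, int]:
        """Assemble frames from (path, timestamp, 4 values) band messages.

        One frame is emitted per timestamp once all five bands have
        arrived for it. Returns (stream, ignored-message count); a
        nonzero count also triggers one summary warning.
        """
        ignored = 0
        by_time: dict[float, dict[str, np.ndarray]] = {}
        for path, t, values in messages:
            band = self.band_of(path)
            if band is None:
                known_aux = path in self.paths
                if not known_aux:
                    ignored += 1
                continue
            by_time.setdefault(round(float(t), 6), {})[band] = np.asarray(
                list(values), float
            )
        times, powers = [], []
        for t in sorted(by_time):
            got = by_time[t]
            if set(got) != set(BAND_NAMES):
                continue
            mat = np.stack([got[b] for b in BAND_NAMES], axis=1)  # (4 elec, 5 bands)
            if mat.shape != (N_ELECTRODES, N_BANDS):
                raise ValueError(f"band message at t={t} has shape {mat.shape}")
            times.append(t)
            powers.append(mat)
        if ignored:
            warnings.warn(f"ignored {ignored} message(s) on unknown stream paths")
        labels = np.full(len(times), "none", dtype="<U8")
        return FrameStream(np.asarray(times), np.asarray(powers).reshape(-1, 4, 5), labels), ignored


def replay_stream(
    path: str | Path,
    dialect: StreamDialect | None = None,  # kept for interface symmetry
    speed: float = float("inf"),
) -> Iterator[tuple[float, np.ndarray, str]]:
    """Replay a session file as a live frame source.

    Yields (timestamp, (4, 5) log-power matrix, label) in timestamp order,
    sleeping (dt / speed) between frames; ``speed=inf`` replays as fast as
    possible. Out-of-order timestamps (e.g. from a corrupted stream) are
    re-sorted with a warning.
    """
    stream, _ = read_session(path)
    order = np.argsort(stream.times, kind="stable")
    if not np.array_equal(order, np.arange(len(stream))):
        warnings.warn(
            f"re-sorted {int((order != np.arange(len(stream))).sum())} out-of-order frame(s)"
        )
    prev_t = None
    for i in order:
        t = float(stream.times[i])
        if np.isfinite(speed) and prev_t is not None and t > prev_t:
            _time.sleep((t - prev_t) / speed)
        prev_t = t
        yield t, stream.powers[i], str(stream.labels[i])
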