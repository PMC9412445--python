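"""Canonical EEG frequency bands and electrode layout for the 4-channel headset.

The five band definitions are the ones streamed by consumer headset bridges
(delta 1-4 Hz, theta 4-8 Hz, alpha 7.5-13 Hz, beta 13-30 Hz, gamma
30-44 Hz). Note that theta and alpha deliberately overlap between 7.5 and
8 Hz; both edges of every band are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """One EEG frequency band: inclusive [low, high] edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low ({self.low}) must be < high ({self.high})")

    def contains(self, f: float) -> bool:
        return self.low <= f <= self.high


#: Electrode order used everywhere (electrode-major feature layout).
ELECTRODES: tuple[str, ...] = ("TP9", "AF7", "AF8", "TP10")

#: Band order used everywhere.
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 7.5, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 44.0),
)

N_ELECTRODES = len(ELECTRODES)
N_BANDS = len(BAND_NAMES)
N_FEATURES = N_ELECTRODES * N_BANDS  # 20

#: Column names of the session table, electrode-major: tp9_delta ... tp10_gamma.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{e.lower()}_{b}" for e in ELECTRODES for b in BAND_NAMES
)


def feature_index(electrode: str, band: str) -> int:
    """Flat index of (electrode, band) in the electrode-major 20-vector."""
    return ELECTRODES.index(electrode) * N_BANDS + BAND_NAMES.index(band)
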