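"""Named child random streams derived from one global seed.

Every stochastic component (session plan, signal synthesis, stream
corruption, cross-validation shuffling, update-interval draws) pulls its
generator from here, so a single integer seed reproduces a whole run while
components stay statistically independent of each other.
"""

from __future__ import annotations

import numpy as np

# stable role identifiers; appending keeps old streams reproducible
_ROLES = {
    "plan": 0,
    "signal": 1,
    "corruption": 2,
    "cv": 3,
    "updater": 4,
}


def child_rng(seed: int, role: str) -> np.random.Generator:
    """Return the named child generator for ``role`` under ``seed``."""
    if role not in _ROLES:
        raise ValueError(f"unknown rng role {role!r}; known: {sorted(_ROLES)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_ROLES[role],))
    return np.random.default_rng(ss)
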