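"""Run configuration: one document tying all pipeline parameter blocks together.

Defaults equal the pipeline's canonical constants: 256-sample window at
10 Hz, 5 bands, 5 CV folds, a 40-prediction / 60% pause vote, and
0.3-3.0 s update intervals. Accepted on disk as YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .decider import DeciderConfig
from .evaluation import EvalConfig
from .features import FeatureConfig
from .appsim import UpdaterParams


@dataclass
class RunConfig:
    seed: int = 0
    n_trials: int = 4
    reading_s: float = 50.0
    task_s: float = 50.0
    mode: str = "frames"  # or "raw"
    cv_folds: int = 5
    cv_scheme: str = "shuffled"
    features: FeatureConfig = field(default_factory=FeatureConfig)
    decider: DeciderConfig = field(default_factory=DeciderConfig)
    updater: UpdaterParams = field(default_factory=UpdaterParams)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("features", FeatureConfig),
            ("decider", DeciderConfig),
            ("updater", UpdaterParams),
            ("evaluation", EvalConfig),
        ):
            if key in d and isinstance(d[key], dict):
                block = dict(d[key])
                if key == "evaluation" and "block_edges_s" in block:
                    block["block_edges_s"] = tuple(block["block_edges_s"])
                d[key] = typ(**block)
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def dump(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
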