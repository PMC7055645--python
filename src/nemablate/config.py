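"""Run configuration: input scenarios, sampling sizes, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

#: Touch-receptor input scenarios for the gentle-touch response.
DEFAULT_SCENARIOS = {
    "anterior": ["ALML", "ALMR", "AVM"],
    "posterior": ["PLML", "PLMR"],
}

CONFIG_VERSION = 1


@dataclass
class RunConfig:
    """Serializable configuration for a scan run.

    ``scenarios`` maps a scenario name to its input neuron list; ``targets``
    of ``None`` means every muscle.  Every run copies its configuration into
    its output directory so results remain self-describing.
    """

    scenarios: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SCENARIOS.items()})
    targets: Optional[list] = None
    trials: int = 3
    orderings: int = 1000
    seed: int = 0
    candidate_pool: Optional[list] = None
    version: int = CONFIG_VERSION

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
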