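"""Run configuration: the knobs shared across the pipeline.

Defaults reproduce the toolkit's standard conventions: 3-nt linkers,
7-nt cis tether, the (3, 7) kcal/mol stability window, folding at 37 C.
Configs serialize to a single JSON file; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    parameter_table_version: str = "v1"
    temperature_c: float = 37.0
    window: tuple[float, float] = (3.0, 7.0)
    linker_len: int = 3
    tether_len: int = 7
    leak_threshold: float = 0.2
    on_threshold: float = 0.5
    crosstalk_threshold: float = 0.2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.temperature_c != 37.0:
            raise ConfigError(
                "the energy model is parameterized at 37 C only; "
                f"got temperature_c={self.temperature_c}"
            )
        low, high = self.window
        if low >= high:
            raise ConfigError(f"window low {low} must be below high {high}")
        if self.linker_len < 0 or self.tether_len < 0:
            raise ConfigError("linker_len and tether_len must be >= 0")
        object.__setattr__(self, "window", (float(low), float(high)))

    def to_json(self) -> str:
        data = asdict(self)
        data["window"] = list(data["window"])
        return json.dumps(data, indent=2, sort_keys=True) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    @property
    def config_hash(self) -> str:
        """Short digest identifying this configuration in report headers."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
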