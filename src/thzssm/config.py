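"""Run configuration: one YAML file with per-stage sections.

Sections map onto the parameter dataclasses of the pipeline stages; unknown
keys are rejected with an error listing them, so a typo in a config file
never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .preprocess import BeadsParams, PeakFindParams
from .ssm import SsmWeights
from .synth import SynthConfig

__all__ = ["RunConfig", "load_config"]

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class RunConfig:
    beads: BeadsParams = field(default_factory=BeadsParams)
    peaks: PeakFindParams = field(default_factory=PeakFindParams)
    weights: SsmWeights = field(default_factory=SsmWeights)
    shape_term: str = "cs"
    synth: SynthConfig = field(default_factory=SynthConfig)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.shape_term not in ("cs", "ccs"):
            raise ValueError(f"shape_term must be 'cs' or 'ccs', got {self.shape_term!r}")
        if self.log_level.upper() not in _LOG_LEVELS:
            raise ValueError(f"log_level must be one of {_LOG_LEVELS}")
        self.log_level = self.log_level.upper()


def _build(cls, section: str, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section {section!r}: {', '.join(unknown)}"
        )
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    sections = {"beads": BeadsParams, "peaks": PeakFindParams,
                "weights": SsmWeights, "synth": SynthConfig}
    known_top = set(sections) | {"shape_term", "log_level"}
    unknown = sorted(set(data) - known_top)
    if unknown:
        raise ValueError(f"unknown key(s) in config: {', '.join(unknown)}")
    kwargs = {}
    for name, cls in sections.items():
        if name in data:
            kwargs[name] = _build(cls, name, dict(data[name] or {}))
    for name in ("shape_term", "log_level"):
        if name in data:
            kwargs[name] = data[name]
    return RunConfig(**kwargs)
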