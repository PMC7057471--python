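"""Run configuration: defaults, YAML overrides, and hashing."""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .clinical import DEFAULT_SOFA_TABLE
from .icd9 import DEFAULT_TAXONOMY_DICT
from .model import STUDY_WINDOW

__all__ = ["RunConfig", "load_config", "config_hash"]


def _parse_window(value) -> tuple[dt.date, dt.date]:
    if isinstance(value, (list, tuple)) and len(value) == 2:
        out = tuple(
            v if isinstance(v, dt.date) else dt.date.fromisoformat(str(v)) for v in value
        )
        return out  # type: ignore[return-value]
    raise ValueError(f"window must be a [start, end] pair, got {value!r}")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on besides the input files."""

    seed: int = 0
    window: tuple[dt.date, dt.date] = STUDY_WINDOW
    #: window for the recent-years sensitivity rerun
    recent_window: tuple[dt.date, dt.date] = (dt.date(2009, 1, 1), dt.date(2012, 12, 31))
    bootstrap_reps: int = 1000
    bootstrap_alpha: float = 0.05
    bootstrap_method: str = "bc"
    horizon_days: int = 90
    same_day_person_days: float = 0.5
    taxonomy: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TAXONOMY_DICT.items()})
    sofa_table: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_SOFA_TABLE)))
    #: overrides applied on top of the generator defaults (synthetic mode)
    generator: dict = field(default_factory=dict)
    #: input file paths (files mode): events, claims, participants, coverage
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key in ("window", "recent_window"):
                value = _parse_window(value)
            setattr(cfg, key, value)
        return cfg

    def as_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("window", "recent_window"):
            d[key] = [x.isoformat() for x in d[key]]
        gen = dict(d.get("generator") or {})
        if "window" in gen:
            gen["window"] = [
                x.isoformat() if isinstance(x, dt.date) else str(x) for x in gen["window"]
            ]
        d["generator"] = gen
        return d


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; missing path means pure defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """Stable sha256 over the canonical JSON form of the configuration."""
    canon = json.dumps(config.as_canonical_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()
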