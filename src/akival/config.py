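"""Configuration objects for the staging engine and pipeline runs.

Every numeric threshold of the detection algorithm lives in
:class:`EngineConfig` so that variant "in-house" rule sets can be simulated
by overriding individual values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

log = logging.getLogger("akival")


@dataclass(frozen=True)
class EngineConfig:
    """Thresholds and toggles of the creatinine staging algorithm.

    Defaults implement the national e-alert rule set: stage by the larger of
    the index-to-reference ratios (short-window minimum and long-window
    median), a 48-hour absolute-rise rule, and an absolute-concentration
    escalation to stage 3.
    """

    ratio_stage1: float = 1.5
    ratio_stage2: float = 2.0
    ratio_stage3: float = 3.0
    delta48_umol: float = 26.0     # strict ">" comparison
    high_c1_umol: float = 354.0
    high_c1_enabled: bool = True
    rv1_window_days: float = 7.0
    rv2_window_days: float = 365.0
    delta_window_hours: float = 48.0
    use_both_ratios: bool = True   # False -> RV1 preferred when present
    match_tolerance_hours: float = 24.0

    def replace(self, **kwargs: Any) -> "EngineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ReadConfig:
    """Validation thresholds applied while reading submission files."""

    scr_max_umol: float = 4000.0
    reject_threshold: float = 0.05  # fraction of rejected rows that is fatal
    min_age_years: int = 18
    max_age_years: int = 99
    censor_post_krt_scr: bool = False


def engine_config_from_mapping(m: Mapping[str, Any] | None) -> EngineConfig:
    if not m:
        return EngineConfig()
    known = {f.name for f in dataclasses.fields(EngineConfig)}
    unknown = set(m) - known
    if unknown:
        raise ValueError(f"unknown engine config keys: {sorted(unknown)}")
    return EngineConfig(**dict(m))


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML run configuration and echo every toggle to the log."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config root must be a mapping, got {type(cfg).__name__}")
    for key, value in sorted(cfg.items()):
        log.info("config %s = %r", key, value)
    return cfg
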