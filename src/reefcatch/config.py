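"""Pipeline configuration: a single YAML file, strictly validated.

Unknown keys are rejected (a misspelt option must never silently fall
back to a default), and every run is stamped with a short hash of the
canonicalised config so output artifacts are attributable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs.

    Paths are resolved relative to the config file's directory. The
    analysis window defaults to the 2008-2017 study decade and the risk
    window to mean 2016-2018 catch.
    """

    # inputs
    habitat_csv: str = "habitat_evidence.csv"
    group_map_csv: str | None = None
    catch_csv: str = "catch.csv"
    region_csv: str = "regions.csv"
    cpue_csv: str = "cpue.csv"
    # analysis choices
    year_start: int = 2008
    year_end: int = 2017
    group_by: str = "region"
    overrides: dict = field(default_factory=dict)  # group_label -> category
    recreational_combine: str = "mean"  # how multi-survey counts combine
    # surplus production / risk
    regime_year: int | None = 2004
    efficiency_trend_pct: float = 0.0
    risk_window: tuple[int, int] = (2016, 2018)
    priors: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)
    # bookkeeping
    seed: int = 0
    outdir: str = "reefcatch_out"

    def __post_init__(self):
        if self.year_end < self.year_start:
            raise ConfigurationError("year_end must be >= year_start")
        if self.group_by not in ("gear", "region", "sector"):
            raise ConfigurationError("group_by must be gear, region or sector")
        if self.recreational_combine not in ("mean", "sum"):
            raise ConfigurationError("recreational_combine must be mean or sum")
        self.risk_window = tuple(int(y) for y in self.risk_window)
        if len(self.risk_window) != 2 or self.risk_window[1] < self.risk_window[0]:
            raise ConfigurationError("risk_window must be (start, end), start<=end")


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config, rejecting unknown keys."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path.name}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigurationError(f"{path.name}: unknown config keys {unknown}")
    cfg = PipelineConfig(**raw)
    base = path.parent
    for attr in ("habitat_csv", "group_map_csv", "catch_csv", "region_csv",
                 "cpue_csv", "outdir"):
        val = getattr(cfg, attr)
        if val is not None and not Path(val).is_absolute():
            setattr(cfg, attr, str(base / val))
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable hash of the canonicalised configuration."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
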