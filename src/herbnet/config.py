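"""Pipeline configuration.

All thresholds default to the published screening and classification
cutoffs: ADME gates OB >= 20%, DL >= 0.18, Caco-2 >= 0; a gene counts as
altered when its model/baseline fold ratio is >= 4 (up) or < 1/4 (down);
a treated gene counts as rescued when its treated/baseline ratio falls in
the open window (1/4, 4).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class AdmeThresholds:
    """Inclusive lower bounds on the three ADME screening properties.

    ob_min is in percent, dl_min unitless on the 0-1 drug-likeness scale,
    caco2_min unitless (Caco-2 permeability may legitimately be negative,
    hence a 0 cutoff is meaningful).
    """

    ob_min: float = 20.0
    dl_min: float = 0.18
    caco2_min: float = 0.0

    def __post_init__(self) -> None:
        if self.ob_min < 0 or self.dl_min < 0:
            raise ConfigError("ob_min and dl_min must be non-negative")


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of every tunable the pipeline reads.

    Fold ratios are expressed as (group mean + pseudocount) /
    (baseline mean + pseudocount).  ``altered_up_min`` is inclusive,
    ``altered_down_max`` strict, and the rescue window is open on both
    sides: up-alteration means a ratio of at least 4, down-alteration a
    ratio strictly below 1/4, and rescue a treated ratio strictly inside
    the 4-fold window.
    """

    adme_thresholds: AdmeThresholds = field(default_factory=AdmeThresholds)
    altered_up_min: float = 4.0
    altered_down_max: float = 0.25
    rescue_lower: float = 0.25
    rescue_upper: float = 4.0
    ppi_score_min: int = 400
    pseudocount: float = 1.0
    group_summary: str = "mean"  # "mean" or "median"
    hub_top_k: int = 10
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.altered_down_max < 1 < self.altered_up_min):
            raise ConfigError(
                "require 0 < altered_down_max < 1 < altered_up_min, got "
                f"{self.altered_down_max}, {self.altered_up_min}"
            )
        if self.rescue_lower > self.altered_down_max:
            raise ConfigError("rescue_lower must be <= altered_down_max")
        if self.rescue_upper > self.altered_up_min:
            raise ConfigError("rescue_upper must be <= altered_up_min")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be non-negative")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 <= self.ppi_score_min <= 1000:
            raise ConfigError("ppi_score_min must lie in [0, 1000]")
        if self.group_summary not in ("mean", "median"):
            raise ConfigError("group_summary must be 'mean' or 'median'")


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML key-value config file; keyword overrides win.

    The file may nest ADME thresholds under ``adme_thresholds`` or give
    ``ob_min``/``dl_min``/``caco2_min`` at top level.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a key-value mapping")
    adme_kwargs = dict(raw.pop("adme_thresholds", {}) or {})
    for key in ("ob_min", "dl_min", "caco2_min"):
        if key in raw:
            adme_kwargs[key] = raw.pop(key)
        if key in overrides and overrides[key] is not None:
            adme_kwargs[key] = overrides.pop(key)
        overrides.pop(key, None)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(adme_thresholds=AdmeThresholds(**adme_kwargs), **raw)
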