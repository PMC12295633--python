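"""Fold-change classification of model-altered genes and treatment rescue.

The analysis contrasts three groups against a designated baseline (sham):
per gene, the model/baseline and treated/baseline fold ratios are taken on
group summary expression.  A gene is *altered* when the model ratio is
>= 4 (up) or < 1/4 (down); an altered gene is *rescued* when its treated
ratio returns to the open window (1/4, 4).  The headline statistic is the
percentage of altered genes rescued, reported rounded to the nearest
integer with the exact fraction alongside.

Boundary semantics are deliberate and asymmetric: up is inclusive at
4.0, down strict at 0.25, and the rescue window open on both ends — a
gene at a model ratio of exactly 4.0 is altered, and a treated ratio of
exactly 4.0 does not rescue it.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .config import PipelineConfig

logger = logging.getLogger(__name__)

BASELINE, MODEL, TREATED = "baseline", "model", "treated"


@dataclass(frozen=True)
class ExpressionStudy:
    """Gene x sample expression matrix with a three-group design.

    ``values`` is genes (rows) by samples (columns), strictly non-negative.
    ``groups`` assigns every sample to one of the three design roles
    (baseline / model / treated); the original group names (e.g. "sham")
    are preserved in ``group_names``.
    """

    values: pd.DataFrame
    groups: Mapping[str, str]  # sample -> role in {baseline, model, treated}
    group_names: Mapping[str, str] = field(
        default_factory=lambda: {BASELINE: "sham", MODEL: "model", TREATED: "treated"}
    )

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group assignment: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        for role in (BASELINE, MODEL, TREATED):
            if not self.samples_in(role):
                raise ValueError(f"group {role!r} has no samples")

    def samples_in(self, role: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == role]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class RescueReport:
    """Per-gene alteration/rescue calls and the summary percentages.

    ``per_gene`` columns: model_ratio, treated_ratio, direction
    (up/down/unchanged), rescued (boolean, NA for unchanged genes).
    Percentages are None when the corresponding denominator is zero.
    """

    per_gene: pd.DataFrame
    n_up: int
    n_down: int
    n_up_rescued: int
    n_down_rescued: int

    @property
    def n_altered(self) -> int:
        return self.n_up + self.n_down

    @property
    def n_rescued(self) -> int:
        return self.n_up_rescued + self.n_down_rescued

    @property
    def up_rescue_pct(self) -> float | None:
        return 100.0 * self.n_up_rescued / self.n_up if self.n_up else None

    @property
    def down_rescue_pct(self) -> float | None:
        return 100.0 * self.n_down_rescued / self.n_down if self.n_down else None

    @property
    def overall_rescue_pct(self) -> float | None:
        if not self.n_altered:
            return None
        return 100.0 * self.n_rescued / self.n_altered

    def summary(self) -> dict:
        """JSON-ready summary; headline percentage at nearest integer."""
        pct = self.overall_rescue_pct
        return {
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_altered": self.n_altered,
            "n_up_rescued": self.n_up_rescued,
            "n_down_rescued": self.n_down_rescued,
            "n_rescued": self.n_rescued,
            "up_rescue_pct": self.up_rescue_pct,
            "down_rescue_pct": self.down_rescue_pct,
            "overall_rescue_pct_exact": pct,
            "overall_rescue_pct": None if pct is None else round(pct),
        }


def compute_ratios(
    study: ExpressionStudy, config: PipelineConfig
) -> pd.DataFrame:
    """Per-gene model/baseline and treated/baseline fold ratios.

    Group summary is the arithmetic mean by default (median via
    ``config.group_summary``); the pseudocount is added symmetrically to
    numerator and denominator so ratios are finite and positive even for
    genes silent in one group.
    """
    summarise = (
        (lambda df: df.mean(axis=1))
        if config.group_summary == "mean"
        else (lambda df: df.median(axis=1))
    )
    means = {
        role: summarise(study.values[study.samples_in(role)])
        for role in (BASELINE, MODEL, TREATED)
    }
    base = means[BASELINE] + config.pseudocount
    if (base <= 0).any():
        zero = base.index[base <= 0][:5].tolist()
        raise ValueError(
            f"genes with zero baseline expression and pseudocount 0 "
            f"(e.g. {zero}); set pseudocount > 0 in the config"
        )
    out = pd.DataFrame(
        {
            "model_ratio": (means[MODEL] + config.pseudocount) / base,
            "treated_ratio": (means[TREATED] + config.pseudocount) / base,
        },
        index=study.values.index,
    )
    return out


def classify_altered(
    model_ratios: pd.Series, config: PipelineConfig
) -> pd.Series:
    """Direction call per gene: 'up' (ratio >= 4), 'down' (< 1/4), else 'unchanged'."""
    if (model_ratios <= 0).any():
        raise ValueError("fold ratios must be positive")
    direction = pd.Series("unchanged", index=model_ratios.index, dtype=object)
    direction[model_ratios >= config.altered_up_min] = "up"
    direction[model_ratios < config.altered_down_max] = "down"
    return direction


def classify_rescue(
    ratios: pd.DataFrame, config: PipelineConfig
) -> RescueReport:
    """Full alteration + rescue classification from a ratio table.

    ``ratios`` must carry ``model_ratio`` and ``treated_ratio`` columns
    (as produced by :func:`compute_ratios`).  Rescue is defined only for
    altered genes: treated ratio strictly inside
    (``rescue_lower``, ``rescue_upper``).
    """
    direction = classify_altered(ratios["model_ratio"], config)
    in_window = (ratios["treated_ratio"] > config.rescue_lower) & (
        ratios["treated_ratio"] < config.rescue_upper
    )
    rescued = pd.Series(pd.NA, index=ratios.index, dtype=object)
    altered = direction != "unchanged"
    rescued[altered] = in_window[altered]

    per_gene = ratios.assign(direction=direction, rescued=rescued)
    n_up = int((direction == "up").sum())
    n_down = int((direction == "down").sum())
    report = RescueReport(
        per_gene=per_gene,
        n_up=n_up,
        n_down=n_down,
        n_up_rescued=int(((direction == "up") & in_window).sum()),
        n_down_rescued=int(((direction == "down") & in_window).sum()),
    )
    logger.info(
        "rescue classification: %d genes, %d up / %d down altered, "
        "%d rescued (%s%%)",
        len(per_gene), n_up, n_down, report.n_rescued,
        "NA" if report.overall_rescue_pct is None
        else f"{report.overall_rescue_pct:.2f}",
    )
    return report


def analyse_study(
    study: ExpressionStudy, config: PipelineConfig
) -> RescueReport:
    """Convenience: ratios then full classification."""
    return classify_rescue(compute_ratios(study, config), config)


def cluster_heatmap_export(
    study: ExpressionStudy, report: RescueReport
) -> pd.DataFrame:
    """Altered genes ordered by hierarchical clustering of log2 ratios.

    Average linkage on Euclidean distances between per-gene
    (log2 model_ratio, log2 treated_ratio) profiles; emits the ordered
    log2-ratio table for external heat-map rendering.  With fewer than two
    altered genes the input order passes through.
    """
    altered = report.per_gene[report.per_gene["direction"] != "unchanged"]
    log2 = np.log2(altered[["model_ratio", "treated_ratio"]]).rename(
        columns={"model_ratio": "log2_model_ratio",
                 "treated_ratio": "log2_treated_ratio"}
    )
    if len(log2) < 2:
        return log2
    order = leaves_list(average(pdist(log2.to_numpy(), metric="euclidean")))
    return log2.iloc[order]
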