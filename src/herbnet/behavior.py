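"""Behavioral trial scoring and normality-gated group comparison.

Scores the three standard rodent cognition/anxiety assays from trial
logs:

* Y-maze spontaneous alternation — working memory; the percentage of
  consecutive three-entry windows visiting three distinct arms:
  ``% alternation = alternations / (total arm entries - 2) x 100``.
* Novel object recognition discrimination ratio — recognition memory;
  ``DR = N time / (N time + F time) x 100``.
* Elevated plus maze closed-arm entries/time — anxiety-like behavior.

Group comparison follows the normality-gated two-path procedure common in
behavioral pharmacology: Shapiro-Wilk per group; if every group is
compatible with normality (p > alpha) a one-way ANOVA with Holm-Sidak
pairwise post hoc tests runs, otherwise Kruskal-Wallis with Dunn's
multiple-comparison post hoc.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Explicit marker for metrics that cannot be computed for a trial
#: (too few entries, zero total exploration time). Propagates as missing,
#: never as zero.
UNDEFINED = float("nan")


@dataclass(frozen=True)
class MazeTrial:
    """One Y-maze session: ordered arm entries with timestamps (seconds)."""

    mouse: str
    entries: tuple[str, ...]
    timestamps: tuple[float, ...]
    arms: frozenset[str] = frozenset({"A", "B", "C"})

    def __post_init__(self) -> None:
        if len(self.entries) != len(self.timestamps):
            raise ValueError("entries and timestamps must align")
        if any(t2 <= t1 for t1, t2 in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be strictly increasing")
        bad = set(self.entries) - self.arms
        if bad:
            raise ValueError(f"unknown arm labels {sorted(bad)}")


@dataclass(frozen=True)
class ObjectTrial:
    """One novel-object-recognition session."""

    mouse: str
    novel_time: float
    familiar_time: float
    distance: float = 0.0
    zone_entries: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.novel_time < 0 or self.familiar_time < 0:
            raise ValueError("exploration times must be non-negative")


@dataclass(frozen=True)
class EpmTrial:
    """One elevated-plus-maze session."""

    mouse: str
    closed_entries: int
    closed_time: float
    open_entries: int = 0
    open_time: float = 0.0

    def __post_init__(self) -> None:
        if min(self.closed_entries, self.open_entries) < 0:
            raise ValueError("entry counts must be non-negative")
        if min(self.closed_time, self.open_time) < 0:
            raise ValueError("arm times must be non-negative")


def spontaneous_alternation(trial: MazeTrial) -> float:
    """Percent alternation over all length-3 windows of consecutive entries.

    An alternation is any window of three consecutive entries visiting
    three distinct arms; the denominator (entries - 2) is exactly the
    window count.  Returns NaN (undefined) for trials with fewer than
    three entries.
    """
    seq = trial.entries
    if len(seq) < 3:
        return UNDEFINED
    windows = len(seq) - 2
    alternations = sum(
        len({seq[i], seq[i + 1], seq[i + 2]}) == 3 for i in range(windows)
    )
    return 100.0 * alternations / windows


def first_arm_latency(
    trial: MazeTrial, trial_start: float = 0.0
) -> tuple[float, int]:
    """(latency to first arm entry in seconds, total arm entries).

    Latency is NaN for an empty trial.
    """
    if not trial.entries:
        return UNDEFINED, 0
    return trial.timestamps[0] - trial_start, len(trial.entries)


def discrimination_ratio(trial: ObjectTrial) -> float:
    """Novel-object exploration as a percentage of total object time."""
    total = trial.novel_time + trial.familiar_time
    if total <= 0:
        return UNDEFINED
    return 100.0 * trial.novel_time / total


# --------------------------------------------------------------------------
# Group comparison


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the normality-gated omnibus + post hoc procedure."""

    path: str  # "parametric" or "nonparametric"
    normality_p: Mapping[str, float]
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    pairwise: Mapping[tuple[str, str], float]  # adjusted p-values
    alpha: float

    @property
    def significant(self) -> bool:
        return self.omnibus_p < self.alpha

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise.items() if p < self.alpha]


def _dunn_posthoc(
    groups: Mapping[str, Sequence[float]]
) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise z tests with tie correction.

    Pairwise p-values are Bonferroni-adjusted over all group pairs, the
    classical form of Dunn's multiple-comparison procedure.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    i = 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = float(ranks[i : i + n_g].mean())
        sizes[g] = n_g
        i += n_g
    # tie correction sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(names, 2))
    raw: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            raw[(a, b)] = 1.0
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw[(a, b)] = 2.0 * stats.norm.sf(abs(z))
    adjusted = np.minimum(np.array([raw[p] for p in pairs]) * len(pairs), 1.0)
    return dict(zip(pairs, adjusted.tolist()))


def group_compare(
    values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """Normality-gated comparison of one behavioral variable across groups.

    Per-group Shapiro-Wilk decides the path: all p > alpha -> one-way
    ANOVA with Holm-Sidak-adjusted pairwise Welch t tests; any p <= alpha
    -> Kruskal-Wallis with Dunn's post hoc.  Missing values (NaN, from
    undefined per-mouse metrics) are dropped per group before testing.

    Raises ValueError naming any group left with fewer than three values.
    """
    clean = {
        g: [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
        for g, vals in values.items()
    }
    if len(clean) < 2:
        raise ValueError("group_compare requires at least two groups")
    for g, vals in clean.items():
        if len(vals) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 usable values")

    normality = {
        g: float(stats.shapiro(np.asarray(vals, dtype=float)).pvalue)
        for g, vals in clean.items()
    }
    arrays = [np.asarray(clean[g], dtype=float) for g in clean]

    if all(p > alpha for p in normality.values()):
        stat, p = stats.f_oneway(*arrays)
        pairs = list(itertools.combinations(clean, 2))
        raw = [
            float(stats.ttest_ind(clean[a], clean[b], equal_var=True).pvalue)
            for a, b in pairs
        ]
        adj = multipletests(raw, method="holm-sidak")[1]
        return GroupComparison(
            path="parametric",
            normality_p=normality,
            omnibus_test="one-way ANOVA",
            omnibus_stat=float(stat),
            omnibus_p=float(p),
            pairwise=dict(zip(pairs, adj.tolist())),
            alpha=alpha,
        )

    stat, p = stats.kruskal(*arrays)
    return GroupComparison(
        path="nonparametric",
        normality_p=normality,
        omnibus_test="Kruskal-Wallis",
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=_dunn_posthoc(clean),
        alpha=alpha,
    )
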