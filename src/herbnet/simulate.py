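"""Synthetic input generators with planted ground truth.

Every table the pipeline consumes can be generated here with a known
answer planted in it: per-herb ADME pass fractions, cross-herb overlaps,
compound target degrees, PPI hub degrees, altered/rescued gene sets with
a stated fold effect and log-normal noise, and behavioral trial logs with
known alternation probability and discrimination ratio.  Downstream
stages are tested by recovering the plant.

All randomness in a call flows from its single integer seed; identical
seed and parameters give byte-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adme import IngredientRecord
from .behavior import EpmTrial, MazeTrial, ObjectTrial
from .config import AdmeThresholds
from .rescue import BASELINE, MODEL, TREATED, ExpressionStudy
from .targets import CompoundTargetMap


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generators, for test harnesses.

    Fields are filled by whichever generator produced the artifact;
    invariants: planted_rescued is a subset of planted_altered, the fold
    effect applied to "up" genes is at least the alteration threshold,
    and all fractions lie in [0, 1].
    """

    planted_pass_fraction: Mapping[str, float] = field(default_factory=dict)
    planted_overlap: tuple[tuple[str, tuple[str, ...]], ...] = ()
    planted_hub_degrees: Mapping[str, int] = field(default_factory=dict)
    planted_altered: Mapping[str, str] = field(default_factory=dict)  # gene -> up/down
    planted_rescued: frozenset[str] = frozenset()
    effect_fold: float = 8.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.planted_rescued) <= set(self.planted_altered):
            raise ValueError("planted_rescued must be a subset of planted_altered")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for frac in self.planted_pass_fraction.values():
            if not 0 <= frac <= 1:
                raise ValueError("pass fractions must lie in [0, 1]")


# --------------------------------------------------------------------------
# Herb-ingredient tables


def gen_herb_ingredient_table(
    herb_sizes: Mapping[str, int],
    overlap_spec: Sequence[tuple[str, tuple[str, ...]]],
    pass_fraction: float,
    seed: int,
    thresholds: AdmeThresholds | None = None,
) -> tuple[list[IngredientRecord], SyntheticTruth]:
    """Herb-ingredient rows with an exact planted ADME pass fraction.

    Each herb gets ``herb_sizes[herb]`` rows; ingredients named in
    ``overlap_spec`` appear in every herb of their pair with identical
    ADME values.  Exactly ``round(pass_fraction * size)`` ingredients per
    herb clear the thresholds.  Shared ingredients are always generated
    as passing (so their status is consistent across herbs), which
    requires each herb's pass quota to cover its shared-ingredient count.
    """
    thr = thresholds or AdmeThresholds()
    if not 0 <= pass_fraction <= 1:
        raise ValueError("pass_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    shared_by_herb: dict[str, list[str]] = {h: [] for h in herb_sizes}
    for name, herbs in overlap_spec:
        if len(herbs) < 2:
            raise ValueError(f"overlap ingredient {name!r} needs >= 2 herbs")
        for h in herbs:
            if h not in herb_sizes:
                raise ValueError(
                    f"overlap ingredient {name!r} names unknown herb {h!r}"
                )
            shared_by_herb[h].append(name)
    for h, shared in shared_by_herb.items():
        if len(shared) > herb_sizes[h]:
            raise ValueError(f"herb {h!r} too small for its shared ingredients")

    def draw_passing() -> tuple[float, float, float]:
        return (
            float(rng.uniform(thr.ob_min, 100.0)),
            float(rng.uniform(thr.dl_min, 1.0)),
            float(rng.uniform(max(thr.caco2_min, 0.0), 2.0)),
        )

    def draw_failing() -> tuple[float, float, float]:
        # fail the OB gate decisively; other properties arbitrary
        return (
            float(rng.uniform(0.0, thr.ob_min * 0.9)),
            float(rng.uniform(0.0, 1.0)),
            float(rng.uniform(-1.0, 2.0)),
        )

    shared_adme: dict[str, tuple[float, float, float]] = {}
    records: list[IngredientRecord] = []
    pass_fraction_by_herb: dict[str, float] = {}
    for herb in herb_sizes:
        size = herb_sizes[herb]
        n_pass = round(pass_fraction * size)
        shared = shared_by_herb[herb]
        if pass_fraction > 0 and n_pass < len(shared):
            raise ValueError(
                f"herb {herb!r}: pass quota {n_pass} below shared count "
                f"{len(shared)}; raise pass_fraction or shrink the overlap"
            )
        pass_fraction_by_herb[herb] = n_pass / size if size else 0.0
        names = shared + [f"{herb}_cpd{i:03d}" for i in range(size - len(shared))]
        for idx, name in enumerate(names):
            is_shared = idx < len(shared)
            passes = (pass_fraction > 0 and is_shared) or (
                not is_shared and idx < len(shared) + (n_pass - len(shared))
            )
            if pass_fraction == 0:
                passes = False
            if is_shared:
                if name not in shared_adme:
                    shared_adme[name] = draw_passing() if passes else draw_failing()
                ob, dl, caco2 = shared_adme[name]
            else:
                ob, dl, caco2 = draw_passing() if passes else draw_failing()
            records.append(
                IngredientRecord(herb=herb, ingredient=name, ob=ob, dl=dl, caco2=caco2)
            )
    truth = SyntheticTruth(
        planted_pass_fraction=pass_fraction_by_herb,
        planted_overlap=tuple((n, tuple(h)) for n, h in overlap_spec),
        seed=seed,
    )
    return records, truth


# --------------------------------------------------------------------------
# Compound-target maps


def gen_compound_target_map(
    compounds: Sequence[str],
    n_targets: int,
    degree_dist: Mapping[str, int],
    seed: int,
) -> CompoundTargetMap:
    """Bipartite compound->target relation with exact per-compound degrees.

    The target universe is ``T0001 .. T{n_targets}``; each compound is
    linked to exactly ``degree_dist[compound]`` targets drawn without
    replacement.
    """
    rng = np.random.default_rng(seed)
    universe = [f"T{i + 1:04d}" for i in range(n_targets)]
    pairs: list[tuple[str, str]] = []
    for compound in compounds:
        degree = degree_dist.get(compound, 0)
        if degree > n_targets:
            raise ValueError(
                f"compound {compound!r} requests degree {degree} > "
                f"target universe {n_targets}"
            )
        chosen = rng.choice(universe, size=degree, replace=False)
        pairs.extend((compound, t) for t in sorted(chosen))
    return CompoundTargetMap.from_pairs(pairs)


# --------------------------------------------------------------------------
# PPI edge tables


def gen_ppi_edges(
    proteins: Sequence[str],
    planted_hubs: Mapping[str, int],
    background_p: float,
    seed: int,
) -> pd.DataFrame:
    """Scored STRING-dialect edge table with planted high-degree hubs.

    Each planted hub is wired to its requested number of distinct
    partners; an Erdos-Renyi background with edge probability
    ``background_p`` is overlaid.  All combined scores are drawn in
    [400, 1000], so default-confidence filtering keeps every edge.  The
    final degree of a hub is therefore >= its planted degree.
    """
    if not 0 <= background_p <= 1:
        raise ValueError("background_p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    proteins = list(proteins)
    n = len(proteins)
    edges: dict[tuple[str, str], int] = {}

    def add(a: str, b: str) -> None:
        key = (a, b) if a < b else (b, a)
        if key not in edges:
            edges[key] = int(rng.integers(400, 1001))

    for hub in planted_hubs:
        degree = planted_hubs[hub]
        if hub not in proteins:
            raise ValueError(f"planted hub {hub!r} not in protein list")
        if degree > n - 1:
            raise ValueError(f"planted degree {degree} exceeds n-1 = {n - 1}")
        others = [p for p in proteins if p != hub]
        partners = rng.choice(others, size=degree, replace=False)
        for partner in partners:
            add(hub, partner)
    if background_p > 0:
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < background_p:
                    add(proteins[i], proteins[j])
    rows = [(a, b, s) for (a, b), s in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "combined_score"])


# --------------------------------------------------------------------------
# Expression matrices


def plant_expression_truth(
    n_genes: int,
    n_up: int,
    n_down: int,
    rescue_fraction: float,
    effect_fold: float = 8.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> SyntheticTruth:
    """Convenience: build a SyntheticTruth over a generic gene universe.

    The first ``n_up`` genes are planted up-altered, the next ``n_down``
    down-altered; round(rescue_fraction * n_altered) of them, balanced
    across directions proportionally, are planted rescued.
    """
    if n_up + n_down > n_genes:
        raise ValueError("altered genes exceed gene universe")
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    altered: dict[str, str] = {}
    for g in genes[:n_up]:
        altered[g] = "up"
    for g in genes[n_up : n_up + n_down]:
        altered[g] = "down"
    n_rescued = round(rescue_fraction * (n_up + n_down))
    n_res_up = min(n_up, round(rescue_fraction * n_up))
    n_res_down = min(n_down, n_rescued - n_res_up)
    rescued = frozenset(genes[:n_res_up] + genes[n_up : n_up + n_res_down])
    return SyntheticTruth(
        planted_altered=altered,
        planted_rescued=rescued,
        effect_fold=effect_fold,
        noise_sd=noise_sd,
        seed=seed,
    )


def gen_expression_matrix(
    n_genes: int, n_per_group: int, truth: SyntheticTruth
) -> ExpressionStudy:
    """Three-group expression study realising a planted truth.

    Baseline (sham) group means are log-uniform over [10, 1e4]; the model
    group multiplies altered genes by ``effect_fold`` (up) or its inverse
    (down); the treated group returns rescued genes to baseline and holds
    non-rescued altered genes at the model mean.  Per-sample values put
    multiplicative log-normal(0, noise_sd) noise on the group mean, so
    every value is strictly positive.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(truth.seed)
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    unknown = set(truth.planted_altered) - set(genes)
    if unknown:
        raise ValueError(
            f"planted genes outside the universe of {n_genes}: "
            f"{sorted(unknown)[:5]}"
        )

    base = 10.0 ** rng.uniform(1.0, 4.0, size=n_genes)
    up = np.array([truth.planted_altered.get(g) == "up" for g in genes])
    down = np.array([truth.planted_altered.get(g) == "down" for g in genes])
    res = np.array([g in truth.planted_rescued for g in genes])

    model_mean = base * np.where(up, truth.effect_fold, 1.0)
    model_mean = model_mean * np.where(down, 1.0 / truth.effect_fold, 1.0)
    treated_mean = np.where(res | ~(up | down), base, model_mean)

    def noisy(mean: np.ndarray, n: int) -> np.ndarray:
        draws = np.tile(mean[:, None], (1, n))
        if truth.noise_sd > 0:
            draws = draws * np.exp(
                rng.normal(0.0, truth.noise_sd, size=draws.shape)
            )
        return draws

    blocks = {
        BASELINE: noisy(base, n_per_group),
        MODEL: noisy(model_mean, n_per_group),
        TREATED: noisy(treated_mean, n_per_group),
    }
    columns: list[str] = []
    groups: dict[str, str] = {}
    data = []
    for role, block in blocks.items():
        for j in range(n_per_group):
            name = f"{role}_{j + 1}"
            columns.append(name)
            groups[name] = role
        data.append(block)
    values = pd.DataFrame(np.hstack(data), index=genes, columns=columns)
    return ExpressionStudy(values=values, groups=groups)


# --------------------------------------------------------------------------
# Behavioral trial logs


@dataclass(frozen=True)
class GroupTrials:
    """Synthetic trial logs for one experimental group."""

    maze: tuple[MazeTrial, ...]
    objects: tuple[ObjectTrial, ...]
    epm: tuple[EpmTrial, ...]
    planted_latencies: tuple[float, ...]


def gen_behavior_trials(
    n_mice: int,
    group_effects: Mapping[str, tuple[float, float, float]],
    seed: int,
    n_entries: int = 15,
) -> dict[str, GroupTrials]:
    """Trial logs per group with planted behavioral effect sizes.

    ``group_effects`` maps each group to (alternation_p, dr_mean,
    epm_entry_mean): the per-step probability that the next Y-maze entry
    completes an alternating triple, the expected discrimination ratio in
    percent, and the Poisson mean of closed-arm entry counts.
    """
    rng = np.random.default_rng(seed)
    arms = ("A", "B", "C")
    out: dict[str, GroupTrials] = {}
    for group, (alt_p, dr_mean, epm_mean) in group_effects.items():
        if not 0 <= alt_p <= 1:
            raise ValueError(f"alternation_p for {group!r} must lie in [0, 1]")
        if not 0 <= dr_mean <= 100:
            raise ValueError(f"dr_mean for {group!r} must lie in [0, 100]")
        maze, objects, epm, latencies = [], [], [], []
        for m in range(n_mice):
            mouse = f"{group}_m{m + 1:02d}"
            # Y-maze: alternate with probability alt_p at each step
            seq = [arms[rng.integers(3)]]
            seq.append(rng.choice([a for a in arms if a != seq[0]]))
            for _ in range(n_entries - 2):
                prev2, prev1 = seq[-2], seq[-1]
                options = [a for a in arms if a != prev1]
                third = [a for a in options if a != prev2]
                if prev2 != prev1 and third and rng.random() < alt_p:
                    seq.append(third[0])
                else:
                    non_alt = [a for a in options if a == prev2] or options
                    seq.append(rng.choice(non_alt))
            latency = float(rng.uniform(1.0, 30.0))
            gaps = rng.uniform(1.0, 5.0, size=n_entries - 1)
            times = latency + np.concatenate([[0.0], np.cumsum(gaps)])
            maze.append(
                MazeTrial(mouse=mouse, entries=tuple(seq),
                          timestamps=tuple(float(t) for t in times))
            )
            latencies.append(latency)
            # NORT: total exploration split by a Beta around dr_mean
            total = float(rng.uniform(20.0, 60.0))
            m_frac = dr_mean / 100.0
            if m_frac in (0.0, 1.0):
                frac = m_frac
            else:
                k = 20.0
                frac = float(rng.beta(k * m_frac, k * (1.0 - m_frac)))
            objects.append(
                ObjectTrial(mouse=mouse, novel_time=total * frac,
                            familiar_time=total * (1.0 - frac),
                            distance=float(rng.uniform(500.0, 1500.0)))
            )
            # EPM: Poisson closed-arm entries
            epm.append(
                EpmTrial(mouse=mouse,
                         closed_entries=int(rng.poisson(epm_mean)),
                         closed_time=float(rng.uniform(100.0, 250.0)),
                         open_entries=int(rng.poisson(max(epm_mean / 2, 0.0))),
                         open_time=float(rng.uniform(10.0, 60.0)))
            )
        out[group] = GroupTrials(
            maze=tuple(maze), objects=tuple(objects), epm=tuple(epm),
            planted_latencies=tuple(latencies),
        )
    return out
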