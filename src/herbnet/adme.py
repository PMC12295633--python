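"""ADME-based ingredient screening and cross-herb overlap accounting.

A multi-herb decoction is screened compound-by-compound: an ingredient
passes for a herb iff its oral bioavailability, drug-likeness and Caco-2
permeability all clear their (inclusive) cutoffs.  Because herbs share
compounds, the per-herb passing sets are then deduplicated into a unique
ingredient set, and ingredients occurring in two or more herbs are
reported as the overlap — the candidate joint effectors of the formula.
"""
from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Mapping

from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IngredientRecord:
    """One herb-attributed compound with its ADME screening properties."""

    herb: str
    ingredient: str
    ob: float  # oral bioavailability, percent
    dl: float  # drug-likeness, unitless 0-1
    caco2: float  # Caco-2 permeability, unitless, may be negative

    def __post_init__(self) -> None:
        if not self.herb or not self.ingredient:
            raise ValueError("herb and ingredient names must be nonempty")
        if self.ob < 0 or self.dl < 0:
            raise ValueError(
                f"negative OB/DL for {self.ingredient!r}: ob={self.ob}, dl={self.dl}"
            )


@dataclass(frozen=True)
class ScreenResult:
    """Per-herb passing sets plus the deduplicated union and overlap map."""

    passing: Mapping[str, frozenset[str]]
    unique_ingredients: frozenset[str]
    overlap: Mapping[str, frozenset[str]]  # ingredient -> herbs (>=2 only)

    @property
    def per_herb_counts(self) -> dict[str, int]:
        return {herb: len(names) for herb, names in self.passing.items()}


def normalize_name(name: str) -> str:
    """Whitespace-trimmed NFC form; the exact-match key for ingredient names."""
    return unicodedata.normalize("NFC", name.strip())


def record_passes(record: IngredientRecord, config: PipelineConfig) -> bool:
    """True iff all three ADME values clear their inclusive cutoffs."""
    thr = config.adme_thresholds
    return (
        record.ob >= thr.ob_min
        and record.dl >= thr.dl_min
        and record.caco2 >= thr.caco2_min
    )


def filter_ingredients(
    records: Iterable[IngredientRecord], config: PipelineConfig
) -> ScreenResult:
    """Screen records by ADME thresholds and compute the overlap structure.

    Pass/fail is evaluated per row; an ingredient enters a herb's passing
    set if any of its rows for that herb passes (databases occasionally
    carry duplicated rows with divergent ADME values).

    Parameters
    ----------
    records : iterable of IngredientRecord
        Must be nonempty.
    config : PipelineConfig
        Supplies ``adme_thresholds``.

    Returns
    -------
    ScreenResult
        With ``unique_ingredients`` equal to the union of the per-herb
        passing sets and ``overlap`` restricted to ingredients passing in
        two or more herbs.
    """
    records = list(records)
    if not records:
        raise ValueError("filter_ingredients requires at least one record")
    passing: dict[str, set[str]] = {}
    n_pass = 0
    for rec in records:
        herb = normalize_name(rec.herb)
        passing.setdefault(herb, set())
        if record_passes(rec, config):
            passing[herb].add(normalize_name(rec.ingredient))
            n_pass += 1
    frozen = {herb: frozenset(names) for herb, names in passing.items()}
    result = ScreenResult(
        passing=frozen,
        unique_ingredients=dedupe_union(frozen),
        overlap=overlap_ingredients(frozen),
    )
    logger.info(
        "ADME screen: %d rows in, %d passing rows, %d unique passing "
        "ingredients, %d overlapping (thresholds OB>=%s DL>=%s Caco-2>=%s)",
        len(records),
        n_pass,
        len(result.unique_ingredients),
        len(result.overlap),
        config.adme_thresholds.ob_min,
        config.adme_thresholds.dl_min,
        config.adme_thresholds.caco2_min,
    )
    return result


def dedupe_union(per_herb_sets: Mapping[str, Iterable[str]]) -> frozenset[str]:
    """Deduplicated union of per-herb ingredient name sets."""
    out: set[str] = set()
    for names in per_herb_sets.values():
        out.update(names)
    return frozenset(out)


def overlap_ingredients(
    per_herb_sets: Mapping[str, Iterable[str]]
) -> dict[str, frozenset[str]]:
    """Map each ingredient present in >=2 herbs to its full herb membership."""
    membership: dict[str, set[str]] = {}
    for herb, names in per_herb_sets.items():
        for name in names:
            membership.setdefault(name, set()).add(herb)
    return {
        name: frozenset(herbs)
        for name, herbs in membership.items()
        if len(herbs) >= 2
    }
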