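"""Compound -> target-protein mapping and the bipartite target network."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompoundTargetMap:
    """Many-to-many relation between compounds and target protein symbols.

    ``compounds`` and ``targets`` are exactly the projections of ``pairs``;
    duplicate pairs are collapsed on construction.
    """

    pairs: frozenset[tuple[str, str]]
    unmatched_compounds: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        unmatched: Iterable[str] = (),
    ) -> "CompoundTargetMap":
        return cls(
            pairs=frozenset((c.strip(), t.strip()) for c, t in pairs),
            unmatched_compounds=frozenset(unmatched),
        )

    @property
    def compounds(self) -> frozenset[str]:
        return frozenset(c for c, _ in self.pairs)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.pairs)

    def targets_of(self, compound: str) -> frozenset[str]:
        return frozenset(t for c, t in self.pairs if c == compound)


def map_targets(
    compounds: Iterable[str], lookup: CompoundTargetMap
) -> CompoundTargetMap:
    """Restrict a compound->target lookup to the given compound set.

    Compounds with no entry in the lookup are retained in
    ``unmatched_compounds`` rather than raised: exported target tables are
    routinely incomplete.  Idempotent — restricting twice equals once.
    """
    wanted = {c.strip() for c in compounds}
    pairs = frozenset(p for p in lookup.pairs if p[0] in wanted)
    matched = {c for c, _ in pairs}
    unmatched = frozenset(wanted - matched)
    result = CompoundTargetMap(pairs=pairs, unmatched_compounds=unmatched)
    logger.info(
        "target mapping: %d compounds queried, %d matched, %d unmatched, "
        "%d pairs, %d distinct targets",
        len(wanted), len(matched), len(unmatched), len(pairs),
        len(result.targets),
    )
    return result


def rank_compounds_by_target_count(
    ctmap: CompoundTargetMap,
) -> list[tuple[str, int]]:
    """Compounds ordered by descending target count, ties lexicographic.

    Compounds known to the map but matching zero targets appear with
    count 0 at the end.
    """
    counts: dict[str, int] = {c: 0 for c in ctmap.unmatched_compounds}
    for compound, _ in ctmap.pairs:
        counts[compound] = counts.get(compound, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
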