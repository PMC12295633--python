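"""Symbol-level concordance between predicted and observed target proteins.

Network-pharmacology predictions arrive as human-style symbols (EGF)
while rodent transcriptomic hits use mouse-style capitalisation (Egf);
the default matching rule is therefore case-insensitive equality after
trimming, a pragmatic cross-species proxy.  An exact rule and a
user-supplied two-column ortholog table are available as alternatives.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .ppi import HubRanking


@dataclass(frozen=True)
class ConcordanceResult:
    predicted: frozenset[str]
    observed: frozenset[str]
    common: tuple[tuple[str, str], ...]  # (predicted symbol, observed symbol)
    jaccard: float


def _key(symbol: str, rule: str) -> str:
    s = symbol.strip()
    return s if rule == "exact" else s.casefold()


def match_symbols(
    predicted: Iterable[str],
    observed: Iterable[str],
    rule: str = "case-insensitive",
    ortholog_map: Mapping[str, str] | None = None,
) -> ConcordanceResult:
    """Match two symbol sets under the chosen rule.

    ``rule`` is "case-insensitive" (default) or "exact".  If an
    ``ortholog_map`` (predicted symbol -> observed symbol) is given it is
    applied to the predicted side before matching, under the same rule.
    Each observed symbol matches at most one predicted symbol (first by
    sorted predicted order).  Jaccard = |common| / |predicted U observed|
    counting union size under the matching rule.
    """
    if rule not in ("case-insensitive", "exact"):
        raise ValueError(f"unknown matching rule {rule!r}")
    pred = frozenset(s.strip() for s in predicted)
    obs = frozenset(s.strip() for s in observed)

    obs_by_key: dict[str, str] = {}
    for o in sorted(obs):
        obs_by_key.setdefault(_key(o, rule), o)

    common: list[tuple[str, str]] = []
    taken: set[str] = set()
    for p in sorted(pred):
        translated = ortholog_map.get(p, p) if ortholog_map else p
        k = _key(translated, rule)
        if k in obs_by_key and k not in taken:
            common.append((p, obs_by_key[k]))
            taken.add(k)

    pred_keys = {_key((ortholog_map.get(p, p) if ortholog_map else p), rule)
                 for p in pred}
    union = len(pred_keys | set(obs_by_key))
    jaccard = len(common) / union if union else 0.0
    return ConcordanceResult(
        predicted=pred, observed=obs, common=tuple(common), jaccard=jaccard
    )


def rank_concordant_hubs(
    result: ConcordanceResult, ranking: HubRanking
) -> list[tuple[str, str, int | None]]:
    """Order the common proteins by their degree in the observed-side PPI.

    Returns (predicted symbol, observed symbol, degree) tuples sorted by
    descending degree, ties lexicographic on the observed symbol; common
    proteins absent from the ranking are listed last with degree None.
    """
    degree_of = dict(ranking.ranked)
    present = [(p, o, degree_of[o]) for p, o in result.common if o in degree_of]
    absent = [(p, o, None) for p, o in result.common if o not in degree_of]
    present.sort(key=lambda t: (-t[2], t[1]))
    absent.sort(key=lambda t: t[1])
    return present + absent
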