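"""Exclusive-region set overlap (Venn partition) for regulated gene/pathway sets.

Given 2-8 named item sets, every item in the union is assigned to exactly
one region — the subset of set names it belongs to — so region counts sum to
the union size.  Items are normalised (trimmed, optionally case-folded)
before comparison and the normalisation map is reported, because labels
exported from different tools differ in whitespace and case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

__all__ = ["VennResult", "set_overlap", "shared_specific"]


@dataclass(frozen=True)
class VennResult:
    set_names: tuple[str, ...]
    regions: dict[frozenset, tuple[str, ...]]  # membership pattern -> exclusive items
    normalization_map: dict[str, str] = field(default_factory=dict)

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def region(self, *names: str) -> tuple[str, ...]:
        """Items exclusive to exactly this combination of sets."""
        return self.regions.get(frozenset(names), ())


def _normalize_item(item: str, case: str) -> str:
    out = str(item).strip()
    if case == "upper":
        out = out.upper()
    elif case == "casefold":
        out = out.casefold()
    elif case != "none":
        raise ValueError("case must be 'none', 'upper' or 'casefold'")
    return out


def set_overlap(named_sets: Mapping[str, Iterable[str]], case: str = "none") -> VennResult:
    """Exact exclusive-region partition of 2-8 named sets.

    ``case``: 'none' (default, trim only — suitable within one species whose
    symbol casing is already consistent), 'upper' or 'casefold' for
    cross-export comparisons.  Region items are sorted for determinism.
    """
    names = tuple(named_sets.keys())
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    if not 2 <= len(names) <= 8:
        raise ValueError(f"need between 2 and 8 sets, got {len(names)}")
    norm_map: dict[str, str] = {}
    normed: dict[str, set[str]] = {}
    for name in names:
        items = set()
        for item in named_sets[name]:
            norm = _normalize_item(item, case)
            if norm != str(item):
                norm_map[str(item)] = norm
            items.add(norm)
        normed[name] = items
    membership: dict[str, frozenset] = {}
    for item in set().union(*normed.values()):
        membership[item] = frozenset(n for n in names if item in normed[n])
    regions: dict[frozenset, list[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = []
    for item, pattern in membership.items():
        regions[pattern].append(item)
    return VennResult(
        set_names=names,
        regions={k: tuple(sorted(v)) for k, v in regions.items()},
        normalization_map=norm_map,
    )


def shared_specific(venn: VennResult, focus: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(items exclusive to ``focus``, items of ``focus`` shared with any other set)."""
    if focus not in venn.set_names:
        raise ValueError(f"unknown set {focus!r}; sets are {venn.set_names}")
    specific = venn.regions.get(frozenset([focus]), ())
    shared: list[str] = []
    for pattern, items in venn.regions.items():
        if focus in pattern and len(pattern) > 1:
            shared.extend(items)
    return specific, tuple(sorted(shared))
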