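"""Static gene panels: the 61-regulator Th-subset catalog and auxiliary gene sets.

The catalog covers eight CD4+ T-helper lineages (Th1, Th2, Th9, Tfh, Th17,
Treg, Th22, Th25).  Each regulator carries a functional category (master
transcription factor, cytokine, receptor, ...) and the non-empty set of
subsets it regulates; one gene may serve several subsets (e.g. IL2 drives
Th1, Th2, Th9 and Treg) and is stored once with a subset set rather than as
duplicated rows.

Symbols are stored exactly as printed in the source tables, including their
misspellings; ``load_aliases`` exposes a correction map (e.g. GADPH -> GAPDH)
that is never applied silently.  See ``data/CHANGELOG.md`` for the full
transcription record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "SUBSETS",
    "CATEGORIES",
    "Regulator",
    "RegulatorCatalog",
    "GeneSet",
    "load_regulator_catalog",
    "regulators_for_subset",
    "load_gene_set",
    "load_aliases",
]

SUBSETS = ("Th1", "Th2", "Th9", "Tfh", "Th17", "Treg", "Th22", "Th25")
CATEGORIES = (
    "transcription_factor",
    "transcription_activator",
    "transcription_repressor",
    "signal_transducer",
    "cytokine",
    "lineage_factor",
    "receptor",
    "other",
)

_GENE_SET_NAMES = ("mhc2_mouse", "cosignal_partial", "housekeeping_human", "housekeeping_mouse")


def _data_text(name: str) -> str:
    ref = resources.files("thprof.data").joinpath(name)
    try:
        return ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise RuntimeError(f"packaged fixture {name!r} is missing or corrupt") from exc


@dataclass(frozen=True)
class Regulator:
    """One Th-subset regulator gene."""

    symbol: str
    common_name: str
    unigene_human: str | None
    unigene_mouse: str | None
    category: str
    subsets: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.symbol}")
        if not self.subsets:
            raise ValueError(f"regulator {self.symbol} has an empty subset set")
        bad = set(self.subsets) - set(SUBSETS)
        if bad:
            raise ValueError(f"unknown subset(s) {sorted(bad)} for {self.symbol}")


@dataclass(frozen=True)
class RegulatorCatalog:
    """Ordered collection of regulators for one species."""

    entries: tuple[Regulator, ...]
    species: str

    def __post_init__(self) -> None:
        if self.species not in ("human", "mouse"):
            raise ValueError(f"species must be 'human' or 'mouse', got {self.species!r}")
        symbols = [r.symbol for r in self.entries]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate symbols in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self.entries)

    def __getitem__(self, symbol: str) -> Regulator:
        for r in self.entries:
            if r.symbol == symbol:
                return r
        raise KeyError(symbol)

    def category_histogram(self) -> dict[str, int]:
        hist: dict[str, int] = {}
        for r in self.entries:
            hist[r.category] = hist.get(r.category, 0) + 1
        return hist

    def subset_map(self) -> dict[str, tuple[str, ...]]:
        """Subset code -> symbols of regulators mapped to it (fixture order)."""
        return {s: tuple(r.symbol for r in self.entries if s in r.subsets) for s in SUBSETS}


@dataclass(frozen=True)
class GeneSet:
    """Named ordered gene set with optional per-gene directionality notes."""

    name: str
    genes: tuple[str, ...]
    description: str = ""
    complete: bool = True
    directionality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes


def _mouse_case(symbol: str) -> str:
    # mouse symbol convention: initial capital, rest lower (Foxp3, Il12rb1, ...)
    return symbol[:1].upper() + symbol[1:].lower()


def load_regulator_catalog(species: str = "human") -> RegulatorCatalog:
    """Load the packaged 61-regulator catalog.

    Parameters
    ----------
    species : {'human', 'mouse'}
        Symbol casing convention: human symbols are kept as printed
        (upper-case); mouse symbols are title-cased (FOXP3 -> Foxp3).
    """
    if species not in ("human", "mouse"):
        raise ValueError(f"species must be 'human' or 'mouse', got {species!r}")
    records = json.loads(_data_text("regulator_catalog.json"))
    entries = []
    for rec in records:
        sym = rec["symbol"] if species == "human" else _mouse_case(rec["symbol"])
        entries.append(
            Regulator(
                symbol=sym,
                common_name=rec["common_name"],
                unigene_human=rec["unigene_human"],
                unigene_mouse=rec["unigene_mouse"],
                category=rec["category"],
                subsets=frozenset(rec["subsets"]),
            )
        )
    return RegulatorCatalog(entries=tuple(entries), species=species)


def regulators_for_subset(catalog: RegulatorCatalog, subset: str) -> list[Regulator]:
    """All regulators mapped to ``subset``, in fixture order."""
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    return [r for r in catalog.entries if subset in r.subsets]


def load_gene_set(name: str) -> GeneSet:
    """Load a packaged gene set by name.

    Known names: ``mhc2_mouse`` (14 MHC class II molecules),
    ``cosignal_partial`` (incomplete co-signaling receptor panel),
    ``housekeeping_human``, ``housekeeping_mouse``.
    """
    if name not in _GENE_SET_NAMES:
        raise ValueError(f"unknown gene set {name!r}; expected one of {_GENE_SET_NAMES}")
    rec = json.loads(_data_text("gene_sets.json"))[name]
    return GeneSet(
        name=name,
        genes=tuple(rec["genes"]),
        description=rec.get("description", ""),
        complete=rec.get("complete", True),
        directionality=rec.get("directionality", {}),
    )


def load_aliases() -> dict[str, str]:
    """Printed-symbol -> official-symbol correction map (informational only)."""
    return json.loads(_data_text("symbol_aliases.json"))


def catalog_to_frame(catalog: RegulatorCatalog):
    """Catalog as a pandas DataFrame (one row per regulator)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "symbol": [r.symbol for r in catalog],
            "common_name": [r.common_name for r in catalog],
            "category": [r.category for r in catalog],
            "subsets": [",".join(s for s in SUBSETS if s in r.subsets) for r in catalog],
        }
    )
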