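"""Aggregate per-gene calls into per-tissue Th-subset summaries.

Builds the tissue-level views of the call matrix: per-(tissue, subset)
expression tallies, per-gene tissue counts, a "tissue pyramid" ranking
tissues by the variety of subsets they highly express, per-tissue dominance
scores, and candidate immune-privilege flags for tissues with essentially no
resident Th-subset activity.

Multi-subset regulators contribute to every subset they map to.  All counts
use *measured* regulators only — catalog genes absent from the call matrix
do not enter denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalogs import SUBSETS, RegulatorCatalog
from .profiling import CALL_EXPRESSED, CALL_HIGH, CallMatrix

__all__ = [
    "SubsetSummary",
    "DominanceReport",
    "summarize_subsets",
    "count_expression",
    "tissue_pyramid",
    "dominant_subsets",
    "immune_privilege_flags",
]


@dataclass(frozen=True)
class SubsetSummary:
    tissue: str
    subset: str
    n_regulators: int
    n_expressed: int  # EXPRESSED or HIGH
    n_high: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_high <= self.n_expressed <= self.n_regulators:
            raise ValueError(
                f"inconsistent counts for ({self.tissue}, {self.subset}): "
                f"high={self.n_high}, expressed={self.n_expressed}, total={self.n_regulators}"
            )

    @property
    def fraction_high(self) -> float:
        return self.n_high / self.n_regulators if self.n_regulators else 0.0

    @property
    def fraction_expressed(self) -> float:
        return self.n_expressed / self.n_regulators if self.n_regulators else 0.0


@dataclass(frozen=True)
class DominanceReport:
    tissue: str
    dominant_subsets: tuple[str, ...]
    scores: dict[str, float]


def summarize_subsets(calls: CallMatrix, catalog: RegulatorCatalog) -> list[SubsetSummary]:
    """One summary per (tissue, subset) pair.

    A regulator mapped to k subsets is tallied in all k of them.  Emits an
    empty list (with a warning) when no catalog gene is measured.
    """
    measured = [g for g in catalog.symbols if g in calls.data.index]
    if not measured:
        import warnings

        warnings.warn("no catalog regulator present in the call matrix; empty summary")
        return []
    subset_map = catalog.subset_map()
    out: list[SubsetSummary] = []
    for tissue in calls.tissues:
        col = calls.data[tissue]
        for subset in SUBSETS:
            genes = [g for g in subset_map[subset] if g in calls.data.index]
            vals = col.loc[genes]
            n_high = int((vals == CALL_HIGH).sum())
            n_expr = int(vals.isin([CALL_EXPRESSED, CALL_HIGH]).sum())
            out.append(SubsetSummary(tissue, subset, len(genes), n_expr, n_high))
    return out


def summaries_to_frame(summaries: list[SubsetSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tissue": [s.tissue for s in summaries],
            "subset": [s.subset for s in summaries],
            "n_regulators": [s.n_regulators for s in summaries],
            "n_expressed": [s.n_expressed for s in summaries],
            "n_high": [s.n_high for s in summaries],
            "fraction_high": [s.fraction_high for s in summaries],
        }
    )


def count_expression(calls: CallMatrix, gene: str) -> tuple[int, int]:
    """(tissues with EXPRESSED or HIGH, tissues with HIGH) for one gene."""
    if gene not in calls.data.index:
        raise ValueError(f"gene {gene!r} absent from the call matrix")
    row = calls.data.loc[gene]
    n_expressed = int(row.isin([CALL_EXPRESSED, CALL_HIGH]).sum())
    n_high = int((row == CALL_HIGH).sum())
    return n_expressed, n_high


def tissue_pyramid(summaries: list[SubsetSummary]) -> pd.DataFrame:
    """Rank tissues by the variety of subsets with at least one HIGH regulator.

    Descending by number of subsets with >=1 HIGH call; ties broken by number
    of subsets with >=1 expressed regulator (descending), then tissue name
    (ascending) for a deterministic total order.
    """
    per_tissue: dict[str, list[int]] = {}
    for s in summaries:
        rec = per_tissue.setdefault(s.tissue, [0, 0])
        if s.n_high > 0:
            rec[0] += 1
        if s.n_expressed > 0:
            rec[1] += 1
    rows = sorted(per_tissue.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))
    return pd.DataFrame(
        {
            "tissue": [t for t, _ in rows],
            "n_subsets_high": [c[0] for _, c in rows],
            "n_subsets_expressed": [c[1] for _, c in rows],
        }
    )


def dominant_subsets(summaries: list[SubsetSummary], tissue: str,
                     normalized: bool = True) -> DominanceReport:
    """Subsets with the maximal dominance score in one tissue.

    The score is size-normalised by default — the fraction of a subset's
    measured regulators called HIGH — because subset panels differ widely in
    size (1 to ~20 genes).  ``normalized=False`` scores by raw HIGH counts.
    Returns an empty dominant set when all scores are zero.
    """
    rows = [s for s in summaries if s.tissue == tissue]
    if not rows:
        raise ValueError(f"tissue {tissue!r} absent from the summaries")
    scores = {
        s.subset: (s.fraction_high if normalized else float(s.n_high)) for s in rows
    }
    best = max(scores.values())
    if best == 0:
        return DominanceReport(tissue, (), scores)
    dominant = tuple(s for s in SUBSETS if s in scores and scores[s] == best)
    return DominanceReport(tissue, dominant, scores)


def immune_privilege_flags(summaries: list[SubsetSummary], min_high: int = 0,
                           max_expressed_fraction: float = 0.6) -> list[str]:
    """Tissues with no/very low resident Th-subset activity.

    A tissue is flagged a candidate immune-privilege site when its total HIGH
    count across all subsets is <= ``min_high`` and the fraction of measured
    regulator slots expressed is below ``max_expressed_fraction``.  The
    defaults are a declared convention calibrated on the packaged human
    reference matrix, not a published rule.
    """
    per_tissue: dict[str, list[int]] = {}
    for s in summaries:
        rec = per_tissue.setdefault(s.tissue, [0, 0, 0])
        rec[0] += s.n_high
        rec[1] += s.n_expressed
        rec[2] += s.n_regulators
    return sorted(
        t for t, (high, expr, total) in per_tissue.items()
        if high <= min_high and total > 0 and expr / total < max_expressed_fraction
    )
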