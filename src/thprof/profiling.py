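"""Trichotomous expression calling against a housekeeping-gene threshold.

The procedure mirrors classic EST-profile mining of gene x tissue
transcripts-per-million (TPM) tables:

1. every gene's TPM is divided by beta-actin's TPM in the same tissue,
   giving dimensionless *arbitrary units* (AU);
2. an upper limit is estimated from a fixed housekeeping panel as
   ``mean(AU_hk) + 2 * sd(AU_hk)`` (sample SD, n-1 denominator) — either one
   pooled limit over all tissues (default) or one per tissue;
3. each cell is called ``NONE`` when TPM < 1 (transcripts rarer than one per
   million are treated as not expressed), ``HIGH`` when AU strictly exceeds
   the upper limit, and ``EXPRESSED`` otherwise.

Ties fall to the lower category (TPM exactly 1 is expressed; AU exactly at
the limit is not high).  Cells missing from a tissue library are treated as
TPM 0 and therefore NONE; this is flagged in provenance, since EST absence is
indistinguishable from non-expression.

:class:`ExpressionCaller` packages steps 1-3 as a scikit-learn style
estimator (``fit`` learns the threshold, ``predict`` labels cells); the
module functions are thin wrappers kept for pipeline scripting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .catalogs import load_gene_set

__all__ = [
    "CALL_NONE",
    "CALL_EXPRESSED",
    "CALL_HIGH",
    "CALL_TOKENS",
    "ExpressionTable",
    "ArbitraryUnitTable",
    "HousekeepingThreshold",
    "CallMatrix",
    "ExpressionCaller",
    "normalize_arbitrary_units",
    "housekeeping_threshold",
    "call_expression",
    "profile_pipeline",
    "load_reference_call_matrix",
]

CALL_NONE = "NONE"
CALL_EXPRESSED = "EXPRESSED"
CALL_HIGH = "HIGH"
CALL_TOKENS = {CALL_NONE: "-", CALL_EXPRESSED: "+", CALL_HIGH: "++"}
_TOKEN_CALLS = {v: k for k, v in CALL_TOKENS.items()}

DEFAULT_REF_GENE = "ACTB"
DEFAULT_TPM_FLOOR = 1.0


def _check_axes(df: pd.DataFrame, what: str) -> None:
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene labels in {what}: {dupes}")
    if df.columns.has_duplicates:
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"duplicate tissue labels in {what}: {dupes}")


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x tissue TPM matrix (non-negative, unique labels)."""

    data: pd.DataFrame
    species: str = "human"

    def __post_init__(self) -> None:
        _check_axes(self.data, "expression table")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("expression table contains missing values; fill absent cells with 0")
        if (values < 0).any():
            bad = self.data.columns[(values < 0).any(axis=0)].tolist()
            raise ValueError(f"negative TPM values in tissue(s) {bad}")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def tissues(self) -> list[str]:
        return self.data.columns.tolist()


@dataclass(frozen=True)
class ArbitraryUnitTable:
    """Reference-normalised expression: AU(g,t) = TPM(g,t) / TPM(ref,t)."""

    data: pd.DataFrame
    ref_gene: str

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def tissues(self) -> list[str]:
        return self.data.columns.tolist()


@dataclass(frozen=True)
class HousekeepingThreshold:
    """mean + 2*SD upper limit of housekeeping AU values.

    ``scope='pooled'`` gives one scalar limit over all tissues;
    ``scope='per_tissue'`` gives one limit per tissue (pd.Series).
    """

    scope: str
    mean: float | pd.Series
    sd: float | pd.Series
    upper: float | pd.Series
    hk_genes: tuple[str, ...]

    def upper_for(self, tissues: Sequence[str]) -> np.ndarray:
        """Upper limit aligned to ``tissues`` as a 1-D array."""
        if self.scope == "pooled":
            return np.full(len(tissues), float(self.upper))
        missing = [t for t in tissues if t not in self.upper.index]
        if missing:
            raise ValueError(f"threshold has no limit for tissue(s) {missing}")
        return self.upper.reindex(tissues).to_numpy(dtype=float)


@dataclass(frozen=True)
class CallMatrix:
    """Gene x tissue matrix of trichotomous calls plus provenance."""

    data: pd.DataFrame  # values in {NONE, EXPRESSED, HIGH}
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_axes(self.data, "call matrix")
        bad = set(np.unique(self.data.to_numpy())) - {CALL_NONE, CALL_EXPRESSED, CALL_HIGH}
        if bad:
            raise ValueError(f"invalid call value(s): {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def tissues(self) -> list[str]:
        return self.data.columns.tolist()

    def to_symbols(self, tokens: dict[str, str] | None = None) -> pd.DataFrame:
        """Render as a symbol matrix with the -, +, ++ tokens."""
        tokens = tokens or CALL_TOKENS
        return self.data.replace(tokens)

    @classmethod
    def from_symbols(cls, symbols: pd.DataFrame, provenance: dict | None = None,
                     tokens: dict[str, str] | None = None) -> "CallMatrix":
        rev = {v: k for k, v in (tokens or CALL_TOKENS).items()}
        bad = set(np.unique(symbols.to_numpy().astype(str))) - set(rev)
        if bad:
            raise ValueError(f"unknown call token(s): {sorted(bad)}")
        return cls(data=symbols.replace(rev), provenance=provenance or {})


class ExpressionCaller(BaseEstimator):
    """Trichotomous expression caller with a learned housekeeping threshold.

    Parameters
    ----------
    ref_gene : str, default 'ACTB'
        Reference gene whose TPM defines the arbitrary-unit denominator.
    hk_genes : sequence of str or {'human', 'mouse'}, default 'human'
        Housekeeping panel for the mean+2SD limit; a species name loads the
        packaged three-gene panel.
    scope : {'pooled', 'per_tissue'}, default 'pooled'
        One global limit from all housekeeping AU values, or one per tissue.
    tpm_floor : float, default 1.0
        TPM below this is called NONE regardless of AU.
    ddof : int, default 1
        SD denominator degrees of freedom (1 = sample SD).

    Attributes
    ----------
    au_ : pd.DataFrame
        Arbitrary units of the fitted table.
    threshold_ : HousekeepingThreshold
        The learned upper limit.
    hk_genes_ : tuple of str
        Resolved housekeeping panel.
    """

    def __init__(self, ref_gene: str = DEFAULT_REF_GENE, hk_genes="human",
                 scope: str = "pooled", tpm_floor: float = DEFAULT_TPM_FLOOR,
                 ddof: int = 1):
        self.ref_gene = ref_gene
        self.hk_genes = hk_genes
        self.scope = scope
        self.tpm_floor = tpm_floor
        self.ddof = ddof

    # -- helpers -----------------------------------------------------------
    def _resolve_hk(self) -> tuple[str, ...]:
        if isinstance(self.hk_genes, str):
            return tuple(load_gene_set(f"housekeeping_{self.hk_genes}").genes)
        return tuple(self.hk_genes)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, ExpressionTable):
            return X.data
        if isinstance(X, pd.DataFrame):
            ExpressionTable(X)  # runs validation
            return X
        raise TypeError("X must be a gene x tissue DataFrame or ExpressionTable")

    def _normalize(self, tpm: pd.DataFrame) -> pd.DataFrame:
        if self.ref_gene not in tpm.index:
            raise ValueError(f"reference gene {self.ref_gene!r} absent from table")
        ref = tpm.loc[self.ref_gene]
        zero = ref.index[ref.to_numpy(dtype=float) <= 0].tolist()
        if zero:
            raise ValueError(
                f"reference gene {self.ref_gene!r} has zero TPM in tissue(s) {zero}; "
                "arbitrary units are undefined there (no silent imputation)"
            )
        return tpm.div(ref, axis=1)

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y=None):
        """Compute arbitrary units and the housekeeping mean+2SD limit."""
        if self.scope not in ("pooled", "per_tissue"):
            raise ValueError(f"scope must be 'pooled' or 'per_tissue', got {self.scope!r}")
        tpm = self._as_frame(X)
        hk = self._resolve_hk()
        missing = [g for g in hk if g not in tpm.index]
        if missing:
            raise ValueError(f"housekeeping gene(s) absent from table: {missing}")
        au = self._normalize(tpm)
        hk_au = au.loc[list(hk)]
        if self.scope == "pooled":
            values = hk_au.to_numpy(dtype=float).ravel()
            values = values[np.isfinite(values)]
            if values.size < 2:
                raise ValueError("fewer than 2 usable housekeeping AU values; threshold degenerate")
            mean = float(values.mean())
            sd = float(values.std(ddof=self.ddof))
            thr = HousekeepingThreshold("pooled", mean, sd, mean + 2.0 * sd, hk)
        else:
            if len(hk) < 2:
                raise ValueError("per-tissue scope needs at least 2 housekeeping genes")
            mean = hk_au.mean(axis=0)
            sd = hk_au.std(axis=0, ddof=self.ddof)
            thr = HousekeepingThreshold("per_tissue", mean, sd, mean + 2.0 * sd, hk)
        self.hk_genes_ = hk
        self.au_ = au
        self.threshold_ = thr
        self.n_features_in_ = tpm.shape[1]
        return self

    def predict(self, X) -> pd.DataFrame:
        """Label every cell of a TPM table with NONE / EXPRESSED / HIGH."""
        if not hasattr(self, "threshold_"):
            raise RuntimeError("ExpressionCaller is not fitted; call fit() first")
        tpm = self._as_frame(X)
        au = self._normalize(tpm)
        upper = self.threshold_.upper_for(au.columns)
        t = tpm.to_numpy(dtype=float)
        a = au.to_numpy(dtype=float)
        calls = np.where(t < self.tpm_floor, CALL_NONE,
                         np.where(a > upper[np.newaxis, :], CALL_HIGH, CALL_EXPRESSED))
        return pd.DataFrame(calls, index=tpm.index, columns=tpm.columns)

    def fit_predict(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).predict(X)


# -- functional wrappers ---------------------------------------------------

def normalize_arbitrary_units(table: ExpressionTable | pd.DataFrame,
                              ref_gene: str = DEFAULT_REF_GENE) -> ArbitraryUnitTable:
    """Divide each tissue column by the reference gene's TPM in that tissue."""
    caller = ExpressionCaller(ref_gene=ref_gene)
    tpm = caller._as_frame(table)
    return ArbitraryUnitTable(data=caller._normalize(tpm), ref_gene=ref_gene)


def housekeeping_threshold(au: ArbitraryUnitTable | pd.DataFrame,
                           hk_genes: Sequence[str],
                           scope: str = "pooled",
                           ddof: int = 1) -> HousekeepingThreshold:
    """mean + 2*SD limit of the housekeeping genes' AU values."""
    au_df = au.data if isinstance(au, ArbitraryUnitTable) else au
    if scope not in ("pooled", "per_tissue"):
        raise ValueError(f"scope must be 'pooled' or 'per_tissue', got {scope!r}")
    hk = tuple(hk_genes)
    missing = [g for g in hk if g not in au_df.index]
    if missing:
        raise ValueError(f"housekeeping gene(s) absent: {missing}")
    hk_au = au_df.loc[list(hk)]
    if scope == "pooled":
        values = hk_au.to_numpy(dtype=float).ravel()
        values = values[np.isfinite(values)]
        if values.size < 2:
            raise ValueError("fewer than 2 usable housekeeping AU values; threshold degenerate")
        mean = float(values.mean())
        sd = float(values.std(ddof=ddof))
        return HousekeepingThreshold("pooled", mean, sd, mean + 2.0 * sd, hk)
    if len(hk) < 2:
        raise ValueError("per-tissue scope needs at least 2 housekeeping genes")
    mean = hk_au.mean(axis=0)
    sd = hk_au.std(axis=0, ddof=ddof)
    return HousekeepingThreshold("per_tissue", mean, sd, mean + 2.0 * sd, hk)


def call_expression(table: ExpressionTable | pd.DataFrame,
                    au: ArbitraryUnitTable | pd.DataFrame,
                    thr: HousekeepingThreshold,
                    tpm_floor: float = DEFAULT_TPM_FLOOR) -> CallMatrix:
    """Apply the two calling rules cell-by-cell.

    TPM below ``tpm_floor`` -> NONE; otherwise AU strictly above the upper
    limit -> HIGH; otherwise EXPRESSED.
    """
    tpm_df = table.data if isinstance(table, ExpressionTable) else table
    au_df = au.data if isinstance(au, ArbitraryUnitTable) else au
    if list(tpm_df.index) != list(au_df.index) or list(tpm_df.columns) != list(au_df.columns):
        raise ValueError("TPM and AU tables must share identical gene and tissue axes")
    upper = thr.upper_for(tpm_df.columns)
    t = tpm_df.to_numpy(dtype=float)
    a = au_df.to_numpy(dtype=float)
    calls = np.where(t < tpm_floor, CALL_NONE,
                     np.where(a > upper[np.newaxis, :], CALL_HIGH, CALL_EXPRESSED))
    prov = {
        "rule": "tpm<floor->NONE; au>upper->HIGH; else EXPRESSED (strict inequalities)",
        "tpm_floor": tpm_floor,
        "scope": thr.scope,
        "hk_genes": list(thr.hk_genes),
    }
    return CallMatrix(data=pd.DataFrame(calls, index=tpm_df.index, columns=tpm_df.columns),
                      provenance=prov)


def profile_pipeline(table: ExpressionTable | pd.DataFrame,
                     ref_gene: str = DEFAULT_REF_GENE,
                     hk_genes="human",
                     scope: str = "pooled",
                     tpm_floor: float = DEFAULT_TPM_FLOOR) -> CallMatrix:
    """Normalise, learn the housekeeping limit, and call every cell."""
    caller = ExpressionCaller(ref_gene=ref_gene, hk_genes=hk_genes, scope=scope,
                              tpm_floor=tpm_floor)
    calls = caller.fit_predict(table)
    thr = caller.threshold_
    prov = {
        "ref_gene": ref_gene,
        "hk_genes": list(caller.hk_genes_),
        "scope": scope,
        "tpm_floor": tpm_floor,
        "threshold_upper": thr.upper if thr.scope == "pooled" else thr.upper.to_dict(),
        "rule": "tpm<floor->NONE; au>upper->HIGH; else EXPRESSED (strict inequalities)",
        "missing_cells_policy": "absent gene/tissue cells must be pre-filled as TPM 0 -> NONE",
    }
    return CallMatrix(data=calls, provenance=prov)


def load_reference_call_matrix() -> CallMatrix:
    """The packaged curated human 56-gene x 32-tissue call matrix.

    A transcription of the published symbol matrix (see data/CHANGELOG.md for
    the transcription record); shipped so per-gene tissue counts are testable
    without the retired source database.
    """
    from io import StringIO

    from .catalogs import _data_text

    symbols = pd.read_csv(StringIO(_data_text("table2_calls.tsv")), sep="\t",
                          index_col=0, dtype=str)
    return CallMatrix.from_symbols(symbols, provenance={"source": "packaged curated fixture"})
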