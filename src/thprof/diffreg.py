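"""Case-vs-control regulation: signed fold changes and gene-set tallies.

Fold changes use the signed convention common in microarray tables: the
ratio r = mean_case / mean_control is reported as r when r >= 1 and as
-(1/r) when r < 1, so -1.28 means 1.28-fold down and |value| >= 1 always.

A gene is called UP when its signed fold change reaches +fc_min and the
p-value clears alpha, DOWN symmetrically, otherwise UNCHANGED.  Defaults
fc_min = 1.2, alpha = 0.05, no multiple-testing correction: sub-2-fold shifts
of master regulators are treated as meaningful whenever raw p < 0.05
(Benjamini-Hochberg is available behind a flag).  Significance comes from a
two-sided Welch (unequal-variance) two-sample t-test; pre-gated printed
tables carry no p-values and are not re-tested.

:class:`DifferentialExpressionClassifier` is the estimator form
(``fit(X, y)`` on a samples x genes matrix with binary group labels, fitted
``fold_change_`` / ``p_value_`` / ``call_`` per gene); the module functions
wrap it for gene x replicate matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .catalogs import GeneSet, _data_text

__all__ = [
    "UP",
    "DOWN",
    "UNCHANGED",
    "DiffTable",
    "GeneSetRegulationCounts",
    "DifferentialExpressionClassifier",
    "signed_fold_change",
    "test_two_groups",
    "classify_regulation",
    "diff_table",
    "load_signed_table",
    "load_mhc2_diff_tables",
    "geneset_regulation_counts",
]

UP = "UP"
DOWN = "DOWN"
UNCHANGED = "UNCHANGED"

DEFAULT_FC_MIN = 1.2
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DiffTable:
    """Per-gene differential records for one case-vs-control contrast."""

    contrast: str
    records: pd.DataFrame  # index gene; columns sfc, p, call
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.records.index.has_duplicates:
            dupes = sorted(self.records.index[self.records.index.duplicated()].unique())
            raise ValueError(f"duplicate gene records in diff table: {dupes}")

    @property
    def genes(self) -> list[str]:
        return self.records.index.tolist()

    def call(self, gene: str) -> str:
        return str(self.records.at[gene, "call"])


@dataclass(frozen=True)
class GeneSetRegulationCounts:
    set_name: str
    n_up: int
    n_down: int
    n_unchanged: int
    n_unmeasured: int
    member_calls: dict[str, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_up + self.n_down + self.n_unchanged + self.n_unmeasured


def signed_fold_change(mean_case: float, mean_control: float, epsilon: float = 0.0) -> float:
    """Signed fold change of two non-negative group means.

    r = (mean_case + eps) / (mean_control + eps); returns r when r >= 1,
    else -1/r.  Both means zero after the pseudo-count is an error, never a
    silent +1: regulation must not be fabricated from absent genes.
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("group means must be non-negative")
    a, b = mean_case + epsilon, mean_control + epsilon
    if a == 0 and b == 0:
        raise ValueError("both group means are zero after the pseudo-count; "
                         "fold change undefined (set epsilon > 0 to rescue)")
    if a == 0 or b == 0:
        raise ValueError("one group mean is zero after the pseudo-count; "
                         "fold change unbounded (set epsilon > 0 to rescue)")
    r = a / b
    return r if r >= 1.0 else -1.0 / r


def test_two_groups(case_values, control_values) -> float:
    """Two-sided Welch two-sample t-test p-value.

    Zero variance in both groups with equal means returns p = 1.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if case.std() == 0 and control.std() == 0:
        return 1.0 if case.mean() == control.mean() else 0.0
    p = stats.ttest_ind(case, control, equal_var=False).pvalue
    return float(np.clip(p, 0.0, 1.0))


def classify_regulation(sfc: float, p_value: float | None,
                        fc_min: float = DEFAULT_FC_MIN,
                        alpha: float = DEFAULT_ALPHA) -> str:
    """UP / DOWN / UNCHANGED from a signed fold change and optional p-value.

    An absent p-value (pre-gated table) passes the significance gate.  An
    exact no-change value (sfc == +1, ratio exactly 1) is UNCHANGED even at
    fc_min = 1: equality with the control mean is never regulation.
    """
    if fc_min < 1.0:
        raise ValueError(f"fc_min must be >= 1, got {fc_min}")
    if sfc == 1.0:
        return UNCHANGED
    significant = p_value is None or (not np.isnan(p_value) and p_value < alpha)
    if significant and sfc >= fc_min:
        return UP
    if significant and sfc <= -fc_min:
        return DOWN
    return UNCHANGED


class DifferentialExpressionClassifier(BaseEstimator):
    """Per-gene UP/DOWN/UNCHANGED labelling of a two-group expression matrix.

    Parameters
    ----------
    fc_min : float, default 1.2
        Minimum |signed fold change| for a call.
    alpha : float, default 0.05
        Raw (or BH-adjusted, see ``correction``) p-value gate.
    epsilon : float, default 0.0
        Pseudo-count added to both group means; 0.5 is the documented option
        for matrices containing all-zero genes.
    correction : {None, 'bh'}, default None
        Optional Benjamini-Hochberg adjustment of the p-values before gating.

    Attributes (after ``fit(X, y)`` with X samples x genes, y group labels)
    ----------
    classes_, genes_, fold_change_, p_value_, call_
    """

    def __init__(self, fc_min: float = DEFAULT_FC_MIN, alpha: float = DEFAULT_ALPHA,
                 epsilon: float = 0.0, correction: str | None = None):
        self.fc_min = fc_min
        self.alpha = alpha
        self.epsilon = epsilon
        self.correction = correction

    def fit(self, X, y):
        """X: samples x genes (DataFrame or array); y: two group labels.

        The lexicographically larger label is treated as 'case' unless labels
        are exactly {'case', 'control'}.
        """
        if self.fc_min < 1.0:
            raise ValueError(f"fc_min must be >= 1, got {self.fc_min}")
        if self.correction not in (None, "bh"):
            raise ValueError("correction must be None or 'bh'")
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        y = np.asarray(y)
        labels = sorted(set(y.tolist()))
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 group labels, got {labels}")
        if set(labels) == {"case", "control"}:
            case_label, control_label = "case", "control"
        else:
            control_label, case_label = labels
        case = X_df.loc[y == case_label]
        control = X_df.loc[y == control_label]
        if len(case) < 2 or len(control) < 2:
            raise ValueError("need at least 2 replicates per group")

        # vectorised signed fold change (same contract as signed_fold_change)
        mc = case.mean(axis=0).to_numpy(dtype=float)
        mo = control.mean(axis=0).to_numpy(dtype=float)
        if (mc < 0).any() or (mo < 0).any():
            raise ValueError("group means must be non-negative")
        a, b = mc + self.epsilon, mo + self.epsilon
        zero = (a == 0) | (b == 0)
        if zero.any():
            bad = np.asarray(X_df.columns)[zero].tolist()
            raise ValueError(
                f"zero group mean after the pseudo-count for gene(s) {bad[:10]}; "
                "fold change undefined/unbounded (set epsilon > 0 to rescue)")
        r = a / b
        with np.errstate(divide="ignore"):
            sfc = np.where(r >= 1.0, r, -1.0 / r)

        # vectorised Welch test; both-groups-zero-variance handled as in
        # test_two_groups (p=1 when means equal, p=0 otherwise)
        with np.errstate(divide="ignore", invalid="ignore"):
            pvals = stats.ttest_ind(case.to_numpy(dtype=float),
                                    control.to_numpy(dtype=float),
                                    axis=0, equal_var=False).pvalue
        flat = (case.std(axis=0, ddof=1).to_numpy() == 0) & \
               (control.std(axis=0, ddof=1).to_numpy() == 0)
        pvals = np.where(flat, np.where(mc == mo, 1.0, 0.0), pvals)
        pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)

        gate = pvals
        if self.correction == "bh":
            from statsmodels.stats.multitest import multipletests

            gate = multipletests(pvals, method="fdr_bh")[1]
        sig = gate < self.alpha
        calls = np.where(sig & (sfc >= self.fc_min) & (sfc != 1.0), UP,
                         np.where(sig & (sfc <= -self.fc_min), DOWN, UNCHANGED))
        self.genes_ = np.asarray(X_df.columns)
        self.fold_change_ = sfc
        self.p_value_ = pvals
        self.adjusted_p_value_ = gate if self.correction else None
        self.call_ = calls
        self.classes_ = np.array([DOWN, UNCHANGED, UP])
        self.n_features_in_ = X_df.shape[1]
        return self

    def predict(self, X=None) -> np.ndarray:
        """Fitted per-gene calls (the labelling is a property of the fit)."""
        if not hasattr(self, "call_"):
            raise RuntimeError("classifier is not fitted; call fit(X, y) first")
        return self.call_.copy()


def diff_table(case_matrix: pd.DataFrame, control_matrix: pd.DataFrame,
               fc_min: float = DEFAULT_FC_MIN, alpha: float = DEFAULT_ALPHA,
               epsilon: float = 0.0, correction: str | None = None,
               contrast: str = "case vs control",
               scale: str = "linear") -> DiffTable:
    """One DiffRecord per shared gene from gene x replicate matrices.

    ``scale`` must be stated explicitly: 'linear' values are used as-is;
    'log2' values are exponentiated before fold changes (silent log detection
    corrupts every fold change and is deliberately not attempted).
    """
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    if list(case_matrix.index) != list(control_matrix.index):
        raise ValueError("case and control matrices must share an identical gene axis")
    case = case_matrix.astype(float)
    control = control_matrix.astype(float)
    if scale == "log2":
        case, control = 2.0 ** case, 2.0 ** control
    X = pd.concat([case.T, control.T], axis=0)
    y = np.array(["case"] * case.shape[1] + ["control"] * control.shape[1])
    clf = DifferentialExpressionClassifier(fc_min=fc_min, alpha=alpha,
                                           epsilon=epsilon, correction=correction).fit(X, y)
    records = pd.DataFrame(
        {"sfc": clf.fold_change_, "p": clf.p_value_, "call": clf.call_},
        index=case.index,
    )
    return DiffTable(contrast=contrast, records=records,
                     thresholds={"fc_min": fc_min, "alpha": alpha, "epsilon": epsilon,
                                 "correction": correction, "scale": scale,
                                 "test": "welch_t_two_sided"})


def load_signed_table(source, contrast: str = "contrast") -> DiffTable:
    """Build a DiffTable from a pre-gated printed signed-fold-change column.

    ``source``: mapping or Series of gene -> signed fold change, with NaN /
    None / blank meaning "not significant".  Printed tables are taken as
    already significance-gated, so blanks become UNCHANGED and no p-value is
    attached.  A finite |value| < 1 violates the signed convention.
    """
    series = pd.Series(source, dtype=object)
    sfc, calls = [], []
    for gene, raw in series.items():
        blank = raw is None or (isinstance(raw, str) and not raw.strip()) or (
            isinstance(raw, float) and np.isnan(raw))
        if blank:
            sfc.append(np.nan)
            calls.append(UNCHANGED)
            continue
        value = float(raw)
        if abs(value) < 1.0:
            raise ValueError(
                f"{gene}: |{value}| < 1 is invalid in a signed-convention table")
        sfc.append(value)
        calls.append(UP if value > 0 else DOWN)
    records = pd.DataFrame({"sfc": sfc, "p": np.nan, "call": calls},
                           index=series.index)
    return DiffTable(contrast=contrast, records=records,
                     thresholds={"pre_gated": True})


_CONTRAST_LABELS = {
    "gata3_ko": "Gata3 KO vs WT Treg",
    "bcl6_ko": "Bcl6 KO vs WT Treg",
    "hdac6_ko": "Hdac6 KO vs WT Treg",
}


def load_mhc2_diff_tables() -> dict[str, DiffTable]:
    """The packaged MHC-class-II knockout contrasts as three DiffTables.

    Keys: 'gata3_ko', 'bcl6_ko', 'hdac6_ko' (Gata3/Bcl6/Hdac6 knockout vs
    wild-type Treg signed fold changes over the 14-gene MHC-II panel).
    """
    df = pd.read_csv(StringIO(_data_text("mhc2_diff_table.tsv")), sep="\t", index_col=0)
    return {key: load_signed_table(df[key], contrast=label)
            for key, label in _CONTRAST_LABELS.items()}


def geneset_regulation_counts(diff: DiffTable, gene_set: GeneSet) -> GeneSetRegulationCounts:
    """Tally UP / DOWN / UNCHANGED / unmeasured over a gene set."""
    if len(gene_set) == 0:  # pragma: no cover - GeneSet forbids this
        raise ValueError("empty gene set")
    member_calls: dict[str, str] = {}
    n_up = n_down = n_unchanged = n_unmeasured = 0
    for gene in gene_set.genes:
        if gene not in diff.records.index:
            n_unmeasured += 1
            member_calls[gene] = "unmeasured"
            continue
        call = diff.call(gene)
        member_calls[gene] = call
        if call == UP:
            n_up += 1
        elif call == DOWN:
            n_down += 1
        else:
            n_unchanged += 1
    return GeneSetRegulationCounts(gene_set.name, n_up, n_down, n_unchanged,
                                   n_unmeasured, member_calls)
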