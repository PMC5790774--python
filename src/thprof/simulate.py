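"""Synthetic inputs with planted truth for every analysis stage.

Two generators, both bit-for-bit reproducible from (config, seed):

``simulate_tissue_panel``
    An EST-style gene x tissue TPM table.  Per tissue, expected tag counts
    are drawn negative-binomially around each gene's target share of the
    library and converted to TPM by column normalisation x 10^6 — mimicking
    EST sampling without modelling library construction.  The panel carries
    a high-abundance beta-actin reference, a low-variance housekeeping trio,
    background expressed genes, planted HIGH genes whose arbitrary units sit
    a configured multiple above the expected housekeeping mean+2SD limit,
    and planted no-expression genes absent from every library (0 tags -> 0
    TPM; a sub-1-TPM planted mean would be ill-defined, since a single
    sampled tag in a 10^5-tag library is already 10 TPM).

``simulate_case_control``
    Gene x replicate matrices for a two-group contrast with multiplicative
    planted effects on a configured fraction of genes and log-normal
    replicate noise of configured coefficient of variation.

Dispersion convention: a gene's count CV c maps to negative-binomial size
1/c^2 (the Poisson term is negligible at the mean counts used).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiling import CALL_EXPRESSED, CALL_HIGH, CALL_NONE, ExpressionTable

__all__ = [
    "PanelSimConfig",
    "CaseControlSimConfig",
    "simulate_tissue_panel",
    "simulate_case_control",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class PanelSimConfig:
    """Study conditions for the tissue-panel generator.

    Defaults emulate the real analysis: 32 tissues, a panel of ~60 assayed
    genes, beta-actin at 1% of tags (10,000 TPM), three housekeeping genes
    at half the actin level with 10% count CV, high genes planted 3x above
    the expected threshold, and one fifth of genes absent everywhere.
    """

    n_genes: int = 60          # non-reference, non-housekeeping panel genes
    n_tissues: int = 32
    ref_gene: str = "ACTB"
    ref_mean_tpm: float = 10_000.0
    hk_genes: tuple[str, ...] = ("HK1", "HK2", "HK3")
    hk_mean_au: float = 0.5
    cv: float = 0.1            # count CV for every gene class
    n_high: int = 10
    high_multiple: float = 3.0  # planted AU as multiple of expected upper limit
    n_none: int = 12
    background_au: float = 0.1
    library_size: int = 100_000

    def __post_init__(self) -> None:
        if self.high_multiple <= 1.0:
            raise ValueError("high_multiple must exceed 1 (planted HIGH must clear the limit)")
        if self.n_high + self.n_none > self.n_genes:
            raise ValueError("n_high + n_none exceeds n_genes")
        if self.cv <= 0 or self.hk_mean_au <= 0 or self.ref_mean_tpm <= 0:
            raise ValueError("dispersion and means must be positive")

    @property
    def expected_upper_au(self) -> float:
        # AU of a housekeeping gene is a ratio of two noisy counts, so its CV
        # is ~ sqrt(2) * cv; the expected mean+2SD limit follows.
        return self.hk_mean_au * (1.0 + 2.0 * _SQRT2 * self.cv)


@dataclass(frozen=True)
class CaseControlSimConfig:
    """Study conditions for the case/control generator.

    Defaults match the recovery suite: 1000 genes, 5 replicates per group,
    20% of genes carrying 2-fold effects (half up, half down), 10% CV.
    """

    n_genes: int = 1000
    n_replicates: int = 5
    frac_up: float = 0.1
    frac_down: float = 0.1
    effect_fold: float = 2.0
    cv: float = 0.1
    base_mean_log: float = 5.0   # natural-log mean of baseline expression
    base_sigma_log: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1
                and self.frac_up + self.frac_down <= 1):
            raise ValueError("effect fractions must lie in [0,1] and sum to <= 1")
        if self.effect_fold < 1.0:
            raise ValueError("effect_fold must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.cv <= 0:
            raise ValueError("cv must be positive")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Negative-binomial draws with the given mean and count CV (size = 1/cv^2)."""
    size = 1.0 / cv**2
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_tissue_panel(config: PanelSimConfig = PanelSimConfig(),
                          seed: int = 0) -> tuple[ExpressionTable, pd.DataFrame]:
    """Simulate a TPM panel; returns (table, truth).

    Truth is a DataFrame indexed by gene with columns ``planted_call``
    (expected call in every tissue: NONE / EXPRESSED / HIGH), ``role``
    (reference / housekeeping / background / planted_high / planted_none)
    and ``target_au``.
    """
    rng = np.random.default_rng(seed)
    c = config
    n_bg = c.n_genes - c.n_high - c.n_none
    genes, roles, target_au, planted = [c.ref_gene], ["reference"], [1.0], [CALL_HIGH]
    for g in c.hk_genes:
        genes.append(g); roles.append("housekeeping")
        target_au.append(c.hk_mean_au); planted.append(CALL_EXPRESSED)
    high_au = c.high_multiple * c.expected_upper_au
    for i in range(c.n_high):
        genes.append(f"HIGH{i+1:03d}"); roles.append("planted_high")
        target_au.append(high_au); planted.append(CALL_HIGH)
    for i in range(c.n_none):
        genes.append(f"NONE{i+1:03d}"); roles.append("planted_none")
        target_au.append(0.0); planted.append(CALL_NONE)
    for i in range(n_bg):
        genes.append(f"BG{i+1:03d}"); roles.append("background")
        target_au.append(c.background_au); planted.append(CALL_EXPRESSED)

    # expected tag count per gene per tissue: target TPM share of the library
    target_tpm = np.array(target_au) * c.ref_mean_tpm
    target_tpm[0] = c.ref_mean_tpm  # reference AU is 1 by definition
    mean_counts = target_tpm / 1e6 * c.library_size
    counts = np.zeros((len(genes), c.n_tissues))
    positive = mean_counts > 0
    for t in range(c.n_tissues):
        counts[positive, t] = _nb_counts(rng, mean_counts[positive], c.cv)
    # the assayed panel is a small slice of the library; the remainder of
    # each library is unassayed mass, so TPM uses the full library size
    tpm = counts / c.library_size * 1e6
    table = ExpressionTable(
        data=pd.DataFrame(tpm, index=genes, columns=[f"tissue{t+1:02d}" for t in range(c.n_tissues)])
    )
    truth = pd.DataFrame({"role": roles, "planted_call": planted, "target_au": target_au},
                         index=pd.Index(genes, name="gene"))
    return table, truth


def simulate_case_control(config: CaseControlSimConfig = CaseControlSimConfig(),
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (case matrix, control matrix, truth), gene x replicate.

    Truth columns: ``planted_call`` (UP / DOWN / UNCHANGED relative to the
    control group) and ``effect_fold`` (signed convention).
    """
    from .diffreg import DOWN, UNCHANGED, UP

    rng = np.random.default_rng(seed)
    c = config
    n_up = int(round(c.frac_up * c.n_genes))
    n_down = int(round(c.frac_down * c.n_genes))
    genes = [f"G{i+1:05d}" for i in range(c.n_genes)]
    calls = np.array([UP] * n_up + [DOWN] * n_down + [UNCHANGED] * (c.n_genes - n_up - n_down))
    effect = np.ones(c.n_genes)
    effect[:n_up] = c.effect_fold
    effect[n_up:n_up + n_down] = 1.0 / c.effect_fold
    base = rng.lognormal(c.base_mean_log, c.base_sigma_log, size=c.n_genes)

    sigma = np.sqrt(np.log1p(c.cv**2))  # log-normal sigma giving the target CV
    mu_correction = -0.5 * sigma**2     # unit-mean multiplicative noise

    def noise(shape):
        return rng.lognormal(mu_correction, sigma, size=shape)

    control = base[:, None] * noise((c.n_genes, c.n_replicates))
    case = (base * effect)[:, None] * noise((c.n_genes, c.n_replicates))
    case_df = pd.DataFrame(case, index=genes,
                           columns=[f"case{j+1}" for j in range(c.n_replicates)])
    control_df = pd.DataFrame(control, index=genes,
                              columns=[f"control{j+1}" for j in range(c.n_replicates)])
    sfc = np.where(effect >= 1, effect, -1.0 / effect)
    truth = pd.DataFrame({"planted_call": calls, "effect_fold": sfc},
                         index=pd.Index(genes, name="gene"))
    return case_df, control_df, truth
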