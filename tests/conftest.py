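import numpy as np
import pandas as pd
import pytest

import thprof as tp


@pytest.fixture(scope="session")
def human_catalog():
    return tp.load_regulator_catalog("human")


@pytest.fixture(scope="session")
def reference_calls():
    """The packaged curated human 56-gene x 32-tissue call matrix."""
    return tp.load_reference_call_matrix()


@pytest.fixture
def toy_tpm():
    """3 genes x 2 tissues, chosen so every AU is hand-checkable."""
    return pd.DataFrame(
        {"t1": [100.0, 50.0, 0.5], "t2": [200.0, 20.0, 40.0]},
        index=["ACTB", "GENE1", "GENE2"],
    )


def straight_line_calls(tpm: pd.DataFrame, ref: str, hk: list[str]) -> pd.DataFrame:
    """Independent per-cell re-implementation of the two calling rules.

    Pure-python, cell-by-cell: AU = TPM/TPM_ref per tissue; pooled upper
    limit = mean + 2*sample-SD of housekeeping AU; TPM<1 -> '-';
    AU>upper -> '++'; else '+'.
    """
    import statistics

    au = {}
    for t in tpm.columns:
        denom = tpm.at[ref, t]
        for g in tpm.index:
            au[(g, t)] = tpm.at[g, t] / denom
    hk_values = [au[(g, t)] for g in hk for t in tpm.columns]
    mean = statistics.fmean(hk_values)
    sd = statistics.stdev(hk_values)
    upper = mean + 2 * sd
    out = pd.DataFrame(index=tpm.index, columns=tpm.columns, dtype=object)
    for g in tpm.index:
        for t in tpm.columns:
            if tpm.at[g, t] < 1.0:
                out.at[g, t] = "NONE"
            elif au[(g, t)] > upper:
                out.at[g, t] = "HIGH"
            else:
                out.at[g, t] = "EXPRESSED"
    return out


def random_tpm_table(rng: np.random.Generator, max_genes: int = 20,
                     max_tissues: int = 10) -> pd.DataFrame:
    """Random TPM table with an always-positive reference and 3 hk genes."""
    n_genes = rng.integers(5, max_genes + 1)
    n_tissues = rng.integers(2, max_tissues + 1)
    genes = ["REF", "K1", "K2", "K3"] + [f"g{i}" for i in range(n_genes)]
    values = rng.gamma(0.6, 40.0, size=(len(genes), n_tissues))
    values[0] = rng.uniform(500, 2000, size=n_tissues)  # reference never zero
    values[1:4] = rng.uniform(10, 400, size=(3, n_tissues))
    return pd.DataFrame(values, index=genes,
                        columns=[f"t{j}" for j in range(n_tissues)])
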