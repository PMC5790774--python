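"""Readers and writers for the TSV dialects, GMT gene sets and sample sheets.

Everything is tab-separated (gene symbols and tissue names are safer without
comma quoting) and UTF-8.  Every writer's output is readable by its paired
reader.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .catalogs import GeneSet
from .profiling import CallMatrix, ExpressionTable

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_call_matrix_tsv",
    "write_call_matrix_tsv",
    "write_calls_long_tsv",
    "read_gmt",
    "write_gmt",
    "read_sample_sheet",
]


def read_expression_tsv(path) -> ExpressionTable:
    """Gene x tissue TPM matrix: header row, first column ``gene``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty expression file")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicated gene row(s): {dupes}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from exc
    if values.isna().any().any():
        bad = values.columns[values.isna().any(axis=0)].tolist()
        raise ValueError(f"{path}: missing/non-numeric cells in column(s) {bad}")
    return ExpressionTable(data=values)


def write_expression_tsv(table: ExpressionTable | pd.DataFrame, path) -> None:
    df = table.data if isinstance(table, ExpressionTable) else table
    df.to_csv(path, sep="\t", index_label="gene")


def read_call_matrix_tsv(path, tokens: dict[str, str] | None = None) -> CallMatrix:
    """Symbol-matrix calls (tokens -, +, ++ by default)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return CallMatrix.from_symbols(df, provenance={"source": str(path)}, tokens=tokens)


def write_call_matrix_tsv(calls: CallMatrix, path, tokens: dict[str, str] | None = None) -> None:
    calls.to_symbols(tokens).to_csv(path, sep="\t", index_label="gene")


def write_calls_long_tsv(table: ExpressionTable, au, calls: CallMatrix, path) -> None:
    """Long-format per-cell report: gene, tissue, tpm, au, call."""
    au_df = au.data if hasattr(au, "data") else au
    long = (
        table.data.stack().rename("tpm").to_frame()
        .join(au_df.stack().rename("au"))
        .join(calls.data.stack().rename("call"))
        .reset_index()
    )
    long.columns = ["gene", "tissue", "tpm", "au", "call"]
    long.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Standard GMT: name, description, then tab-separated members."""
    sets: list[GeneSet] = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields "
                             f"(name, description, members), got {len(fields)}")
        name, description, *members = fields
        members = [m for m in members if m.strip()]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            warnings.warn(f"{path}:{lineno}: duplicate member(s) dropped in {name!r}")
        sets.append(GeneSet(name=name, genes=tuple(unique), description=description))
    return sets


def write_gmt(gene_sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, gs.description or "na", *gs.genes]) + "\n")


def read_sample_sheet(path) -> pd.Series:
    """Two-column TSV ``sample<TAB>group`` -> Series sample -> group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: sample sheet must have columns 'sample' and 'group'")
    if df["sample"].duplicated().any():
        dupes = sorted(df.loc[df["sample"].duplicated(), "sample"])
        raise ValueError(f"{path}: duplicated sample(s): {dupes}")
    return df.set_index("sample")["group"]
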