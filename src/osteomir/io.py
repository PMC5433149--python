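"""TSV/BED/GMT readers and writers.

Matrix TSVs are features x samples with the first column holding feature ids
and the header holding sample ids. Survival TSVs have columns
(sample, time_months, event) plus optional covariates. BED intervals are read
natively as 0-based half-open; 1-based probe position tables are converted on
ingest via an explicit flag.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, SurvivalTable

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_survival_tsv",
    "write_survival_tsv",
    "read_bed",
    "read_probe_annotation_tsv",
    "read_gmt",
    "read_edge_list_tsv",
    "write_matrix_tsv",
]


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_tsv(x: ExpressionMatrix, path) -> None:
    x.values.to_csv(path, sep="\t", index_label="feature")


def write_matrix_tsv(df: pd.DataFrame, path, index_label: str = "id") -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", index_label=index_label)


def read_survival_tsv(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "time_months" in df.columns:
        df = df.rename(columns={"time_months": "time"})
    return SurvivalTable(df)


def write_survival_tsv(surv: SurvivalTable, path) -> None:
    out = surv.data.rename(columns={"time": "time_months"})
    out.to_csv(path, sep="\t", index_label="sample")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (first three columns chrom/start/end, optional name)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(4, df.shape[1])]
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    return df


def read_probe_annotation_tsv(path, positions_are_1based: bool = False) -> pd.DataFrame:
    """Read a probe annotation table (probe, chrom, pos, ...).

    Set ``positions_are_1based`` when the table uses 1-based coordinates;
    positions are converted to the internal 0-based convention.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("probe", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"probe annotation needs a '{col}' column")
    if positions_are_1based:
        df = df.assign(pos=df["pos"] - 1)
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name <tab> description <tab> members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_edge_list_tsv(path, value_col: str = "weight") -> pd.DataFrame:
    """Read a (source, target, weight) edge list and pivot to a dense matrix."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError("edge list needs source, target and weight columns")
    src, tgt = cols[0], cols[1]
    val = value_col if value_col in df.columns else cols[2]
    return df.pivot_table(index=src, columns=tgt, values=val, fill_value=0.0)
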