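"""Core in-memory containers shared across the pipeline.

All matrices are pandas DataFrames with features (probes, genes, regulators)
on rows and samples on columns, mirroring the TSV layout used on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "MethylationPanel",
    "RegulatoryPriors",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what}: {dup}")


@dataclass
class ExpressionMatrix:
    """Dense feature x sample expression matrix.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
    normalized
        Whether the matrix has been quantile normalized.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(features)], self.normalized)


@dataclass
class SurvivalTable:
    """Per-sample time-to-event table.

    ``data`` is indexed by sample id with columns ``time`` (months, positive)
    and ``event`` (0 censored / 1 event), plus optional numeric covariates
    (e.g. ``necrosis_optimal``, ``alt_chemo``).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data)
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table needs a '{col}' column")
        _check_unique(self.data.index, "sample ids")
        t = self.data["time"].to_numpy(dtype=float)
        e = self.data["event"].to_numpy()
        if not (np.all(np.isfinite(t)) and np.all(t > 0)):
            raise ValueError("times must be positive and finite")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def loc(self, samples) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(samples)])

    def align_to(self, expr: ExpressionMatrix) -> "SurvivalTable":
        """Reorder rows to the sample order of an expression matrix."""
        missing = expr.sample_ids.difference(self.data.index)
        if len(missing):
            raise KeyError(f"samples without survival data: {list(missing)[:5]}")
        return SurvivalTable(self.data.loc[expr.sample_ids])


@dataclass
class MethylationPanel:
    """Methylation beta matrix plus probe genomic annotations.

    ``beta`` is probes x samples, strictly inside (0, 1); ``annotations`` is
    indexed by probe id with columns ``chrom``, ``pos`` (0-based single base)
    and ``ctcf_class`` in {in_site, near_site, not_in_site}.
    """

    beta: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.beta = pd.DataFrame(self.beta)
        self.annotations = pd.DataFrame(self.annotations)
        _check_unique(self.beta.index, "probe ids")
        arr = self.beta.to_numpy(dtype=float)
        if not (np.all(arr > 0) and np.all(arr < 1)):
            raise ValueError("beta values must lie strictly inside (0, 1)")
        if not self.beta.index.equals(self.annotations.index):
            raise ValueError("beta rows and annotation rows must share probe ids")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def m(self) -> pd.DataFrame:
        """M-value transform log2(beta / (1 - beta))."""
        from .preprocess import beta_to_m

        return beta_to_m(self.beta)


@dataclass
class RegulatoryPriors:
    """Inputs of the message-passing network inference.

    motif
        W0 prior, regulators x genes.
    ppi
        P0 cooperativity prior, regulators x regulators, symmetric with unit
        diagonal.
    expression
        Gene expression (genes x samples) from which the gene-gene
        coexpression C0 is computed.
    mirna_regulators
        Regulator ids that are miRNAs; these never gain cooperativity edges.
    """

    motif: pd.DataFrame
    ppi: pd.DataFrame
    expression: pd.DataFrame
    mirna_regulators: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.motif = pd.DataFrame(self.motif)
        self.ppi = pd.DataFrame(self.ppi)
        self.expression = pd.DataFrame(self.expression)
        if not self.ppi.index.equals(self.motif.index):
            raise ValueError("PPI rows must match motif regulators")
        if not self.ppi.columns.equals(self.motif.index):
            raise ValueError("PPI must be square over the regulators")
        p = self.ppi.to_numpy(dtype=float)
        if not np.allclose(p, p.T):
            raise ValueError("PPI prior must be symmetric")
        if not np.allclose(np.diag(p), 1.0):
            raise ValueError("PPI prior must have unit diagonal")
        if not self.expression.index.equals(self.motif.columns):
            raise ValueError("expression rows must match motif genes")
        unknown = set(self.mirna_regulators) - set(self.motif.index)
        if unknown:
            raise ValueError(f"miRNA regulators not in motif prior: {sorted(unknown)[:5]}")
        self.mirna_regulators = list(self.mirna_regulators)

    @property
    def regulators(self) -> pd.Index:
        return self.motif.index

    @property
    def genes(self) -> pd.Index:
        return self.motif.columns

    @property
    def mirna_indices(self) -> np.ndarray:
        return np.array([self.motif.index.get_loc(r) for r in self.mirna_regulators], dtype=int)
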