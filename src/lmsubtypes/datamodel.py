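"""Core in-memory containers shared by every pipeline stage.

The universal currency is the :class:`ExpressionMatrix`: a genes x samples
real matrix on log2 scale (HGNC symbols as row keys), backed by a pandas
DataFrame. Clinical/molecular metadata travel in a :class:`CohortAnnotation`,
gene signatures in a :class:`GeneSetCollection`, and cross-classification
counts in a :class:`ContingencyTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortAnnotation",
    "GeneSetCollection",
    "ContingencyTable",
    "ANNOTATION_REQUIRED",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix.

    Parameters
    ----------
    data:
        DataFrame with gene symbols as index and sample IDs as columns.
    scale:
        ``"log2"`` (default contract for the whole pipeline) or ``"linear"``.
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix must have at least one gene and one sample")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:10]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:10]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite (no NaN/inf)")

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def to_linear(self) -> "ExpressionMatrix":
        """Exponential (2^x) transform; identity if already linear."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(np.exp2(self.data), scale="linear")

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)], scale=self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(samples)], scale=self.scale)


ANNOTATION_REQUIRED = ("sample_id", "patient_id", "tissue")

_BOOL_COLUMNS = (
    "neoadjuvant",
    "extra_hepatic",
    "mut_kras",
    "mut_nras",
    "mut_braf_v600e",
    "mut_tp53",
)
_SURVIVAL_COLUMNS = ("os_time_months", "os_event", "css_time_months", "css_event")


@dataclass
class CohortAnnotation:
    """Per-sample clinical and molecular metadata.

    ``table`` is indexed by ``sample_id``; optional columns that are absent
    are simply not present in the frame. Boolean-ish columns accept
    0/1/true/false and keep NA for unknown.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ANNOTATION_REQUIRED:
            if col != "sample_id" and col not in self.table.columns:
                raise ValueError(f"annotation missing required column {col!r}")
        if self.table.index.name != "sample_id":
            raise ValueError("annotation table must be indexed by sample_id")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id: {dups[:10]}")
        bad_tissue = set(self.table["tissue"].dropna()) - {"tumor", "normal_liver"}
        if bad_tissue:
            raise ValueError(f"unknown tissue values: {sorted(bad_tissue)}")
        tumor = self.table[self.table["tissue"] == "tumor"]
        if tumor["patient_id"].isna().any():
            raise ValueError("every tumor sample must map to a patient")
        for col in ("os_time_months", "css_time_months"):
            if col in self.table.columns:
                t = pd.to_numeric(self.table[col], errors="coerce")
                if (t.dropna() < 0).any():
                    raise ValueError(f"{col} contains negative times")
        for col in ("os_event", "css_event"):
            if col in self.table.columns:
                vals = set(pd.to_numeric(self.table[col], errors="coerce").dropna())
                if not vals <= {0, 1}:
                    raise ValueError(f"{col} must be 0/1, got {sorted(vals)}")

    @property
    def samples(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def tumor_samples(self) -> list[str]:
        return self.table.index[self.table["tissue"] == "tumor"].tolist()

    @property
    def normal_samples(self) -> list[str]:
        return self.table.index[self.table["tissue"] == "normal_liver"].tolist()

    def patients(self) -> list[str]:
        return sorted(self.table.loc[self.table["tissue"] == "tumor", "patient_id"].unique())

    def subset(self, samples: Sequence[str]) -> "CohortAnnotation":
        return CohortAnnotation(self.table.loc[list(samples)].copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (uppercase HGNC symbols), order-preserving."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene-set collection is empty")
        norm: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g).upper(), None)
            members = list(seen)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            norm[name] = members
        self.sets = norm

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ContingencyTable:
    """Labelled non-negative integer cross-classification counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("contingency counts must be integers")
            self.counts = self.counts.astype(int)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if arr.sum() <= 0:
            raise ValueError("contingency table total must be positive")

    @property
    def row_labels(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def col_labels(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_labels(cls, labels_a: Mapping[str, str], labels_b: Mapping[str, str]) -> "ContingencyTable":
        common = sorted(set(labels_a) & set(labels_b))
        if not common:
            raise ValueError("no shared samples between labelings")
        a = pd.Series({s: labels_a[s] for s in common})
        b = pd.Series({s: labels_b[s] for s in common})
        return cls(pd.crosstab(a, b))
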