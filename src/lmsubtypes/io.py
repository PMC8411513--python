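"""Readers and writers for the tab-delimited / GMT formats used by the pipeline.

All expression files are genes x samples: first column gene symbols, header
row of sample IDs, tab-delimited. Matrices are complete (missing values are
rejected); the only sanctioned imputation in the pipeline is the
mini-classifier's median rule.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    ANNOTATION_REQUIRED,
    CohortAnnotation,
    ExpressionMatrix,
    GeneSetCollection,
)

logger = logging.getLogger("lmsubtypes")

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_annotation",
    "write_annotation",
    "write_subtype_calls",
    "read_subtype_calls",
    "load_config",
]


def read_expression_matrix(path: str | Path, id_policy: str = "error") -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix.

    ``id_policy`` controls duplicate gene symbols: ``"error"`` rejects them,
    ``"median_aggregate"`` collapses duplicate rows to their per-sample median
    (the convention for cross-platform symbol collisions).
    """
    if id_policy not in ("error", "median_aggregate"):
        raise ValueError(f"unknown id_policy {id_policy!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    df.index = df.index.astype(str)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row!r}")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"{path}: missing values in rows {rows[:5]}")
    if df.index.duplicated().any():
        if id_policy == "error":
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"{path}: duplicate gene symbols {dups[:10]} (id_policy='error')")
        # median across duplicate rows, preserving first-occurrence order
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).median().loc[order]
        logger.info("median-aggregated duplicate gene symbols in %s", path)
    return ExpressionMatrix(df, scale="log2")


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name TAB description TAB gene1 TAB ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_annotation(path: str | Path) -> CohortAnnotation:
    """Read a tab-delimited annotation table; see CohortAnnotation for columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    for col in ANNOTATION_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id {dups[:10]}")
    df = df.set_index("sample_id")
    for col in ("lesion_id", "region_id", "resection", "msi", "cms_label", "cris_label"):
        if col in df.columns:
            df[col] = df[col].astype("string")
    for col in ("neoadjuvant", "extra_hepatic", "mut_kras", "mut_nras", "mut_braf_v600e", "mut_tp53"):
        if col in df.columns:
            df[col] = _coerce_bool(df[col])
    for col in ("os_time_months", "css_time_months"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("os_event", "css_event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if "resection_round" in df.columns:
        df["resection_round"] = pd.to_numeric(df["resection_round"], errors="coerce").astype("Int64")
    return CohortAnnotation(df)


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "1": True, "0": False, "true": True, "false": False,
        "yes": True, "no": False, "t": True, "f": False,
        1: True, 0: False, 1.0: True, 0.0: False, True: True, False: False,
    }

    def conv(v):  # NA stays NA (= unknown)
        if pd.isna(v):
            return pd.NA
        key = v.lower() if isinstance(v, str) else v
        if key not in mapping:
            raise ValueError(f"cannot coerce {v!r} to boolean")
        return mapping[key]

    return series.map(conv).astype("boolean")


def write_annotation(annot: CohortAnnotation, path: str | Path) -> None:
    annot.table.to_csv(path, sep="\t", index_label="sample_id")


def write_subtype_calls(
    labels: Mapping[str, str],
    posteriors: pd.DataFrame,
    path: str | Path,
    atol: float = 1e-6,
) -> None:
    """Write per-sample calls with class posterior columns.

    Every labelled sample needs a posterior row summing to 1 within ``atol``.
    Column order is deterministic: sample_id, call, then classes sorted.
    """
    missing = [s for s in labels if s not in posteriors.index]
    if missing:
        raise ValueError(f"no posterior row for samples {missing[:10]}")
    sums = posteriors.loc[list(labels)].sum(axis=1)
    bad = sums[(sums - 1.0).abs() > atol]
    if len(bad):
        raise ValueError(f"posterior rows not normalized for samples {bad.index.tolist()[:10]}")
    classes = sorted(posteriors.columns)
    out = posteriors.loc[list(labels), classes].copy()
    out.insert(0, "call", [labels[s] for s in out.index])
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_subtype_calls(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    labels = df["call"].to_dict()
    posteriors = df.drop(columns="call")
    return labels, posteriors


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline config; a top-level ``seed`` field is required so
    every stochastic stage is reproducible from one number."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError(f"{path}: config must contain a 'seed' field")
    return cfg
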