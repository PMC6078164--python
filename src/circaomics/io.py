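"""TSV/YAML input-output for matrices, truth tables, results and configs.

Sample columns carry circadian time explicitly (``CT{hours}_r{rep}``) so
phase semantics survive file round-trips; empty cells read as missing
values, never as zero.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import FeatureMatrix, TimeGrid

logger = logging.getLogger(__name__)


def read_matrix(
    path, layer: str = "unknown", scale: str = "linear", sep: str = "\t"
) -> FeatureMatrix:
    """Read a feature-by-sample TSV/CSV into a FeatureMatrix.

    The first column is the feature id; remaining columns must be named
    ``CT{hours}_r{rep}``.  Duplicate feature ids and non-numeric cells are
    hard errors; empty cells become missing values.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate feature id(s) in {path}: {list(dup[:5])}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()]
            raise ValueError(
                f"non-numeric cell(s) in {path}, column {col!r}, "
                f"row(s) {list(bad[:3])}"
            )
    grid = TimeGrid.from_columns(df.columns)
    return FeatureMatrix(df.astype(float), grid, layer, scale)


def write_matrix(matrix: FeatureMatrix, path) -> None:
    out = matrix.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_enzyme_map(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    required = {"protein_id", "ec_number", "metabolite_id"}
    if not required <= set(m.columns):
        raise ValueError(f"enzyme map needs columns {sorted(required)}")
    return m


def write_enzyme_map(enzyme_map: pd.DataFrame, path) -> None:
    enzyme_map.to_csv(path, sep="\t", index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_results(results: pd.DataFrame, path) -> None:
    out = results.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "rhythmic" in df.columns:
        df["rhythmic"] = df["rhythmic"].astype(bool)
    return df


def write_fdr_report(report, dirpath, stem: str = "fdr") -> None:
    """FDR summary as YAML plus the permutation-count vector as TSV."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / f"{stem}_report.yaml", "w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=True)
    pd.Series(report.permutation_counts, name="rescaled_positive_count").to_csv(
        d / f"{stem}_permutation_counts.tsv", sep="\t", index_label="permutation"
    )
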