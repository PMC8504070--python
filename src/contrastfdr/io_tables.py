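"""Delimited-table readers and writers.

Input matrices are feature-by-replicate tables (TSV or CSV, dialect
auto-detected from the extension) with a header row and a feature-ID
column. Result tables carry one row per feature plus a ``#``-prefixed
key-value metadata block recording the resolved run configuration, and
round-trip losslessly through write -> read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .api import AnalysisResult
from .scores import MeasurementPair

__all__ = ["read_matrix", "read_pair", "write_result", "read_result", "write_benchmark"]


def _delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path, delimiter: str | None = None, id_column: int | str = 0):
    """Read a feature-by-replicate matrix; returns (feature_ids, values).

    Rejects ragged rows, duplicate feature IDs, non-numeric cells, NaN and
    negative entries, naming the offending cell where possible.
    """
    path = Path(path)
    sep = _delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=id_column)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature ID {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric cell at feature {row!r}, column {col!r}"
            )
        df[col] = vals
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row for feature {row!r}")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path}: negative entry at feature {df.index[i]!r}, column "
            f"{df.columns[j]!r}; shift or transform the data to be non-negative"
        )
    return df.index.to_numpy(), values


def read_pair(x_path, y_path, delimiter: str | None = None) -> MeasurementPair:
    """Read the experimental and background matrices into one container."""
    ids_x, x = read_matrix(x_path, delimiter=delimiter)
    ids_y, y = read_matrix(y_path, delimiter=delimiter)
    if x.shape[0] != y.shape[0]:
        raise ValueError(
            f"feature counts differ: {x_path} has {x.shape[0]} rows, "
            f"{y_path} has {y.shape[0]}"
        )
    if not np.array_equal(ids_x, ids_y):
        raise ValueError("feature IDs differ between the two matrices")
    return MeasurementPair(x=x, y=y, feature_ids=ids_x)


def write_result(result: AnalysisResult, path) -> None:
    """Write a per-feature result table with a metadata header block."""
    path = Path(path)
    cfg = result.config
    meta = {
        "tool": f"contrastfdr {__version__}",
        "mode": cfg.mode,
        "score": cfg.score,
        "procedure": cfg.procedure,
        "h": "" if result.plan is None else str(result.plan.h),
        "seed": str(cfg.seed),
        "q": repr(cfg.q),
        "cutoff": repr(result.cutoff),
    }
    disc = np.zeros(len(result.feature_ids), dtype=bool)
    disc[result.discoveries] = True
    df = pd.DataFrame({
        "feature_id": result.feature_ids,
        "contrast_score": result.contrast_scores,
        "fdr_estimate": result.fdr_estimates,
        "discovery": disc.astype(int),
    })
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_result(path):
    """Read back a result table; returns (metadata dict, DataFrame)."""
    path = Path(path)
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    return meta, df


def write_benchmark(table: pd.DataFrame, path) -> None:
    """Write a benchmark summary table as TSV."""
    table.to_csv(path, sep="\t", index=False)
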