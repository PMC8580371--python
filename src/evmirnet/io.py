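"""Readers and writers for the pipeline's tabular formats.

Schemas (all plain text):

* Ct matrix — CSV, first column ``mirna``, remaining columns one per
  subject, cells numeric Ct values.
* DE table — CSV with columns ``transcript``, ``log2fc``, ``direction``.
* Interaction table — TSV with columns ``mirna``, ``target``, ``source``
  and optional ``score``.
* PPI edge table — TSV with columns ``protein_a``, ``protein_b`` and one
  numeric column per evidence channel.

Validation errors name the offending column and 1-based data row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "read_ct_matrix",
    "write_ct_matrix",
    "read_de_table",
    "write_de_table",
    "read_interactions",
    "write_interactions",
    "read_ppi_edges",
    "write_ppi_edges",
    "write_graph",
    "write_json",
]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_ct_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "mirna":
        raise SchemaError(f"{path}: first column must be 'mirna', got {df.columns[0]!r}")
    dup = df["mirna"][df["mirna"].duplicated()]
    if not dup.empty:
        raise SchemaError(
            f"{path}: duplicate miRNA id {dup.iloc[0]!r} at data row {dup.index[0] + 1}"
        )
    df = df.set_index("mirna")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            raise SchemaError(
                f"{path}: non-numeric Ct in column {col!r} at data row {bad[0] + 1}"
            )
        if (vals < 0).any():
            row = int(np.flatnonzero((vals < 0).to_numpy())[0])
            raise SchemaError(f"{path}: negative Ct in column {col!r} at data row {row + 1}")
        df[col] = vals
    return df


def write_ct_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.rename_axis("mirna").to_csv(path, float_format="%.17g")


def read_de_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, ["transcript", "log2fc", "direction"], path)
    dup = df["transcript"][df["transcript"].duplicated()]
    if not dup.empty:
        raise SchemaError(
            f"{path}: duplicate transcript {dup.iloc[0]!r} at data row {dup.index[0] + 1}"
        )
    lfc = pd.to_numeric(df["log2fc"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(lfc.to_numpy()))
    if bad.size:
        raise SchemaError(f"{path}: non-numeric log2fc at data row {bad[0] + 1}")
    df["log2fc"] = lfc
    for i, (v, d) in enumerate(zip(df["log2fc"], df["direction"])):
        if d not in ("up", "down"):
            raise SchemaError(f"{path}: direction must be up|down at data row {i + 1}, got {d!r}")
        if (d == "up") != (v > 0):
            raise SchemaError(
                f"{path}: direction {d!r} inconsistent with log2fc={v} at data row {i + 1}"
            )
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_interactions(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["mirna", "target", "source"], path)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    else:
        df["score"] = np.nan  # unscored
    df = df.drop_duplicates(subset=["mirna", "target", "source"]).reset_index(drop=True)
    return df


def write_interactions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ppi_edges(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["protein_a", "protein_b"], path)
    channels = [c for c in df.columns if c not in ("protein_a", "protein_b")]
    if not channels:
        raise SchemaError(f"{path}: no evidence-channel column found")
    for col in channels:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy()))
        if bad.size:
            raise SchemaError(
                f"{path}: non-numeric score in channel {col!r} at data row {bad[0] + 1}"
            )
        df[col] = vals
    return df


def write_ppi_edges(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_graph(g: nx.Graph, basepath: str | Path) -> None:
    """Write a graph as both edge-list TSV and GraphML."""
    basepath = Path(basepath)
    rows = sorted(tuple(sorted(map(str, e))) for e in g.edges)
    pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
        basepath.with_suffix(".edges.tsv"), sep="\t", index=False
    )
    nx.write_graphml(g, basepath.with_suffix(".graphml"))


def write_json(obj: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o: Any) -> Any:
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
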