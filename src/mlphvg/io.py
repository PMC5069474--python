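"""Readers and writers: series files, edge lists, feature tables, labels.

Series files are single-column text or CSV, one sample per row, with an
optional header line (auto-detected).  Edge lists are two-column
whitespace-separated text with 1-based node indices, one edge per line,
``i < j``, sorted lexicographically — a diff-stable dialect.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import LabeledFeatureSet
from .graph import TimeSeries, VisibilityGraph
from .metrics import FeatureVector

__all__ = [
    "SeriesLoadError",
    "read_series",
    "write_series",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "features_to_frame",
    "write_feature_table",
    "read_feature_table",
    "read_labels",
    "join_features_labels",
]


class SeriesLoadError(ValueError):
    """Raised when a series file cannot be parsed into finite samples."""


def _parse_sample(token: str) -> float:
    return float(token)


def read_series(path: str | os.PathLike) -> TimeSeries:
    """Read a single-column text/CSV series file.

    The first line is treated as a header and skipped if it does not parse
    as a number.  NaN or infinite values, empty files and non-numeric body
    lines raise :class:`SeriesLoadError` naming the offending line.
    """
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    stripped = [ln.strip().rstrip(",") for ln in lines]
    nonempty = [(idx, ln) for idx, ln in enumerate(stripped) if ln]
    if not nonempty:
        raise SeriesLoadError(f"{path}: file is empty")
    first_idx, first = nonempty[0]
    try:
        v = _parse_sample(first)
    except ValueError:
        v = None  # header line, skipped
    if v is not None:
        if not np.isfinite(v):
            raise SeriesLoadError(
                f"{path}: non-finite value {first!r} at line {first_idx + 1}"
            )
        values.append(v)
    for idx, ln in nonempty[1:]:
        try:
            v = _parse_sample(ln)
        except ValueError:
            raise SeriesLoadError(
                f"{path}: non-numeric value {ln!r} at line {idx + 1}"
            ) from None
        if not np.isfinite(v):
            raise SeriesLoadError(
                f"{path}: non-finite value {ln!r} at line {idx + 1}"
            )
        values.append(v)
    if not values:
        raise SeriesLoadError(f"{path}: no numeric samples found")
    return TimeSeries(np.asarray(values, dtype=float))


def write_series(path: str | os.PathLike, series: TimeSeries) -> None:
    """Write a series as single-column text, one sample per line."""
    np.savetxt(path, series.values, fmt="%.17g")


def write_edgelist(path: str | os.PathLike, graph: VisibilityGraph) -> None:
    """Write a 1-based, lexicographically sorted two-column edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in graph.sorted_edges():
            fh.write(f"{i + 1} {j + 1}\n")


def read_edgelist(path: str | os.PathLike, n_nodes: int | None = None, L: int = 0) -> VisibilityGraph:
    """Read an edge list written by :func:`write_edgelist`.

    ``n_nodes`` defaults to the largest index seen.
    """
    edges = set()
    max_node = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln:
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed edge at line {lineno}")
            a, b = int(parts[0]) - 1, int(parts[1]) - 1
            if a == b:
                raise ValueError(f"{path}: self-loop at line {lineno}")
            edges.add((min(a, b), max(a, b)))
            max_node = max(max_node, a, b)
    n = n_nodes if n_nodes is not None else max_node + 1
    return VisibilityGraph(n_nodes=n, edges=frozenset(edges), L=L)


def write_graphml(
    path: str | os.PathLike, graph: VisibilityGraph, scale: int | None = None
) -> None:
    """GraphML export with node attribute ``t`` (1-based sample index) and
    graph attributes ``scale`` and ``L``."""
    import networkx as nx

    nx.write_graphml(graph.to_networkx(scale=scale), path)


def features_to_frame(features: Iterable[FeatureVector]) -> pd.DataFrame:
    rows = [
        {
            "signal_id": f.signal_id,
            "scale": f.scale,
            "avg_clustering": f.avg_clustering,
            "clustering_entropy": f.clustering_entropy,
        }
        for f in features
    ]
    return pd.DataFrame(rows, columns=["signal_id", "scale", "avg_clustering", "clustering_entropy"])


def write_feature_table(path: str | os.PathLike, features: Iterable[FeatureVector]) -> None:
    """CSV with columns signal_id, scale, avg_clustering, clustering_entropy."""
    features_to_frame(features).to_csv(path, index=False)


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"signal_id": str})
    required = {"signal_id", "scale", "avg_clustering", "clustering_entropy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
    return df


def read_labels(path: str | os.PathLike) -> pd.DataFrame:
    """Labels CSV with columns signal_id, label (0/1)."""
    df = pd.read_csv(path, dtype={"signal_id": str})
    if not {"signal_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: labels file must have columns signal_id,label")
    return df[["signal_id", "label"]]


def join_features_labels(
    features: pd.DataFrame, labels: pd.DataFrame, scale: int
) -> LabeledFeatureSet:
    """Select one scale from a feature table and join class labels."""
    sub = features[features["scale"] == scale]
    if sub.empty:
        raise ValueError(f"feature table contains no rows at scale {scale}")
    merged = sub.merge(labels, on="signal_id", how="left", validate="one_to_one")
    if merged["label"].isna().any():
        missing = merged.loc[merged["label"].isna(), "signal_id"].tolist()[:5]
        raise ValueError(f"labels missing for signals: {missing}")
    return LabeledFeatureSet(
        signal_ids=tuple(merged["signal_id"]),
        features=merged[["avg_clustering", "clustering_entropy"]].to_numpy(),
        labels=merged["label"].to_numpy(dtype=int),
    )
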