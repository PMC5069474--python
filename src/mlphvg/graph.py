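"""Coarse-graining and (limited penetrable) horizontal visibility graphs.

A horizontal visibility graph (HVG) maps a time series onto a network:
every sample is a node, and two samples ``x(i)`` and ``x(j)`` are linked
when a horizontal line can be drawn between them without intersecting any
intermediate sample, i.e. every in-between value is strictly lower than
both endpoints.  The limited penetrable variant (LPHVG) relaxes this:
up to ``L`` in-between samples may block the line, which makes the mapping
robust to noise.  Combining the LPHVG with coarse-graining at scale
factors ``s`` yields the multiscale LPHVG (MLPHVG) family of networks.

Tie rule: the visibility criterion is strict, so an in-between sample
*equal* to the lower endpoint blocks the line.  A constant series at
``L = 0`` therefore maps to the path graph.
"""

from __future__ import annotations

from bisect import insort
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "CoarseSeries",
    "VisibilityGraph",
    "MultiscaleGraphs",
    "InvalidScaleError",
    "coarse_grain",
    "build_hvg",
    "build_lphvg",
    "build_mlphvg",
]


class InvalidScaleError(ValueError):
    """Raised when a coarse-graining scale is out of range for a series."""


@dataclass(frozen=True)
class TimeSeries:
    """An ordered sequence of finite real samples.

    Parameters
    ----------
    values : array-like of float
        The samples, in time order.  Must all be finite.
    sampling_rate : float, optional
        Sampling rate in Hz.  Metadata only; never used in any computation.
    """

    values: np.ndarray
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError(f"expected a 1-D series, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"non-finite value at position {bad + 1}")
        if self.sampling_rate is not None and self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CoarseSeries:
    """A coarse-grained series: non-overlapping window means at scale ``s``."""

    values: np.ndarray
    scale: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class VisibilityGraph:
    """An undirected simple graph on time-ordered sample indices.

    Nodes are ``0 .. n_nodes-1`` internally (serialized 1-based); ``edges``
    holds pairs ``(i, j)`` with ``i < j``.  ``L`` records the penetrable
    distance used during construction.
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    L: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)

    def to_networkx(self, scale: int | None = None):
        """Convert to a :class:`networkx.Graph` with node attribute ``t``
        (1-based sample index) and graph attributes ``L`` and ``scale``."""
        import networkx as nx

        g = nx.Graph(L=self.L)
        if scale is not None:
            g.graph["scale"] = scale
        g.add_nodes_from((i, {"t": i + 1}) for i in range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class MultiscaleGraphs:
    """Per-scale LPHVGs of one series, sharing a penetrable distance ``L``."""

    graphs: Mapping[int, VisibilityGraph]
    L: int

    @property
    def scales(self) -> list[int]:
        return sorted(self.graphs)

    def __getitem__(self, s: int) -> VisibilityGraph:
        return self.graphs[s]

    def __iter__(self):
        return iter(self.scales)


def coarse_grain(series: TimeSeries | Sequence[float], s: int) -> CoarseSeries:
    """Coarse-grain a series at scale factor ``s``.

    Element ``j`` of the result is the arithmetic mean of samples
    ``(j-1)*s + 1 .. j*s`` (1-based); trailing samples beyond
    ``s * floor(N/s)`` are discarded, following the standard
    multiscale-entropy convention.  ``s = 1`` returns the series unchanged.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    n = x.size
    if not (isinstance(s, (int, np.integer)) and not isinstance(s, bool)):
        raise InvalidScaleError(f"scale must be an integer, got {s!r}")
    if s < 1 or s > n:
        raise InvalidScaleError(f"scale s={s} out of range for series of length N={n}")
    m = n // s
    y = x[: m * s].reshape(m, s).mean(axis=1)
    return CoarseSeries(values=y, scale=int(s))


def _as_values(series) -> np.ndarray:
    if isinstance(series, (TimeSeries, CoarseSeries)):
        return series.values
    return np.asarray(series, dtype=float)


def _lphvg_edges(y: np.ndarray, L: int) -> list[tuple[int, int]]:
    """Edge list of the LPHVG of ``y`` with penetrable distance ``L``.

    Pair (i, j) is linked iff at most L in-between samples are >= the lower
    endpoint, equivalently iff the (L+1)-th largest in-between value is
    strictly below min(y[i], y[j]).  The rightward scan from each node keeps
    the L+1 largest in-between values seen so far (``top``, ascending) and
    stops once top[0] can block every remaining pair: thresholds of future
    pairs never exceed min(y[i], max of the remaining suffix).
    """
    n = y.size
    if n < 2:
        raise ValueError(f"series too short for graph construction (length {n})")
    suffmax = np.maximum.accumulate(y[::-1])[::-1]
    yl = y.tolist()
    sm = suffmax.tolist()
    k = L + 1
    edges: list[tuple[int, int]] = []
    for i in range(n - 1):
        yi = yl[i]
        top: list[float] = []
        for j in range(i + 1, n):
            yj = yl[j]
            if len(top) < k:
                edges.append((i, j))
            else:
                thr = yi if yi < yj else yj
                if top[0] < thr:
                    edges.append((i, j))
            # y[j] becomes an in-between sample for the next pair
            if len(top) < k:
                insort(top, yj)
            elif yj > top[0]:
                top.pop(0)
                insort(top, yj)
            if j + 1 < n and len(top) == k:
                bound = sm[j + 1]
                if yi < bound:
                    bound = yi
                if top[0] >= bound:
                    break
    return edges


def build_hvg(series: CoarseSeries | TimeSeries | Sequence[float]) -> VisibilityGraph:
    """Horizontal visibility graph: link (i, j) iff every in-between sample
    is strictly below ``min(y(i), y(j))``.  Equivalent to ``build_lphvg``
    with ``L = 0``."""
    return build_lphvg(series, L=0)


def build_lphvg(
    series: CoarseSeries | TimeSeries | Sequence[float], L: int
) -> VisibilityGraph:
    """Limited penetrable horizontal visibility graph.

    Link (i, j) iff the number of in-between samples at or above
    ``min(y(i), y(j))`` (blockers) is at most ``L``.  ``L = 0`` reduces
    exactly to the HVG; the HVG edge set is a subset of every LPHVG edge set.
    """
    if L < 0:
        raise ValueError(f"penetrable distance L must be non-negative, got {L}")
    y = _as_values(series)
    if y.size < 2:
        raise ValueError(f"series too short for graph construction (length {y.size})")
    edges = _lphvg_edges(y, int(L))
    return VisibilityGraph(n_nodes=int(y.size), edges=frozenset(edges), L=int(L))


def build_mlphvg(
    series: TimeSeries | Sequence[float],
    scales: Iterable[int],
    L: int,
) -> MultiscaleGraphs:
    """Build the LPHVG of the scale-``s`` coarse-grained series for every
    ``s`` in ``scales``.  The graph at scale ``s`` has ``floor(N/s)`` nodes."""
    x = series if isinstance(series, TimeSeries) else TimeSeries(np.asarray(series, float))
    n = len(x)
    scale_list = sorted({int(s) for s in scales})
    if not scale_list:
        raise InvalidScaleError("scale list is empty")
    graphs: dict[int, VisibilityGraph] = {}
    for s in scale_list:
        if s < 1 or s > n or n // s < 2:
            raise InvalidScaleError(
                f"scale s={s} leaves fewer than 2 points for series of length N={n}"
            )
        graphs[s] = build_lphvg(coarse_grain(x, s), L=L)
    return MultiscaleGraphs(graphs=graphs, L=int(L))
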