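"""Network statistics of visibility graphs and multiscale feature vectors.

Two measures summarise each graph:

* the average clustering coefficient C-bar, the mean over nodes of
  ``C_i = tau_{i,closed} / tau_i`` where ``tau_i = deg_i (deg_i - 1) / 2``
  is the number of triplets centered on node i and ``tau_{i,closed}`` the
  number of those that are closed (triangles);
* the clustering coefficient entropy ``E_C``, the Shannon entropy (natural
  log) of the distribution ``p_i = C_i / sum_j C_j`` taken over nodes with
  strictly positive ``C_i``.  An all-zero profile has ``E_C = 0``.

The per-signal, per-scale pair (C-bar, E_C) is the two-dimensional feature
vector used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .graph import TimeSeries, VisibilityGraph, build_mlphvg

__all__ = [
    "ClusteringProfile",
    "FeatureVector",
    "local_clustering",
    "average_clustering",
    "clustering_entropy",
    "degree_stats",
    "graph_features",
    "extract_features",
]


@dataclass(frozen=True)
class ClusteringProfile:
    """Per-node clustering coefficients of one graph."""

    coefficients: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )

    def __len__(self) -> int:
        return self.coefficients.size


@dataclass(frozen=True)
class FeatureVector:
    """The (C-bar, E_C) pair of one signal at one scale."""

    signal_id: str
    scale: int
    avg_clustering: float
    clustering_entropy: float

    def as_pair(self) -> tuple[float, float]:
        return (self.avg_clustering, self.clustering_entropy)


def local_clustering(graph: VisibilityGraph) -> ClusteringProfile:
    """Per-node clustering coefficients.

    ``C_i`` is the fraction of neighbour pairs of node i that are themselves
    linked; nodes of degree < 2 get ``C_i = 0``.
    """
    adj = graph.adjacency()
    coeffs = np.zeros(graph.n_nodes, dtype=float)
    for i, nbrs in enumerate(adj):
        d = len(nbrs)
        if d < 2:
            continue
        closed = 0
        nb = sorted(nbrs)
        for a_idx, a in enumerate(nb):
            adj_a = adj[a]
            for b in nb[a_idx + 1 :]:
                if b in adj_a:
                    closed += 1
        coeffs[i] = closed / (d * (d - 1) / 2)
    return ClusteringProfile(coefficients=coeffs)


def average_clustering(profile: ClusteringProfile) -> float:
    """Arithmetic mean of the per-node coefficients, zeros included."""
    if len(profile) == 0:
        raise ValueError("empty clustering profile")
    return float(profile.coefficients.mean())


def clustering_entropy(profile: ClusteringProfile) -> float:
    """Shannon entropy (nats) of the normalised positive-C_i distribution.

    Bounded by ``ln K`` where K is the number of nodes with ``C_i > 0``;
    equals 0 for degenerate (<= 1 positive coefficient) profiles.
    """
    c = profile.coefficients
    pos = c[c > 0]
    if pos.size == 0:
        return 0.0
    p = pos / pos.sum()
    return float(-(p * np.log(p)).sum())


def degree_stats(graph: VisibilityGraph) -> tuple[np.ndarray, float]:
    """Degree sequence and mean degree ``2 |E| / n`` of a graph."""
    deg = graph.degrees()
    return deg, float(2 * graph.n_edges / graph.n_nodes)


def graph_features(graph: VisibilityGraph) -> tuple[float, float]:
    """(C-bar, E_C) of a single graph."""
    prof = local_clustering(graph)
    return average_clustering(prof), clustering_entropy(prof)


def extract_features(
    series: TimeSeries | Sequence[float],
    scales: Iterable[int],
    L: int,
    signal_id: str = "signal",
) -> list[FeatureVector]:
    """One (C-bar, E_C) feature vector per scale, computed from the
    scale-s LPHVG of the coarse-grained series.  Deterministic given
    (series, scales, L)."""
    ms = build_mlphvg(series, scales, L)
    out = []
    for s in ms.scales:
        cbar, ec = graph_features(ms[s])
        out.append(
            FeatureVector(
                signal_id=signal_id,
                scale=s,
                avg_clustering=cbar,
                clustering_entropy=ec,
            )
        )
    return out
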