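"""Brute-force LPHVG construction used as an independent correctness oracle.

The literal definition: for every pair (i, j) count the in-between samples
at or above the lower endpoint and link the pair when that count is at most
L.  O(n^3); intended for tests on short series only.
"""

from __future__ import annotations

import numpy as np

from .graph import CoarseSeries, TimeSeries, VisibilityGraph

__all__ = ["build_lphvg_oracle"]


def build_lphvg_oracle(series, L: int) -> VisibilityGraph:
    """Literal triple-loop LPHVG, contract-identical to
    :func:`mlphvg.graph.build_lphvg`."""
    if L < 0:
        raise ValueError(f"penetrable distance L must be non-negative, got {L}")
    if isinstance(series, (TimeSeries, CoarseSeries)):
        y = series.values
    else:
        y = np.asarray(series, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError(f"series too short for graph construction (length {n})")
    edges = set()
    for i in range(n - 1):
        for j in range(i + 1, n):
            thr = min(y[i], y[j])
            # literal blocker count over every in-between sample
            blockers = int(np.count_nonzero(y[i + 1 : j] >= thr))
            if blockers <= L:
                edges.add((i, j))
    return VisibilityGraph(n_nodes=n, edges=frozenset(edges), L=int(L))
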