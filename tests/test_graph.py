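"""Coarse-graining and visibility-graph construction contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlphvg import (
    InvalidScaleError,
    TimeSeries,
    build_hvg,
    build_lphvg,
    build_mlphvg,
    coarse_grain,
)
from mlphvg.oracle import build_lphvg_oracle


def edge_set(graph):
    return set(graph.sorted_edges())


class TestCoarseGrain:
    @pytest.mark.parametrize(
        "values, s, expected",
        [
            ([1, 2, 3, 4], 2, [1.5, 3.5]),
            ([5, 1, 7], 1, [5, 1, 7]),
            ([1, 2, 3, 4, 5], 2, [1.5, 3.5]),  # trailing sample discarded
            ([2, 4, 6, 8, 10, 12], 3, [4.0, 10.0]),
        ],
    )
    def test_window_means(self, values, s, expected):
        cs = coarse_grain(TimeSeries(np.array(values, float)), s)
        assert cs.scale == s
        np.testing.assert_allclose(cs.values, expected)

    def test_scale_one_is_identity(self, rng):
        x = rng.normal(size=57)
        np.testing.assert_array_equal(coarse_grain(x, 1).values, x)

    def test_length_is_floor_n_over_s(self, rng):
        x = rng.normal(size=101)
        for s in range(1, 12):
            assert len(coarse_grain(x, s)) == 101 // s

    @pytest.mark.parametrize("s", [0, -1, 11])
    def test_invalid_scale_rejected(self, s):
        with pytest.raises(InvalidScaleError, match="scale"):
            coarse_grain(np.arange(10.0), s)


class TestTimeSeries:
    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError, match="non-finite"):
            TimeSeries(np.array([1.0, bad, 2.0]))


class TestHVG:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([3, 1, 2], {(0, 1), (0, 2), (1, 2)}),
            ([1, 3, 2], {(0, 1), (1, 2)}),
            ([1, 2, 3, 4, 5], {(i, i + 1) for i in range(4)}),  # monotone ramp
            ([2, 2, 2, 2], {(0, 1), (1, 2), (2, 3)}),  # ties block strictly
        ],
    )
    def test_edge_sets(self, values, expected):
        g = build_hvg(np.array(values, float))
        assert edge_set(g) == expected
        assert g.L == 0

    def test_monotone_decreasing_is_path(self):
        g = build_hvg(np.arange(30.0)[::-1])
        assert edge_set(g) == {(i, i + 1) for i in range(29)}

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_hvg(np.array([1.0]))


class TestLPHVG:
    def test_one_blocker_allowed(self):
        g = build_lphvg(np.array([1.0, 3.0, 2.0]), L=1)
        assert edge_set(g) == {(0, 1), (0, 2), (1, 2)}

    def test_monotone_ramp_l1(self):
        g = build_lphvg(np.arange(1.0, 6.0), L=1)
        expected = {(i, i + 1) for i in range(4)} | {(i, i + 2) for i in range(3)}
        assert edge_set(g) == expected
        assert g.n_edges == 7

    def test_l0_equals_hvg(self, rng):
        for _ in range(20):
            y = rng.uniform(size=int(rng.integers(5, 200)))
            assert edge_set(build_lphvg(y, 0)) == edge_set(build_hvg(y))

    def test_negative_l_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            build_lphvg(np.array([1.0, 2.0]), L=-1)

    def test_monotone_in_l(self, rng):
        for _ in range(15):
            y = rng.uniform(size=int(rng.integers(10, 150)))
            prev = edge_set(build_lphvg(y, 0))
            for L in (1, 2, 3):
                cur = edge_set(build_lphvg(y, L))
                assert prev <= cur
                prev = cur

    def test_consecutive_pairs_always_connected_and_connected_graph(self, rng):
        import networkx as nx

        for L in (0, 1, 2):
            y = rng.uniform(size=80)
            g = build_lphvg(y, L)
            assert {(i, i + 1) for i in range(79)} <= edge_set(g)
            assert nx.is_connected(g.to_networkx())


class TestOracleEquivalence:
    def test_matches_fast_construction(self, rng):
        for _ in range(30):
            y = rng.uniform(size=int(rng.integers(10, 200)))
            for L in (0, 1, 2):
                assert edge_set(build_lphvg(y, L)) == edge_set(
                    build_lphvg_oracle(y, L)
                )

    def test_oracle_on_known_cases(self):
        assert edge_set(build_lphvg_oracle([3.0, 1.0, 2.0], 0)) == {
            (0, 1),
            (0, 2),
            (1, 2),
        }
        assert edge_set(build_lphvg_oracle([2.0, 2.0, 2.0, 2.0], 0)) == {
            (0, 1),
            (1, 2),
            (2, 3),
        }


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    values=st.lists(st.integers(-1000, 1000), min_size=2, max_size=60),
    L=st.integers(0, 2),
)
def test_lphvg_properties(values, L):
    """Edge-set equality with the oracle, shift/scale invariance and basic
    structural invariants on arbitrary series with ties.  Integer-valued
    samples keep the affine transform exact in floating point."""
    y = np.array(values, dtype=float)
    g = build_lphvg(y, L)
    assert set(g.sorted_edges()) == set(build_lphvg_oracle(y, L).sorted_edges())
    # affine amplitude invariance (positive scale + shift)
    g2 = build_lphvg(2.5 * y + 7.0, L)
    assert g.edges == g2.edges
    # simple graph on time-ordered indices
    for i, j in g.edges:
        assert 0 <= i < j < len(values)
    assert {(i, i + 1) for i in range(len(values) - 1)} <= set(g.sorted_edges())


class TestMultiscale:
    def test_node_counts(self, rng):
        x = TimeSeries(rng.uniform(size=100))
        ms = build_mlphvg(x, [1, 2, 5], L=1)
        assert [ms[s].n_nodes for s in ms.scales] == [100, 50, 20]
        assert ms.L == 1

    def test_scale_one_matches_raw_series(self, rng):
        x = rng.uniform(size=64)
        ms = build_mlphvg(x, [1], L=2)
        assert ms[1].edges == build_lphvg(x, 2).edges

    def test_graph_equals_composition(self, rng):
        x = TimeSeries(rng.uniform(size=90))
        ms = build_mlphvg(x, [3], L=1)
        assert ms[3].edges == build_lphvg(coarse_grain(x, 3), 1).edges

    def test_l0_subset_of_l1_across_scales(self, rng):
        x = TimeSeries(rng.uniform(size=200))
        m0 = build_mlphvg(x, range(1, 6), L=0)
        m1 = build_mlphvg(x, range(1, 6), L=1)
        for s in m0.scales:
            assert m0[s].edges <= m1[s].edges

    def test_scale_leaving_single_point_rejected(self):
        with pytest.raises(InvalidScaleError, match="s=6"):
            build_mlphvg(np.arange(10.0), [1, 6], L=0)
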