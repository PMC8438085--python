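"""Per-farm edge estimation, FDR control, wTO transform and consensus."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from milktrace.io_tables import COMPARTMENTS, canonical_pair
from milktrace.transfer_network import (
    FarmEdgeEstimate,
    FarmNetwork,
    bh_adjust,
    build_farm_network,
    consensus,
    fdr_adjust,
    pair_correlation,
    significant_links,
    wto_transform,
)


def naive_pearson(a, b):
    """Two-pass covariance oracle for the correlation coefficient."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    da, db = a - a.mean(), b - b.mean()
    return float(np.sum(da * db) / math.sqrt(np.sum(da**2) * np.sum(db**2)))


class TestPairCorrelation:
    def test_identical_vectors(self):
        r, p, n = pair_correlation([0.1, 0.2, 0.7], [0.1, 0.2, 0.7])
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_hand_computed_example(self):
        # covariance arithmetic: sum dxdy = 0.04, sum dx^2 = sum dy^2 = 0.05
        r, p, n = pair_correlation([0.1, 0.2, 0.3, 0.4], [0.1, 0.3, 0.2, 0.4])
        assert r == pytest.approx(0.8, abs=1e-12)
        assert n == 4

    def test_exclusion_of_doubly_absent_genera(self):
        r, p, n = pair_correlation(
            [0.5, 0.5, 0, 0, 0], [0, 0, 0.5, 0.5, 0]
        )
        assert n == 4  # genus 5 dropped
        assert r == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        r, p, n = pair_correlation([0.25, 0.25, 0.25, 0.25], [0.1, 0.2, 0.3, 0.4])
        assert r is None and p is None

    def test_too_few_genera_undefined(self):
        r, p, n = pair_correlation([0.5, 0.5, 0], [0.3, 0.7, 0])
        assert r is None and n == 2

    def test_matches_naive_covariance_oracle(self, rng):
        for _ in range(100):
            k = int(rng.integers(4, 50))
            a = rng.random(k) + 1e-3
            b = rng.random(k) + 1e-3
            r, _, _ = pair_correlation(a, b)
            assert r == pytest.approx(naive_pearson(a, b), abs=1e-12)

    def test_log_transform_changes_scale_not_exclusion(self):
        a = [0.5, 0.5, 0, 0.0, 0]
        b = [0, 0.1, 0.4, 0.5, 0]
        _, _, n = pair_correlation(a, b, transform="log10")
        assert n == 4


class TestFdrAdjust:
    def _estimates(self, pvals):
        return [
            FarmEdgeEstimate(
                farm=f"F{i}", pair=("soil", "milk"), r=0.5, p=p, n_genera=100
            )
            for i, p in enumerate(pvals)
        ]

    def test_single_test_identity(self):
        est = fdr_adjust(self._estimates([0.02]), alpha=0.05)
        assert est[0].q == pytest.approx(0.02)

    def test_hand_computed_bh_example(self):
        # step-up min_{j>=i} p_j * m / j: all become 0.04
        est = fdr_adjust(self._estimates([0.01, 0.02, 0.03, 0.04]))
        assert [e.q for e in est] == pytest.approx([0.04] * 4)

    def test_q_monotone_in_sorted_p(self, rng):
        pvals = np.sort(rng.random(50))
        q = bh_adjust(pvals)
        assert (np.diff(q) >= -1e-15).all()

    def test_undefined_edges_pass_through(self):
        ests = self._estimates([0.0001]) + [
            FarmEdgeEstimate(farm="X", pair=("soil", "milk"), r=None, p=None, n_genera=1)
        ]
        out = fdr_adjust(ests, alpha=0.001)
        assert out[1].q is None and not out[1].significant


class TestFarmNetwork:
    def _est(self, pair, r, sig):
        return FarmEdgeEstimate(
            farm="F", pair=canonical_pair(*pair), r=r, p=0.0001, n_genera=100,
            q=0.0001, significant=sig,
        )

    def test_all_significant(self):
        pairs = [
            ("soil", "phyllosphere"), ("soil", "cow-teat"), ("soil", "milk"),
            ("phyllosphere", "cow-teat"), ("phyllosphere", "milk"),
            ("cow-teat", "milk"),
        ]
        net = build_farm_network([self._est(p, 0.5, True) for p in pairs])
        adj = net.adjacency()
        assert (adj.to_numpy() == adj.to_numpy().T).all()
        assert np.count_nonzero(adj.to_numpy()) == 12  # 6 undirected edges
        assert np.diag(adj.to_numpy()).sum() == 0

    def test_non_significant_edges_zeroed(self):
        net = build_farm_network(
            [self._est(("soil", "milk"), 0.9, False)]
        )
        assert net.weight("soil", "milk") == 0.0

    def test_missing_compartment_flagged_absent(self):
        net = build_farm_network([self._est(("soil", "phyllosphere"), 0.4, True)])
        assert "milk" not in net.present


class TestWtoTransform:
    def _net(self, weights):
        return FarmNetwork(farm="F", weights={canonical_pair(*k): v for k, v in weights.items()})

    def test_fully_connected_unit_triangle(self):
        # 3-node unit weights: omega = (1 + 1) / (2 + 1 - 1) = 1
        net = FarmNetwork(
            farm="F",
            weights={
                ("soil", "phyllosphere"): 1.0,
                ("soil", "cow-teat"): 1.0,
                ("phyllosphere", "cow-teat"): 1.0,
            },
            present=frozenset({"soil", "phyllosphere", "cow-teat"}),
        )
        out = wto_transform(net)
        for w in out.weights.values():
            assert w == pytest.approx(1.0)

    def test_single_edge(self):
        # omega = 0.5 / (0.5 + 1 - 0.5) = 0.5
        net = self._net({("soil", "phyllosphere"): 0.5})
        out = wto_transform(net)
        assert out.weight("soil", "phyllosphere") == pytest.approx(0.5)

    def test_empty_network_stays_empty(self):
        out = wto_transform(FarmNetwork(farm="F", weights={}))
        assert all(w == 0 for w in out.weights.values())

    def test_matches_direct_formula_on_random_networks(self, rng):
        for _ in range(50):
            weights = {
                canonical_pair(a, b): float(rng.uniform(-1, 1))
                for i, a in enumerate(COMPARTMENTS)
                for b in COMPARTMENTS[i + 1 :]
            }
            net = FarmNetwork(farm="F", weights=weights)
            out = wto_transform(net)
            adj = net.adjacency().to_numpy()
            k = np.abs(adj).sum(axis=1)
            for i in range(4):
                for j in range(i + 1, 4):
                    shared = sum(
                        adj[i, u] * adj[u, j] for u in range(4) if u not in (i, j)
                    )
                    expected = (adj[i, j] + shared) / (
                        min(k[i], k[j]) + 1 - abs(adj[i, j])
                    )
                    pair = canonical_pair(COMPARTMENTS[i], COMPARTMENTS[j])
                    assert out.weights[pair] == pytest.approx(expected, abs=1e-12)


class TestConsensus:
    def _nets(self, weights_per_farm, pair=("soil", "phyllosphere")):
        return [
            FarmNetwork(farm=f"F{i}", weights={pair: w})
            for i, w in enumerate(weights_per_farm)
        ]

    def test_unanimity_identity(self):
        edges = consensus(self._nets([0.4, 0.4, 0.4]), n_boot=100, seed=0)
        e = [e for e in edges if e.pair == ("soil", "phyllosphere")][0]
        assert e.consensus_weight == pytest.approx(0.4)

    def test_sign_cancellation(self):
        edges = consensus(self._nets([0.5, -0.5]), n_boot=100, seed=0)
        e = [e for e in edges if e.pair == ("soil", "phyllosphere")][0]
        assert e.consensus_weight == pytest.approx(0.0, abs=1e-12)

    def test_weighted_average_example(self):
        # alpha = (0.8, 0.2) -> CN = 0.64 + 0.04 = 0.68
        edges = consensus(self._nets([0.8, 0.2]), n_boot=100, seed=0)
        e = [e for e in edges if e.pair == ("soil", "phyllosphere")][0]
        assert e.consensus_weight == pytest.approx(0.68)

    def test_convexity_bound_and_order_invariance(self, rng):
        for _ in range(30):
            w = rng.uniform(-1, 1, size=int(rng.integers(2, 10)))
            edges = consensus(self._nets(list(w)), n_boot=50, seed=1)
            e = [e for e in edges if e.pair == ("soil", "phyllosphere")][0]
            assert abs(e.consensus_weight) <= np.max(np.abs(w)) + 1e-12
            shuffled = consensus(self._nets(list(w[::-1])), n_boot=50, seed=1)
            e2 = [x for x in shuffled if x.pair == ("soil", "phyllosphere")][0]
            assert e2.consensus_weight == pytest.approx(e.consensus_weight)

    def test_duplication_invariance(self):
        w = [0.7, 0.1, -0.3]
        e1 = consensus(self._nets(w), n_boot=50, seed=0)[0].consensus_weight
        e2 = consensus(self._nets(w + w), n_boot=50, seed=0)[0].consensus_weight
        assert e2 == pytest.approx(e1)

    def test_undefined_edges_excluded_from_weighting(self):
        nets = self._nets([0.6, float("nan"), 0.6])
        e = consensus(nets, n_boot=100, seed=0)[0]
        assert e.consensus_weight == pytest.approx(0.6)
        assert e.n_farms == 2

    def test_nodes_absent_anywhere_are_removed(self):
        full = FarmNetwork(farm="A", weights={("soil", "phyllosphere"): 0.5})
        partial = FarmNetwork(
            farm="B",
            weights={("soil", "phyllosphere"): 0.5},
            present=frozenset({"soil", "phyllosphere", "cow-teat"}),
        )
        edges = consensus([full, partial], n_boot=50, seed=0)
        assert all("milk" not in e.pair for e in edges)

    def test_needs_two_networks(self):
        with pytest.raises(ValueError):
            consensus(self._nets([0.5]), n_boot=10, seed=0)

    def test_p_value_floor_and_significance_threshold(self):
        nets = self._nets([0.5] * 30)
        edges = consensus(nets, n_boot=2000, seed=0)
        e = edges[0]
        assert e.p_value == pytest.approx(1 / 2001)
        assert significant_links(edges, alpha=0.001)[0].pair == e.pair
        # strict threshold: p exactly at alpha is dropped
        e.p_value = 0.001
        assert significant_links([e], alpha=0.001) == []
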