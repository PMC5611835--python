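"""C3Net / bagged-ensemble inference against brute-force oracles."""

import math

import numpy as np
import pytest

from grnloop.inference import (
    InferenceParams,
    bc3net,
    bc3net10,
    c3net,
    edge_pvalue,
    ensemble_edge_pvalue,
    mi_null,
    network_overlap,
    required_null_size,
)
from grnloop.io import DISEASED, ExpressionMatrix
from grnloop.mi import MIMatrix, pearson_mi
from grnloop.network import WeightedNetwork, edge_key


def _matrix(values, rng_tag="s"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"G{i}" for i in range(values.shape[0])],
        [f"{rng_tag}{j}" for j in range(values.shape[1])],
        values,
        [DISEASED] * values.shape[1],
    )


def _mim(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    return MIMatrix(ids, values, "pearson", 10)


PERMISSIVE_NULL = np.zeros(1000)  # every positive MI is maximally significant


def brute_force_c3net(mim, null, alpha1):
    """Independent re-implementation: per-gene argmax over significant partners."""
    p = mim.n_genes
    n_pairs = p * (p - 1) // 2
    edges = set()
    for i in range(p):
        candidates = []
        for j in range(p):
            if j == i:
                continue
            n_ge = sum(1 for v in null if v >= mim.values[i, j])
            pval = (1 + n_ge) / (1 + len(null))
            if pval * n_pairs <= alpha1:
                candidates.append(j)
        if not candidates:
            continue
        best_mi = max(mim.values[i, j] for j in candidates)
        winners = [j for j in candidates if mim.values[i, j] == best_mi]
        j_star = min(winners, key=lambda j: mim.gene_ids[j])
        edges.add(edge_key(mim.gene_ids[i], mim.gene_ids[j_star]))
    return edges


class TestEdgePvalue:
    def test_add_one_rule_above_all(self):
        null = np.sort(np.linspace(0, 1, 999))
        assert edge_pvalue(2.0, null) == pytest.approx(1 / 1000)

    def test_below_all_gives_one(self):
        null = np.sort(np.linspace(0.5, 1, 999))
        assert edge_pvalue(0.1, null) == pytest.approx(1.0)

    def test_at_median_is_about_half(self):
        null = np.sort(np.arange(1, 1002, dtype=float))  # odd size, median 501
        # direct count: 501 values >= 501
        assert edge_pvalue(501.0, null) == pytest.approx((1 + 501) / (1 + 1001))


class TestMiNull:
    def test_contract_sorted_length(self, rng):
        m = _matrix(rng.normal(size=(6, 20)))
        null = mi_null(m, 1000, rng)
        assert null.shape == (1000,)
        assert np.all(np.diff(null) >= 0)

    def test_deterministic_under_seed(self, rng):
        m = _matrix(rng.normal(size=(6, 20)))
        a = mi_null(m, 1000, np.random.default_rng(5))
        b = mi_null(m, 1000, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_median_matches_independent_pair_reference(self):
        # i.i.d. noise: the null's median should match a Monte-Carlo
        # reference of MI between independent vectors of the same length
        rng = np.random.default_rng(11)
        m_samples = 40
        m = _matrix(rng.normal(size=(30, m_samples)))
        null = mi_null(m, 20_000, np.random.default_rng(1))
        ref_rng = np.random.default_rng(2)
        ref = np.array(
            [
                pearson_mi(ref_rng.normal(size=m_samples), ref_rng.normal(size=m_samples))
                for _ in range(4000)
            ]
        )
        assert np.median(null) == pytest.approx(np.median(ref), rel=0.15)

    def test_rejects_small_n_perm(self, rng):
        m = _matrix(rng.normal(size=(4, 10)))
        with pytest.raises(ValueError):
            mi_null(m, 500, rng)

    def test_required_null_size_threshold(self):
        # with exactly this null size the best achievable corrected p equals alpha
        for p, alpha in [(10, 0.05), (50, 0.01), (300, 0.05)]:
            n = required_null_size(p, alpha)
            n_pairs = p * (p - 1) // 2
            assert (1 / (1 + n)) * n_pairs <= alpha
            assert (1 / n) * n_pairs > alpha


class TestC3Net:
    def test_three_gene_argmax_union(self):
        # A picks B (0.9), B picks A, C picks B (0.5) -> edges {AB, BC}
        values = np.array([[0, 0.9, 0.2], [0.9, 0, 0.5], [0.2, 0.5, 0]])
        net = c3net(_mim(values), PERMISSIVE_NULL, alpha1=0.05)
        assert net.edge_set() == {("G0", "G1"), ("G1", "G2")}
        assert all(w == 1.0 for w in net.edges.values())

    def test_nothing_significant_all_isolated(self):
        values = np.array([[0, 0.9], [0.9, 0]])
        strict_null = np.full(1000, 10.0)  # null dominates every MI
        net = c3net(_mim(values), strict_null, alpha1=0.05)
        assert net.n_edges == 0
        assert net.nodes == {"G0", "G1"}

    def test_tie_breaks_to_lexicographically_smallest(self):
        values = np.array(
            [[0, 0.7, 0.7, 0.1], [0.7, 0, 0.2, 0.1], [0.7, 0.2, 0, 0.1], [0.1, 0.1, 0.1, 0]]
        )
        ids = ["G0", "GZ", "GA", "GB"]
        net = c3net(_mim(values, ids), PERMISSIVE_NULL, 0.05)
        # G0 ties between GZ and GA -> picks GA
        assert net.has_edge("G0", "GA")

    def test_edge_count_bounded_by_gene_count(self, rng):
        for _ in range(20):
            p = int(rng.integers(3, 9))
            vals = np.abs(rng.normal(size=(p, p)))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            net = c3net(_mim(vals), PERMISSIVE_NULL, 0.05)
            assert net.n_edges <= p

    def test_matches_brute_force_oracle(self, rng):
        null = np.sort(rng.uniform(0, 0.6, size=1500))
        for _ in range(50):
            p = int(rng.integers(3, 9))
            vals = np.abs(rng.normal(0, 0.4, size=(p, p)))
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0)
            mim = _mim(vals)
            assert c3net(mim, null, 0.3).edge_set() == brute_force_c3net(mim, null, 0.3)


class TestEnsembleBinomial:
    def test_tail_matches_direct_summation(self):
        B, p0 = 100, 0.01
        for k in [1, 2, 5, 10]:
            direct = sum(
                math.comb(B, x) * p0**x * (1 - p0) ** (B - x) for x in range(k, B + 1)
            )
            assert ensemble_edge_pvalue(k, B, p0) == pytest.approx(direct, rel=1e-10)

    def test_printed_example_tail_value(self):
        # k=5 successes in B=100 at density 0.01: tail ~ 3.4e-3
        assert ensemble_edge_pvalue(5, 100, 0.01) == pytest.approx(0.00343, abs=5e-5)

    def test_zero_count_tail_is_one(self):
        assert ensemble_edge_pvalue(0, 100, 0.01) == 1.0


def _block_matrix(rng, n_genes=12, block=6, rho=0.9, m=40):
    """Small matrix with one strongly equicorrelated block."""
    values = rng.standard_normal((n_genes, m))
    z = rng.standard_normal(m)
    values[:block] = np.sqrt(rho) * z + np.sqrt(1 - rho) * values[:block]
    return _matrix(values)


class TestBaggedEnsembles:
    PARAMS = InferenceParams(B=20, R=3, n_perm=2000)

    def test_deterministic_under_seed(self, rng):
        m = _block_matrix(np.random.default_rng(0))
        a = bc3net(m, self.PARAMS, np.random.default_rng(9))
        b = bc3net(m, self.PARAMS, np.random.default_rng(9))
        assert a == b

    def test_weights_are_bootstrap_frequencies(self):
        m = _block_matrix(np.random.default_rng(0))
        net = bc3net(m, self.PARAMS, np.random.default_rng(9))
        assert net.n_edges > 0
        for (u, v), w in net.edges.items():
            k = round(w * self.PARAMS.B)
            assert w == pytest.approx(k / self.PARAMS.B)
            assert 0 < w <= 1.0
        assert net.nodes == set(m.gene_ids)

    def test_bc3net10_mean_of_runs_with_absent_as_zero(self):
        m = _block_matrix(np.random.default_rng(1))
        params = InferenceParams(B=10, R=4, n_perm=2000)
        rng = np.random.default_rng(4)
        runs = [bc3net(m, params, s) for s in np.random.default_rng(4).spawn(4)]
        net = bc3net10(m, params, np.random.default_rng(4))
        assert net.nodes == set.union(*[r.nodes for r in runs])
        for e, w in net.edges.items():
            total = sum(r.edges.get(e, 0.0) for r in runs)
            assert w == pytest.approx(total / 4)
        # every positive-weight run edge appears in the mean network
        for r in runs:
            assert set(r.edges) <= set(net.edges)

    def test_bc3net10_single_repeat_equals_bc3net(self):
        m = _block_matrix(np.random.default_rng(2))
        params = InferenceParams(B=10, R=1, n_perm=2000)
        single = bc3net(m, params, np.random.default_rng(7).spawn(1)[0])
        ensemble = bc3net10(m, params, np.random.default_rng(7))
        assert ensemble == single

    def test_bc3net_edges_subset_of_bootstrap_union(self):
        # candidate filtering can only remove edges, never invent them
        m = _block_matrix(np.random.default_rng(3))
        net = bc3net(m, self.PARAMS, np.random.default_rng(3))
        full = bc3net(
            m,
            InferenceParams(B=20, R=3, n_perm=2000, alpha2=1.0),
            np.random.default_rng(3),
        )
        assert set(net.edges) <= set(full.edges)

    def test_bc3net10_weight_bounds(self):
        m = _block_matrix(np.random.default_rng(5))
        params = InferenceParams(B=10, R=3, n_perm=2000)
        runs = [bc3net(m, params, s) for s in np.random.default_rng(6).spawn(3)]
        net = bc3net10(m, params, np.random.default_rng(6))
        for e, w in net.edges.items():
            per_run = [r.edges.get(e, 0.0) for r in runs]
            assert w <= max(per_run) + 1e-12
            positives = [x for x in per_run if x > 0]
            assert w >= min(positives) / params.R - 1e-12


class TestNetworkOverlap:
    def _net(self, edges, nodes=()):
        net = WeightedNetwork(nodes=nodes)
        for u, v, w in edges:
            net.add_edge(u, v, w)
        return net

    def test_identical_networks(self):
        n = self._net([("A", "B", 0.5), ("B", "C", 0.9)])
        assert network_overlap([n, n.copy()]) == (1.0, 1.0)

    def test_disjoint_edges_same_nodes(self):
        a = self._net([("A", "B", 0.5)], nodes={"A", "B", "C"})
        b = self._net([("B", "C", 0.5)], nodes={"A", "B", "C"})
        eo, no = network_overlap([a, b])
        assert eo == 0.0 and no == 1.0

    def test_jaccard_arithmetic(self):
        a = self._net([("a", "b", 0.9), ("b", "c", 0.9), ("c", "d", 0.9)])
        b = self._net([("a", "b", 0.9), ("b", "c", 0.9), ("c", "e", 0.9)])
        eo, _ = network_overlap([a, b])
        assert eo == pytest.approx(2 / 4)

    def test_cutoff_shrinks_edge_sets_monotonically(self):
        a = self._net([("a", "b", 0.4), ("b", "c", 0.6), ("c", "d", 0.9)])
        for cutoff in [0.0, 0.5, 0.7]:
            kept = {e for e, w in a.edges.items() if w >= cutoff}
            assert kept <= {e for e, w in a.edges.items() if w >= 0.0}

    def test_requires_two_networks(self):
        with pytest.raises(ValueError):
            network_overlap([self._net([("a", "b", 1.0)])])
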