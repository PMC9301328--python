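"""Signed TRF-correlation networks: thresholding, modularity, detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import trfnet
from trfnet.network import _signed_q, canonical_labels


def set_partitions(items):
    """All set partitions (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def modularity_oracle(w, labels, gamma=1.0):
    """Double-loop signed modularity, written independently of the package."""
    n = w.shape[0]
    wp = np.where(w > 0, w, 0.0)
    wn = np.where(w < 0, -w, 0.0)
    out = {}
    for ws in (wp, wn):
        v = ws.sum()
        if v == 0:
            out[id(ws)] = 0.0
            continue
        k = ws.sum(axis=1)
        q = 0.0
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    q += ws[i, j] - gamma * k[i] * k[j] / v
        out[id(ws)] = q / v
    vp, vn = wp.sum(), wn.sum()
    return out[id(wp)] - (vn / (vp + vn)) * out[id(wn)]


class TestTrfConnectivity:
    def test_identical_rows_fully_connected(self):
        w = np.tile(np.sin(np.linspace(0, 6, 50)), (4, 1))
        c = trfnet.trf_connectivity(w)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(c.values[off], 1.0)

    def test_negated_row_anticorrelated(self):
        base = np.sin(np.linspace(0, 6, 50))
        c = trfnet.trf_connectivity(np.stack([base, -base]))
        assert c.values[0, 1] == pytest.approx(-1.0)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal((4, 30))
        c = trfnet.trf_connectivity(w)
        for i in range(4):
            for j in range(4):
                xi, xj = w[i] - w[i].mean(), w[j] - w[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert c.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_rows(self):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((20, 30))
        w[3] = 5.0  # constant row -> missing correlations
        c = trfnet.trf_connectivity(w)
        assert np.all(np.isnan(c.values[3, [0, 1, 2, 4]]))
        assert c.values[3, 3] == 1.0
        w[:5] = 1.0  # 25% degenerate -> error
        with pytest.raises(ValueError):
            trfnet.trf_connectivity(w)


class TestEdgeCount:
    @pytest.mark.parametrize("n,expected", [(68, 2278), (2, 1), (10, 45)])
    def test_values(self, n, expected):
        assert trfnet.edge_count(n) == expected

    def test_matches_enumeration(self):
        assert trfnet.edge_count(10) == len(list(itertools.combinations(range(10), 2)))

    def test_too_few_nodes(self):
        with pytest.raises(ValueError):
            trfnet.edge_count(1)


class TestThresholdDensity:
    def test_full_density_keeps_everything(self):
        rng = np.random.default_rng(2)
        c = rng.uniform(-1, 1, (6, 6))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        g = trfnet.threshold_density(c, 1.0)
        assert g.n_edges == trfnet.edge_count(6)

    def test_density_014_on_68_nodes_keeps_319_edges(self):
        rng = np.random.default_rng(3)
        c = rng.uniform(-1, 1, (68, 68))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        g = trfnet.threshold_density(c, 0.14)
        assert g.n_edges == 319  # ceil(0.14 * 2278)

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(4)
        c = rng.uniform(-1, 1, (8, 8))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        t = 0.3
        g = trfnet.threshold_density(c, t)
        iu = np.triu_indices(8, 1)
        vals = sorted(zip(np.abs(c[iu]), iu[0], iu[1]), key=lambda x: (-x[0], x[1], x[2]))
        m = int(np.ceil(t * len(vals)))
        kept = {(i, j) for _, i, j in vals[:m]}
        found = {(i, j) for i, j in zip(*np.nonzero(np.triu(g.values, 1)))}
        assert found == kept
        for i, j in kept:
            assert g.values[i, j] == c[i, j]  # signs and weights preserved

    def test_binarize(self):
        c = np.array([[1.0, 0.9, -0.8], [0.9, 1.0, 0.1], [-0.8, 0.1, 1.0]])
        g = trfnet.threshold_density(c, 0.67, binarize=True)
        assert set(np.unique(g.values)) <= {-1.0, 0.0, 1.0}

    @pytest.mark.parametrize("t", [0.0, -0.1, 1.5])
    def test_invalid_density(self, t):
        with pytest.raises(ValueError):
            trfnet.threshold_density(np.eye(4), t)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000), st.floats(min_value=0.01, max_value=1.0))
    def test_edge_count_invariant(self, seed, t):
        rng = np.random.default_rng(seed)
        n = 7
        c = rng.uniform(-1, 1, (n, n))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1.0)
        g = trfnet.threshold_density(c, t)
        assert g.n_edges == int(np.ceil(t * trfnet.edge_count(n)))
        np.testing.assert_array_equal(g.values, g.values.T)


class TestModularitySigned:
    def test_all_positive_complete_graph_single_community_is_zero(self):
        w = np.ones((5, 5)) - np.eye(5)
        assert trfnet.modularity_signed(w, np.ones(5, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0.0)
        q = trfnet.modularity_signed(w, [1, 1, 1, 2, 2, 2])
        assert q == pytest.approx(0.5, abs=1e-12)

    def test_matches_exhaustive_oracle_on_signed_toy(self):
        rng = np.random.default_rng(5)
        w = rng.uniform(-1, 1, (6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        for part in set_partitions(list(range(6))):
            labels = np.empty(6, dtype=int)
            for ci, group in enumerate(part, start=1):
                labels[group] = ci
            labels = canonical_labels(labels)
            assert trfnet.modularity_signed(w, labels) == pytest.approx(
                modularity_oracle(w, labels), abs=1e-10
            )

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ValueError):
            trfnet.modularity_signed(np.zeros((4, 4)), np.ones(4, dtype=int))


class TestDetectCommunities:
    def test_two_cliques_recovered_every_run(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0.0)
        for seed in range(5):
            p = trfnet.detect_communities(w, n_runs=3, seed=seed)
            assert p.n_communities == 2
            np.testing.assert_array_equal(p.labels, [1, 1, 1, 2, 2, 2])

    def test_planted_four_block_signed_recovery(self):
        rng = np.random.default_rng(6)
        n = 40
        truth = np.repeat(np.arange(4), 10)
        w = np.where(truth[:, None] == truth[None, :], 0.8, -0.2)
        w = w + 0.05 * ((lambda a: (a + a.T) / 2)(rng.standard_normal((n, n))))
        np.fill_diagonal(w, 0.0)
        p = trfnet.detect_communities(w, n_runs=20, seed=7)
        assert adjusted_rand_score(truth, p.labels) == 1.0

    def test_quality_is_self_consistent(self):
        rng = np.random.default_rng(8)
        w = rng.uniform(-1, 1, (12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        p = trfnet.detect_communities(w, n_runs=10, seed=9)
        assert p.quality == pytest.approx(trfnet.modularity_signed(w, p), abs=1e-12)

    def test_never_below_single_community_baseline(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            w = rng.uniform(-1, 1, (10, 10))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            p = trfnet.detect_communities(w, n_runs=5, seed=seed)
            assert p.quality >= _signed_q(w, np.ones(10, dtype=int), 1.0) - 1e-12

    def test_determinism(self):
        rng = np.random.default_rng(10)
        w = rng.uniform(-1, 1, (15, 15))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        a = trfnet.detect_communities(w, n_runs=10, seed=11)
        b = trfnet.detect_communities(w, n_runs=10, seed=11)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            trfnet.detect_communities(np.zeros((4, 4)), seed=0)


def test_mean_connectivity_fisher_average():
    a = np.array([[1.0, 0.4], [0.4, 1.0]])
    b = np.array([[1.0, 0.8], [0.8, 1.0]])
    m = trfnet.mean_connectivity([a, b])
    expected = np.tanh((np.arctanh(0.4) + np.arctanh(0.8)) / 2)
    assert m.values[0, 1] == pytest.approx(expected, abs=1e-9)
    assert m.values[0, 0] == 1.0
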