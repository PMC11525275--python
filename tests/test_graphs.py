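"""Graph metrics: hand-computed oracles, exhaustive checks, consensus clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest

from wmhnet import graphs

rng = np.random.default_rng(5)


def _adj(edges, n, weights=None):
    W = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        w = 1.0 if weights is None else weights[k]
        W[i, j] = W[j, i] = w
    return W


TRIANGLE = _adj([(0, 1), (1, 2), (0, 2)], 3)
PATH = _adj([(0, 1), (1, 2)], 3)
TWO_TRIANGLES = _adj([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], 6)


class TestDensity:
    def test_complete_graph(self):
        assert graphs.density(TRIANGLE) == 1.0

    def test_partial_graph(self):
        assert graphs.density(PATH) == pytest.approx(2 / 3)

    def test_generator_cohort_density(self, connectomes, config):
        d = np.mean([graphs.density(W) for W in connectomes.matrices])
        assert d == pytest.approx(config.base_density_target, abs=0.05)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            graphs.density(-TRIANGLE)


class TestClustering:
    def test_unweighted_triangle(self):
        assert graphs.clustering_coefficient(TRIANGLE) == pytest.approx(1.0)

    def test_path_graph(self):
        assert graphs.clustering_coefficient(PATH) == 0.0

    def test_weighted_triangle_formula_oracle(self):
        W = _adj([(0, 1), (0, 2), (1, 2)], 3, weights=[1.0, 0.5, 0.5])
        # node 0 (incident 1, 0.5; opposite 0.5): (1*0.5*0.5)^(1/3)
        c0 = (1.0 * 0.5 * 0.5) ** (1 / 3)
        c1 = (1.0 * 0.5 * 0.5) ** (1 / 3)
        c2 = (0.5 * 0.5 * 1.0) ** (1 / 3)
        assert graphs.clustering_coefficient(W) == pytest.approx((c0 + c1 + c2) / 3)
        assert c0 == pytest.approx(0.630, abs=1e-3)

    def test_matches_networkx_onnela(self):
        W = rng.random((12, 12))
        W = np.triu(W, 1) * (rng.random((12, 12)) < 0.5)
        W = W + W.T
        G = nx.from_numpy_array(W)
        ref = np.mean(list(nx.clustering(G, weight="weight").values()))
        assert graphs.clustering_coefficient(W) == pytest.approx(ref, abs=1e-10)

    def test_all_zero_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert graphs.clustering_coefficient(np.zeros((4, 4))) == 0.0


class TestModularity:
    def test_single_module_is_zero(self):
        assert graphs.modularity_q(TWO_TRIANGLES, np.zeros(6)) == pytest.approx(0.0)

    def test_two_disjoint_triangles_hand_value(self):
        part = np.array([0, 0, 0, 1, 1, 1])
        assert graphs.modularity_q(TWO_TRIANGLES, part) == pytest.approx(0.5)

    def test_matches_networkx_with_resolution(self):
        W = rng.random((10, 10))
        W = np.triu(W, 1) * (rng.random((10, 10)) < 0.6)
        W = W + W.T
        part = rng.integers(0, 3, size=10)
        G = nx.from_numpy_array(W)
        comms = [set(np.flatnonzero(part == c)) for c in np.unique(part)]
        for gamma in (1.0, 1.25, 1.5):
            ref = nx.community.modularity(G, comms, weight="weight", resolution=gamma)
            assert graphs.modularity_q(W, part, gamma) == pytest.approx(ref, abs=1e-12)

    def test_true_partition_maximizes_on_two_clique_toy(self):
        W = _adj([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)], 6)
        true_q = graphs.modularity_q(W, np.array([0, 0, 0, 1, 1, 1]))
        for labels in itertools.product(range(6), repeat=6):
            assert graphs.modularity_q(W, np.array(labels)) <= true_q + 1e-12

    def test_additive_over_disconnected_components(self):
        # block-diagonal graph: Q contributions decompose by component
        A = _adj([(0, 1), (1, 2), (0, 2)], 3)
        B = _adj([(0, 1), (1, 2), (2, 3), (3, 0)], 4)
        W = np.zeros((7, 7))
        W[:3, :3], W[3:, 3:] = A, B
        part = np.array([0, 0, 0, 1, 1, 2, 2])
        mA, mB = A.sum() / 2, B.sum() / 2
        m = mA + mB

        def contribution(block, labels, offset, sblock):
            q = 0.0
            s = block.sum(axis=1)
            for c in np.unique(labels):
                idx = labels == c
                q += block[np.ix_(idx, idx)].sum() / (2 * m) - (s[idx].sum() / (2 * m)) ** 2
            return q

        expected = contribution(A, part[:3], 0, mA) + contribution(B, part[3:], 3, mB)
        assert graphs.modularity_q(W, part) == pytest.approx(expected, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            graphs.modularity_q(np.zeros((4, 4)), np.zeros(4))


class TestConsensus:
    def test_two_cliques_found_exactly(self):
        part, q = graphs.consensus_partition(TWO_TRIANGLES, n_runs=10, seed=0)
        assert len(set(part)) == 2
        assert np.array_equal(part[:3], [part[0]] * 3)
        assert q == pytest.approx(graphs.modularity_q(TWO_TRIANGLES, part))

    def test_recovers_planted_four_blocks(self):
        wins = 0
        labels = np.repeat(np.arange(4), 4)
        for s in range(10):
            g = np.random.default_rng(s)
            P = np.where(labels[:, None] == labels[None, :], 0.95, 0.08)
            A = (g.random((16, 16)) < P).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            part, _ = graphs.consensus_partition(A, n_runs=20, seed=s)
            exact = len(set(zip(labels.tolist(), part.tolist()))) == 4 and len(set(part)) == 4
            wins += exact
        assert wins >= 9

    def test_deterministic_given_seed(self, connectomes):
        W = connectomes.matrices[0]
        p1, q1 = graphs.consensus_partition(W, gamma=1.25, n_runs=8, seed=4)
        p2, q2 = graphs.consensus_partition(W, gamma=1.25, n_runs=8, seed=4)
        assert np.array_equal(p1, p2) and q1 == q2

    def test_louvain_never_beats_exhaustive_maximum(self):
        for s in range(5):
            g = np.random.default_rng(s)
            W = (g.random((7, 7)) < 0.4).astype(float)
            W = np.triu(W, 1)
            W = W + W.T
            if W.sum() == 0:
                continue
            part, q = graphs.consensus_partition(W, n_runs=10, seed=s)
            best = max(
                graphs.modularity_q(W, np.array(labels))
                for labels in itertools.product(range(4), repeat=7)
            )
            assert q <= best + 1e-12


class TestCommunicability:
    def test_empty_graph(self):
        assert graphs.communicability_global(np.zeros((3, 3))) == 0.0

    def test_two_node_closed_form_sinh(self):
        W = _adj([(0, 1)], 2)
        assert graphs.communicability_global(W) == pytest.approx(np.sinh(1.0), abs=1e-12)

    def test_invariant_to_global_weight_scaling(self, connectomes):
        W = connectomes.matrices[0]
        a = graphs.communicability_global(W)
        b = graphs.communicability_global(3.7 * W)
        assert a == pytest.approx(b, rel=1e-10)


class TestMetricRegressions:
    def _toy_tables(self, n=68, seed=0):
        import pandas as pd

        g = np.random.default_rng(seed)
        wmh = np.exp(g.standard_normal(n) + 6)
        pheno = pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(n)],
                "wmh_global_k07": wmh,
                "age_years": g.uniform(18, 78, n),
                "fluid": g.standard_normal(n),
            }
        )
        return pheno, np.log(wmh), g

    def test_exact_linear_metric(self):
        import pandas as pd

        pheno, lw, g = self._toy_tables()
        metrics = pd.DataFrame({"participant_id": pheno["participant_id"], "m": 2 * lw + 1})
        out = graphs.metrics_regressions(metrics, pheno)
        row = out[(out["metric"] == "m") & (out["model"] == "unadjusted")].iloc[0]
        assert row["beta"] == pytest.approx(1.0, abs=1e-10)
        assert row["r_squared"] == pytest.approx(1.0, abs=1e-10)

    def test_beta_b_sd_identity(self):
        import pandas as pd

        pheno, lw, g = self._toy_tables(seed=3)
        y = lw + g.standard_normal(len(lw))
        metrics = pd.DataFrame({"participant_id": pheno["participant_id"], "m": y})
        out = graphs.metrics_regressions(metrics, pheno)
        row = out[(out["model"] == "unadjusted")].iloc[0]
        assert row["beta"] == pytest.approx(
            row["b"] * lw.std(ddof=1) / y.std(ddof=1), abs=1e-10
        )

    def test_null_metric_ci_coverage(self):
        import pandas as pd

        covered = 0
        n_sim = 500
        for s in range(n_sim):
            pheno, lw, g = self._toy_tables(n=40, seed=20_000 + s)
            metrics = pd.DataFrame(
                {"participant_id": pheno["participant_id"], "m": g.standard_normal(40)}
            )
            out = graphs.metrics_regressions(metrics, pheno)
            row = out[out["model"] == "unadjusted"].iloc[0]
            covered += row["ci_low"] <= 0 <= row["ci_high"]
        assert covered / n_sim >= 0.93

    def test_misaligned_ids_rejected(self):
        import pandas as pd

        pheno, lw, g = self._toy_tables()
        metrics = pd.DataFrame({"participant_id": ["nope"], "m": [1.0]})
        with pytest.raises(Exception):
            graphs.metrics_regressions(metrics, pheno)
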