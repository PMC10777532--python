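"""Z-matrix gating, correlation network, threshold search, spinglass, modularity."""

import numpy as np
import pandas as pd
import pytest

from coloclust import network, synthetic, validation
from coloclust.coloc import ColocEvent
from coloclust.network import (ClusterConfig, ZMatrixConfig, build_zmatrix,
                               min_degree_threshold, modularity, snp_correlation,
                               spinglass_cluster, summarize_clusters)


def _event(lead, traits):
    return ColocEvent(region_id="r", traits=traits, method="multitrait",
                      lead_id=lead, accepted=True)


def _lookup(rows):
    """rows: {trait: {snp: (z, p, n)}} -> per-trait lookup tables."""
    out = {}
    for trait, snps in rows.items():
        out[trait] = pd.DataFrame(
            [{"SNP": s, "Z": z, "P": p, "N": n} for s, (z, p, n) in snps.items()]
        )
    return out


class TestBuildZmatrix:
    def test_sample_size_gates(self):
        events = [_event("v1", ("t2d", "big")), _event("v2", ("t2d", "small"))]
        lookup = _lookup({
            "big": {"v1": (5.0, 1e-6, 100_000), "v2": (5.0, 1e-6, 100_000)},
            "small": {"v1": (5.0, 1e-6, 50_000), "v2": (5.0, 1e-6, 50_000)},
        })
        z = build_zmatrix(events, lookup, index_trait="t2d")
        # p = 1e-6 fails the 5e-8 gate for N > 60k but passes 1e-5 for N < 60k
        assert z.loc["v1", "big"] == 0.0
        assert z.loc["v2", "small"] == 5.0

    def test_noncolocalized_trait_entries_stay_zero(self):
        events = [_event("v1", ("t2d", "a"))]
        lookup = _lookup({
            "a": {"v1": (9.0, 1e-18, 100_000)},
            "b": {"v1": (9.0, 1e-18, 100_000)},
        })
        z = build_zmatrix(events, lookup, index_trait="t2d", traits=["a", "b"])
        assert z.loc["v1", "a"] == 9.0 and z.loc["v1", "b"] == 0.0

    def test_unresolvable_lead_raises(self):
        events = [_event("v9", ("t2d", "a"))]
        lookup = _lookup({"a": {"v1": (9.0, 1e-18, 100_000)}})
        with pytest.raises(KeyError, match="v9"):
            build_zmatrix(events, lookup, index_trait="t2d")


class TestSnpCorrelation:
    def test_identical_and_anticorrelated_rows(self):
        z = pd.DataFrame([[1.0, -1.0, 0.0], [1.0, -1.0, 0.0], [-1.0, 1.0, 0.0]],
                         index=["a", "b", "c"], columns=["x", "y", "w"])
        corr = snp_correlation(z)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, rng):
        z = pd.DataFrame(rng.standard_normal((10, 6)))
        corr = snp_correlation(z).to_numpy()
        x = z.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        manual = (xc @ xc.T) / np.outer(np.linalg.norm(xc, axis=1),
                                        np.linalg.norm(xc, axis=1))
        assert np.max(np.abs(corr - manual)) < 1e-10

    def test_zero_variance_row_correlates_zero(self):
        z = pd.DataFrame([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]], index=["a", "b"])
        corr = snp_correlation(z)
        assert corr.loc["a", "b"] == 0.0 and corr.loc["b", "b"] == 1.0


class TestMinDegreeThreshold:
    def test_three_node_example(self):
        corr = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]])
        assert min_degree_threshold(corr) == pytest.approx(0.5)

    def test_complete_graph_constant_weight(self):
        corr = np.full((4, 4), 0.7)
        np.fill_diagonal(corr, 1.0)
        assert min_degree_threshold(corr) == pytest.approx(0.7)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            x = rng.standard_normal((10, 5))
            corr = np.corrcoef(x)
            assert (min_degree_threshold(corr)
                    == validation.brute_force_min_degree_threshold(corr))

    def test_isolated_vertex_excluded(self):
        corr = np.eye(3)
        corr[0, 1] = corr[1, 0] = 0.6
        assert min_degree_threshold(corr) == pytest.approx(0.6)


class TestModularity:
    def test_single_community_is_zero(self, rng):
        adj = np.abs(rng.standard_normal((6, 6)))
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        assert modularity(adj, np.zeros(6)) == pytest.approx(0.0)

    def test_two_triangles_hand_computation(self):
        assert validation.two_triangle_modularity() == pytest.approx(2 * (3 / 7 - 0.25),
                                                                     abs=1e-12)

    def test_matches_independent_oracle(self, rng):
        for _ in range(50):
            adj = rng.random((12, 12)) * (rng.random((12, 12)) < 0.4)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            labels = rng.integers(0, 3, 12)
            assert modularity(adj, labels) == pytest.approx(
                validation.brute_force_modularity(adj, labels), abs=1e-10)

    def test_relabeling_invariance(self, rng):
        adj = rng.random((8, 8))
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        labels = np.array([0, 0, 1, 1, 2, 2, 2, 0])
        perm = np.array([5, 7, 2])  # arbitrary relabeling
        assert modularity(adj, labels) == pytest.approx(modularity(adj, perm[labels]))


class TestSpinglass:
    def _clique_pair_corr(self):
        # two 5-cliques (weight 0.9 inside) joined by one weak edge
        corr = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        corr[i, j] = 0.9
        corr[4, 5] = corr[5, 4] = 0.3
        np.fill_diagonal(corr, 1.0)
        return pd.DataFrame(corr, index=[f"v{i}" for i in range(10)],
                            columns=[f"v{i}" for i in range(10)])

    def test_two_cliques_recovered(self):
        corr = self._clique_pair_corr()
        sol = spinglass_cluster(corr, cutoff=0.3, cfg=ClusterConfig(seed=0, n_restarts=4))
        labels = sol.labels(list(corr.index))
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        assert sol.retained and sol.k == 2

    def test_small_cluster_excluded_from_retained(self):
        corr = self._clique_pair_corr().iloc[:8, :8]  # 5-clique + 3-clique
        sol = spinglass_cluster(corr, cutoff=0.3, cfg=ClusterConfig(seed=0, n_restarts=4))
        counts = pd.Series(sol.labels(list(corr.index))).value_counts()
        small = counts.index[counts < 4]
        assert all(c not in sol.retained for c in small)
        assert len(sol.retained) == 1

    def test_beats_random_partitions(self, rng):
        corr = self._clique_pair_corr()
        sol = spinglass_cluster(corr, cutoff=0.3, cfg=ClusterConfig(seed=1, n_restarts=4))
        names, pruned = network._prune(corr, 0.3)
        rand_q = [modularity(pruned, rng.integers(0, 3, 10)) for _ in range(100)]
        assert sol.modularity >= max(rand_q)

    def test_planted_three_cluster_recovery_single_seed(self):
        plan = synthetic.default_scenario().cluster_plan
        zmat, truth = synthetic.simulate_zmatrix(
            plan, ["bmi", "whr", "trig", "fg", "hdl"], seed=3)
        corr = snp_correlation(zmat)
        cutoff = min_degree_threshold(corr)
        sol = spinglass_cluster(corr, cutoff, ClusterConfig(seed=3, n_restarts=5))
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(truth.to_numpy(), sol.labels(list(zmat.index)))
        assert ari >= 0.9

    def test_empty_graph_rejected(self):
        corr = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            spinglass_cluster(corr, cutoff=0.5)


class TestSummarizeClusters:
    def test_mean_signature(self):
        zmat = pd.DataFrame({"A": [5.0, 5.0, 5.0, 5.0, 0.0], "B": [0.0] * 5},
                            index=[f"v{i}" for i in range(5)])
        sol = network.ClusterSolution(
            membership={f"v{i}": 0 if i < 4 else 1 for i in range(5)},
            k=2, modularity=0.0, cutoff=0.5, retained=[0])
        sig = summarize_clusters(zmat, sol)
        wide = sig.set_index(["CLUSTER", "TRAIT"])["MEAN_Z"]
        assert wide.loc[(0, "A")] == pytest.approx(5.0)
        assert wide.loc[(0, "B")] == pytest.approx(0.0)
        assert (1, "A") not in wide.index  # non-retained cluster absent

    def test_empty_retained_gives_empty_table(self):
        zmat = pd.DataFrame({"A": [1.0]}, index=["v0"])
        sol = network.ClusterSolution(membership={"v0": 0}, k=1, modularity=0.0,
                                      cutoff=0.5, retained=[])
        sig = summarize_clusters(zmat, sol)
        assert sig.empty and list(sig.columns) == ["CLUSTER", "TRAIT", "MEAN_Z", "N_VARIANTS"]
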