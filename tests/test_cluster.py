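import numpy as np
import pytest

from netclust import (
    AnalysisConfig,
    cluster_pvalues,
    edge_index_map,
    extract_clusters,
    make_permutations,
    max_cluster_extent,
    null_distribution,
    run_cluster_analysis,
    subsample_stability,
    supra_threshold_edges,
    threshold_sweep,
    vectorize,
)
from netclust.cluster import ClusterSet, NullDistribution, default_tau_grid
from netclust.correlation import CorrelationFields
from netclust import SyntheticSpec, generate_cohort, generate_null_cohort
from netclust.io import Cohort, BehaviorTable


def edges_for(emap, pairs):
    """Flat edge indices for a list of (i, j) node pairs."""
    lookup = {tuple(p): k for k, p in enumerate(map(tuple, emap.pairs))}
    return np.array([lookup[tuple(sorted(p))] for p in pairs])


class TestSupraThreshold:
    def test_negative_side_strictly_below(self):
        r = np.array([-0.5, -0.3, 0.4])
        assert supra_threshold_edges(r, -0.39, "negative").tolist() == [0]

    def test_extreme_threshold_empty(self):
        r = np.array([-0.5, -0.3, 0.4])
        assert supra_threshold_edges(r, -1.0, "negative").size == 0

    def test_boundary_value_excluded(self):
        r = np.array([-0.35, -0.36])
        assert supra_threshold_edges(r, -0.35, "negative").tolist() == [1]

    def test_positive_side(self):
        r = np.array([-0.5, 0.3, 0.4])
        assert supra_threshold_edges(r, 0.35, "positive").tolist() == [2]

    def test_sign_mismatch_rejected(self):
        with pytest.raises(ValueError):
            supra_threshold_edges(np.array([0.1]), 0.3, "negative")


class TestExtractClusters:
    def test_shared_node_joins_edges(self):
        emap = edge_index_map(4)
        cs = extract_clusters(edges_for(emap, [(0, 1), (1, 2)]), emap)
        assert cs.count == 1
        assert cs.sizes.tolist() == [2]

    def test_disjoint_edges_separate_clusters(self):
        emap = edge_index_map(4)
        cs = extract_clusters(edges_for(emap, [(0, 1), (2, 3)]), emap)
        assert cs.count == 2
        assert cs.sizes.tolist() == [1, 1]

    def test_empty_input(self):
        cs = extract_clusters([], edge_index_map(4))
        assert cs.count == 0
        assert max_cluster_extent(cs) == 0

    def test_matches_networkx_component_oracle(self, rng):
        nx = pytest.importorskip("networkx")
        for trial in range(50):
            n = int(rng.integers(5, 31))
            emap = edge_index_map(n)
            k = int(rng.integers(1, min(50, emap.m) + 1))
            edges = rng.choice(emap.m, size=k, replace=False)
            cs = extract_clusters(edges, emap)
            g = nx.Graph()
            g.add_edges_from(map(tuple, emap.pairs[edges]))
            want = sorted(len(c.edges) for c in
                          [g.subgraph(c) for c in nx.connected_components(g)])
            assert sorted(cs.sizes.tolist()) == want

    def test_deterministic_order(self):
        emap = edge_index_map(6)
        edges = edges_for(emap, [(4, 5), (0, 1), (1, 2), (2, 3)])
        cs = extract_clusters(edges, emap)
        assert cs.sizes.tolist() == [3, 1]  # big first
        assert cs.clusters[0].edges.tolist() == sorted(
            edges_for(emap, [(0, 1), (1, 2), (2, 3)]).tolist())


class TestMaxClusterExtent:
    def test_reports_largest(self):
        emap = edge_index_map(10)
        # components of sizes 3, 1, 4
        pairs = [(0, 1), (1, 2), (2, 3), (4, 5), (6, 7), (7, 8), (8, 9), (6, 9)]
        cs = extract_clusters(edges_for(emap, pairs), emap)
        assert max_cluster_extent(cs) == 4


class TestNullDistribution:
    def test_single_permutation(self):
        emap = edge_index_map(4)
        r = np.array([[-0.5], [-0.45], [0.1], [0.2], [0.0], [0.0]])
        f = CorrelationFields(r=r, method="spearman")
        null = null_distribution(f, -0.4, "negative", emap)
        # edges 0 (0,1) and 1 (0,2) share node 0 -> one cluster of 2
        assert null.M.tolist() == [2]

    def test_toy_enumeration_matches_hand_computation(self):
        emap = edge_index_map(4)
        # rows: 6 edges in row-major pair order; columns: 5 permutations;
        # -0.6 marks a supra-threshold edge at tau=-0.4, -0.1 a sub-threshold
        r = np.array([
            [-0.6, -0.1, -0.6, -0.1, -0.6],  # e0 (0,1)
            [-0.1, -0.6, -0.1, -0.1, -0.1],  # e1 (0,2)
            [-0.6, -0.6, -0.1, -0.6, -0.1],  # e2 (0,3)
            [-0.1, -0.1, -0.6, -0.6, -0.1],  # e3 (1,2)
            [-0.6, -0.1, -0.1, -0.1, -0.6],  # e4 (1,3)
            [-0.1, -0.6, -0.1, -0.6, -0.1],  # e5 (2,3)
        ])
        # hand-derived per column:
        # col0 {e0,e2,e4}: (0,1),(0,3),(1,3) triangle -> M=3
        # col1 {e1,e2,e5}: (0,2),(0,3),(2,3) connected -> M=3
        # col2 {e0,e3}: (0,1),(1,2) share node 1 -> M=2
        # col3 {e2,e3,e5}: (0,3)-(2,3)-(1,2) chained -> M=3
        # col4 {e0,e4}: (0,1),(1,3) share node 1 -> M=2
        f = CorrelationFields(r=r, method="spearman")
        null = null_distribution(f, -0.4, "negative", emap)
        assert null.M.tolist() == [3, 3, 2, 3, 2]

    def test_null_data_right_skewed(self):
        cohort, behavior = generate_null_cohort(
            SyntheticSpec(n_subjects=40, n_nodes=30, seed=5))
        W = vectorize(cohort)
        from netclust import correlation_fields

        perms = make_permutations(40, 500, seed=6)
        f = correlation_fields(W, behavior.measure, perms)
        null = null_distribution(f, -0.35, "negative", edge_index_map(30))
        M = null.M
        assert np.median(M) <= np.mean(M)  # right skew
        assert M.min() >= 0


class TestClusterPValues:
    def _cs(self, emap, sizes_pairs):
        return extract_clusters(edges_for(emap, sizes_pairs), emap)

    def test_hand_count(self):
        emap = edge_index_map(12)
        # one observed cluster of size 4 (a path of 4 edges)
        cs = self._cs(emap, [(0, 1), (1, 2), (2, 3), (3, 4)])
        null = NullDistribution(M=np.array([3, 1, 4, 2, 4]), threshold=-0.3,
                                side="negative")
        res = cluster_pvalues(cs, null)
        assert res.p[0] == pytest.approx(2 / 5)

    def test_floor_and_ceiling(self):
        emap = edge_index_map(12)
        cs = self._cs(emap, [(0, 1), (1, 2)])
        res = cluster_pvalues(cs, NullDistribution(
            M=np.array([0, 0, 0, 0, 2]), threshold=-0.3, side="negative"))
        assert res.p[0] == pytest.approx(1 / 5)  # only the observed entry
        res = cluster_pvalues(cs, NullDistribution(
            M=np.array([5, 6, 7, 2, 2]), threshold=-0.3, side="negative"))
        assert res.p[0] == 1.0

    def test_p_non_increasing_in_size(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(tau_init=-0.3, n_permutations=200, seed=1)
        res = run_cluster_analysis(cohort, behavior, cfg)
        sizes = res.observed.sizes
        for a in range(len(sizes)):
            for b in range(len(sizes)):
                if sizes[a] >= sizes[b]:
                    assert res.p[a] <= res.p[b]


class TestRunClusterAnalysis:
    def test_deterministic_for_fixed_seed(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(tau_init=-0.35, n_permutations=300, seed=11)
        a = run_cluster_analysis(cohort, behavior, cfg)
        b = run_cluster_analysis(cohort, behavior, cfg)
        np.testing.assert_array_equal(a.null.M, b.null.M)
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.r_observed, b.r_observed)

    def test_planted_effect_recovered(self, planted_cohort):
        cohort, behavior, planted = planted_cohort
        cfg = AnalysisConfig(tau_init=-0.35, n_permutations=1000, seed=11)
        res = run_cluster_analysis(cohort, behavior, cfg)
        assert res.min_p <= 0.05
        emap = edge_index_map(cohort.n_nodes)
        sig = set(map(tuple, emap.pairs[res.significant_edges()]))
        overlap = sig & set(map(tuple, planted))
        assert len(overlap) >= 10  # most of the planted sub-network

    def test_node_relabeling_invariance(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(tau_init=-0.35, n_permutations=200, seed=4)
        base = run_cluster_analysis(cohort, behavior, cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n_nodes)
        relabeled = Cohort(
            subjects=list(cohort.subjects),
            matrices=cohort.matrices[:, perm][:, :, perm],
            node_labels=[cohort.node_labels[i] for i in perm],
        )
        res = run_cluster_analysis(relabeled, behavior, cfg)
        assert sorted(res.observed.sizes.tolist()) == sorted(
            base.observed.sizes.tolist())
        np.testing.assert_array_equal(np.sort(res.p), np.sort(base.p))
        np.testing.assert_array_equal(res.null.M, base.null.M)

    def test_requires_aligned_inputs(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        shuffled = BehaviorTable(
            subjects=list(reversed(behavior.subjects)),
            measure=behavior.measure[::-1].copy(),
            covariates=None,
        )
        with pytest.raises(ValueError, match="align"):
            run_cluster_analysis(cohort, shuffled,
                                 AnalysisConfig(n_permutations=10))

    def test_tau_zero_needs_explicit_side(self):
        cfg = AnalysisConfig(tau_init=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            cfg.resolved_side()
        assert AnalysisConfig(tau_init=0.0, side="positive").resolved_side() \
            == "positive"


class TestThresholdSweep:
    def test_default_grid_has_100_thresholds_excluding_zero(self):
        grid = default_tau_grid()
        assert len(grid) == 100
        assert 0.0 not in grid
        assert grid.min() == pytest.approx(-0.5)
        assert grid.max() == pytest.approx(0.5)

    def test_sweep_monotonicity_and_stable_ranges(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(n_permutations=200, seed=2, alpha=0.05)
        grid = np.array([-0.45, -0.4, -0.35, -0.3, -0.25])
        df = threshold_sweep(cohort, behavior, cfg, grid)
        assert len(df) == len(grid)
        # supra-threshold set (hence total edge count) shrinks as |tau| grows
        totals = df["max_size"].to_numpy()
        assert (np.diff(totals) >= 0).all()  # tau increasing toward 0
        assert isinstance(df.attrs["stable_ranges"], list)

    def test_extreme_tau_gives_no_clusters(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(n_permutations=50, seed=2)
        df = threshold_sweep(cohort, behavior, cfg, np.array([-0.99]))
        assert df["n_clusters"].iloc[0] == 0

    def test_zero_in_grid_rejected(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(n_permutations=50, seed=2)
        with pytest.raises(ValueError):
            threshold_sweep(cohort, behavior, cfg, np.array([0.0]))


class TestSubsampleStability:
    def test_zero_drop_identical_to_full(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(tau_init=-0.35, n_permutations=200, seed=3)
        df = subsample_stability(cohort, behavior, cfg, drop_fraction=0.0, B=3)
        assert len(df) == 3
        assert (df["min_p"] == df.attrs["full_min_p"]).all()

    def test_default_design_reports_twenty_runs(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(tau_init=-0.35, n_permutations=100, seed=3)
        df = subsample_stability(cohort, behavior, cfg, drop_fraction=0.10,
                                 B=20)
        assert len(df) == 20
        assert (df["n_subjects"] == 36).all()  # 10% of 40 removed

    def test_strong_effect_recovered_across_runs(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(tau_init=-0.35, n_permutations=300, seed=3)
        df = subsample_stability(cohort, behavior, cfg, drop_fraction=0.10,
                                 B=5)
        assert df.attrs["n_significant"] >= 4
        assert df["recovered_fraction"].mean() > 0.5

    def test_invalid_drop_fraction(self, planted_cohort):
        cohort, behavior, _ = planted_cohort
        cfg = AnalysisConfig(n_permutations=10)
        with pytest.raises(ValueError):
            subsample_stability(cohort, behavior, cfg, drop_fraction=0.6, B=2)
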