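import numpy as np
import pytest

from _oracles import modularity_bf
from conftest import random_digraph
from hfnet.graph_metrics import nodal_metrics
from hfnet.ntd import (
    MetricDynamicsMatrix,
    SimilarityMatrix,
    louvain_signed_partition,
    metric_dynamics,
    modularity_null,
    modularity_partition,
    modularity_q,
    similarity,
    state_statistics,
    summarize_dynamics,
)


def planted_block_matrix(rng, n_blocks=3, block=30, r_within=0.9, n_t=200):
    """Rows sharing a latent factor correlate ~r_within within blocks, ~0 across."""
    z = rng.standard_normal((n_blocks, n_t))
    rows = [
        np.sqrt(r_within) * z[b] + np.sqrt(1 - r_within) * rng.standard_normal(n_t)
        for b in range(n_blocks)
        for _ in range(block)
    ]
    return np.array(rows)


def exact_recovery(assignment, truth):
    if len(set(assignment)) != len(set(truth)):
        return False
    mapping = {}
    for a, t in zip(assignment, truth):
        if mapping.setdefault(t, a) != a:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestMetricDynamics:
    def test_columns_equal_per_window_metric_calls(self):
        rng = np.random.default_rng(0)
        graphs = [random_digraph(rng, 4) for _ in range(5)]
        m = metric_dynamics(graphs, "s_out")
        assert m.values.shape == (4, 5)
        for w, g in enumerate(graphs):
            assert np.allclose(m.values[:, w], nodal_metrics(g).s_out)

    def test_constant_sequence_gives_identical_columns(self):
        rng = np.random.default_rng(1)
        g = random_digraph(rng, 5)
        m = metric_dynamics([g, g, g], "cc")
        assert np.ptp(m.values, axis=1).max() == 0.0

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            metric_dynamics([np.zeros((3, 3))], "betweenness")

    def test_mismatched_node_sets_rejected(self):
        with pytest.raises(ValueError, match="share"):
            metric_dynamics([np.zeros((3, 3)), np.zeros((4, 4))], "s_in")


class TestSummaries:
    def test_grand_mean_identical_for_both_orders(self):
        rng = np.random.default_rng(2)
        m = MetricDynamicsMatrix(values=rng.random((12, 9)), metric="s_out")
        s = summarize_dynamics(m)
        v = m.values
        assert s["grand_mean"] == pytest.approx(v.mean(axis=0).mean())
        assert s["grand_mean"] == pytest.approx(v.mean(axis=1).mean())

    def test_constant_matrix_has_zero_spread(self):
        m = MetricDynamicsMatrix(values=np.full((6, 7), 3.2), metric="cc")
        s = summarize_dynamics(m)
        assert s["sd_across_nodes"] == pytest.approx(0.0, abs=1e-12)
        assert s["sd_across_time"] == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_gives_unit_population_sd(self):
        v = np.indices((8, 8)).sum(axis=0) % 2 * 2.0 - 1.0
        s = summarize_dynamics(MetricDynamicsMatrix(values=v, metric="cpl"))
        assert s["sd_across_nodes"] == pytest.approx(1.0)
        assert s["sd_across_time"] == pytest.approx(1.0)


class TestSimilarity:
    def test_axis_shapes(self):
        rng = np.random.default_rng(3)
        m = MetricDynamicsMatrix(values=rng.random((20, 11)), metric="s_in")
        assert similarity(m, "temporal").values.shape == (11, 11)
        assert similarity(m, "nodal").values.shape == (20, 20)

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(4)
        s = similarity(MetricDynamicsMatrix(values=rng.random((10, 30)), metric="cc"), "nodal")
        assert np.allclose(s.values, s.values.T, atol=1e-12)
        assert np.allclose(np.diag(s.values), 1.0)

    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(5)
        v = rng.random((15, 6))
        v[:, 3] = v[:, 0]
        s = similarity(MetricDynamicsMatrix(values=v, metric="cc"), "temporal")
        assert s.values[0, 3] == pytest.approx(1.0)

    def test_zero_variance_row_excluded_with_warning(self):
        rng = np.random.default_rng(6)
        v = rng.random((8, 20))
        v[2] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            s = similarity(MetricDynamicsMatrix(values=v, metric="cc"), "nodal")
        assert s.excluded[2]
        assert np.all(np.isnan(s.values[2]))

    def test_invalid_axis_rejected(self):
        m = MetricDynamicsMatrix(values=np.zeros((3, 3)), metric="cc")
        with pytest.raises(ValueError):
            similarity(m, "spatial-temporal")


class TestModularityQ:
    def test_single_module_partition_scores_zero(self):
        rng = np.random.default_rng(7)
        w = np.abs(rng.random((12, 12)))
        w = (w + w.T) / 2
        assert modularity_q(w, np.zeros(12, int)) == pytest.approx(0.0, abs=1e-12)

    def test_two_disconnected_cliques_score_half(self):
        w = np.zeros((16, 16))
        w[:8, :8] = 1.0
        w[8:, 8:] = 1.0
        np.fill_diagonal(w, 0.0)
        q = modularity_q(w, np.repeat([0, 1], 8))
        assert q == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            w = rng.random((10, 10))
            w = (w + w.T) / 2
            assignment = rng.integers(0, 3, 10)
            assert modularity_q(w, assignment) == pytest.approx(
                modularity_bf(w, assignment), abs=1e-12
            )


class TestPartitions:
    def test_planted_blocks_recovered_unsigned(self):
        rng = np.random.default_rng(9)
        m = MetricDynamicsMatrix(values=planted_block_matrix(rng), metric="s_out")
        s = similarity(m, "nodal")
        p = modularity_partition(s, seed=0)
        assert exact_recovery(p.assignment, np.repeat([0, 1, 2], 30))
        assert p.q > 0.2

    def test_anticorrelated_groups_recovered_signed(self):
        w = np.block(
            [
                [np.full((15, 15), 0.8), np.full((15, 15), -0.8)],
                [np.full((15, 15), -0.8), np.full((15, 15), 0.8)],
            ]
        )
        np.fill_diagonal(w, 1.0)
        p = louvain_signed_partition(SimilarityMatrix(values=w, axis="nodal"), seed=0)
        assert p.n_modules == 2
        assert exact_recovery(p.assignment, np.repeat([0, 1], 15))

    def test_signed_and_unsigned_agree_on_positive_blocks(self):
        rng = np.random.default_rng(10)
        m = MetricDynamicsMatrix(values=planted_block_matrix(rng), metric="cc")
        s = similarity(m, "nodal")
        p_u = modularity_partition(s, seed=1)
        p_s = louvain_signed_partition(s, seed=1)
        assert exact_recovery(p_s.assignment, p_u.assignment)

    def test_partition_invariant_under_relabeling(self):
        rng = np.random.default_rng(11)
        v = planted_block_matrix(rng, n_blocks=2, block=20)
        m = MetricDynamicsMatrix(values=v, metric="cc")
        p1 = modularity_partition(similarity(m, "nodal"), seed=2)
        perm = rng.permutation(40)
        m2 = MetricDynamicsMatrix(values=v[perm], metric="cc")
        p2 = modularity_partition(similarity(m2, "nodal"), seed=2)
        assert exact_recovery(p2.assignment, p1.assignment[perm])

    def test_q_of_returned_partition_matches_oracle(self):
        rng = np.random.default_rng(12)
        m = MetricDynamicsMatrix(values=planted_block_matrix(rng), metric="cc")
        s = similarity(m, "temporal" if False else "nodal")
        p = modularity_partition(s, seed=3)
        w = np.clip(np.nan_to_num(s.values), 0.0, None)
        assert p.q == pytest.approx(modularity_bf(w, p.assignment), abs=1e-12)

    def test_state_count_recovery_across_seeds(self):
        # K planted temporal states, K in {2, 3, 4}: recovered in >= 90 % of runs
        hits = total = 0
        for k in (2, 3, 4):
            for seed in range(17):
                rng = np.random.default_rng(1000 * k + seed)
                patterns = rng.normal(0, 1, (k, 30))
                cols = [
                    patterns[w // (36 // k) if w // (36 // k) < k else k - 1]
                    + 0.3 * rng.standard_normal(30)
                    for w in range(36)
                ]
                m = MetricDynamicsMatrix(values=np.array(cols).T, metric="s_out")
                p = modularity_partition(similarity(m, "temporal"), seed=seed)
                hits += p.n_modules == k
                total += 1
        assert hits / total >= 0.9


class TestStateStatistics:
    def test_contiguous_blocks(self):
        p_assign = np.repeat([0, 1, 2], 27)
        from hfnet.ntd import PartitionResult

        p = PartitionResult(
            assignment=p_assign,
            q=0.5,
            n_modules=3,
            element_counts=np.array([27, 27, 27]),
            axis="temporal",
        )
        st = state_statistics(p)
        assert st.n_modules == 3
        assert st.min_size == st.max_size == 27
        assert st.n_runs == 3 and st.min_run == st.max_run == 27

    def test_community_size_extremes(self):
        from hfnet.ntd import PartitionResult

        p = PartitionResult(
            assignment=np.repeat([0, 1, 2], [150, 200, 230]),
            q=0.1,
            n_modules=3,
            element_counts=np.array([150, 200, 230]),
            axis="nodal",
        )
        st = state_statistics(p)
        assert st.min_size == 150 and st.max_size == 230
        assert st.n_runs is None

    def test_noncontiguous_state_has_more_runs_than_modules(self):
        from hfnet.ntd import PartitionResult

        assignment = np.array([0, 0, 1, 1, 0, 0])
        p = PartitionResult(
            assignment=assignment,
            q=0.0,
            n_modules=2,
            element_counts=np.array([4, 2]),
            axis="temporal",
        )
        st = state_statistics(p)
        assert st.n_runs == 3 and st.min_run == 2


class TestModularityNull:
    def test_planted_structure_beats_null(self):
        rng = np.random.default_rng(13)
        m = MetricDynamicsMatrix(values=planted_block_matrix(rng, block=15), metric="cc")
        s = similarity(m, "nodal")
        out = modularity_null(s, n=30, seed=0, signed=False)
        assert out["q_observed"] > np.quantile(out["null"], 0.99)
        assert out["p_value"] < 0.05

    def test_unstructured_matrix_within_null(self):
        rng = np.random.default_rng(14)
        m = MetricDynamicsMatrix(values=rng.standard_normal((30, 60)), metric="cc")
        s = similarity(m, "nodal")
        out = modularity_null(s, n=30, seed=1, signed=False)
        assert out["p_value"] > 0.05

    def test_single_draw_null(self):
        rng = np.random.default_rng(15)
        m = MetricDynamicsMatrix(values=rng.random((10, 20)), metric="cc")
        out = modularity_null(similarity(m, "nodal"), n=1, seed=2)
        assert out["null"].shape == (1,)
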