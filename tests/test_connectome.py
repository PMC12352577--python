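"""Connectome construction, thresholding, partitioning, consolidation."""

import numpy as np
import pytest

from conntopo import (
    ConnectomeError,
    FCMatrix,
    Partition,
    consolidate_supergraph,
    dissimilarity_matrix,
    fc_from_timeseries,
    graph_betti,
    group_average_fc,
    induced_subnetwork,
    threshold_graph,
    weight_levels,
)
from conntopo.synthetic import make_partition

from .conftest import random_fc


class TestFCFromTimeseries:
    def test_perfectly_correlated_and_anticorrelated_rows_give_weight_one(self):
        t = np.linspace(0, 1, 50)
        X = np.vstack([t, 2 * t + 1, -3 * t, np.sin(7 * t)])
        fc = fc_from_timeseries(X)
        assert fc.W[0, 1] == pytest.approx(1.0)   # correlated
        assert fc.W[0, 2] == pytest.approx(1.0)   # anti-correlated, |r|
        assert np.all(np.diag(fc.W) == 1.0)

    def test_planted_correlation_recovered(self, rng):
        # trivariate normal with all pairwise correlations 0.5
        cov = np.full((3, 3), 0.5)
        np.fill_diagonal(cov, 1.0)
        X = rng.multivariate_normal(np.zeros(3), cov, size=10_000).T
        fc = fc_from_timeseries(X)
        iu = np.triu_indices(3, 1)
        assert np.allclose(fc.W[iu], 0.5, atol=0.02)

    def test_constant_row_rejected_by_name(self):
        X = np.vstack([np.arange(5.0), np.full(5, 3.0)])
        with pytest.raises(ConnectomeError, match="R1"):
            fc_from_timeseries(X)

    def test_output_satisfies_fc_invariants(self, rng):
        X = rng.standard_normal((12, 40))
        fc = fc_from_timeseries(X)
        assert np.allclose(fc.W, fc.W.T)
        assert fc.W.min() >= 0 and fc.W.max() <= 1
        assert np.all(np.diag(fc.W) == 1.0)


class TestGroupAverage:
    def test_mean_of_identical_matrices_is_identity_operation(self, rng):
        fc = random_fc(rng, 6)
        avg = group_average_fc([fc, fc, fc])
        assert np.allclose(avg.W, fc.W)

    def test_entrywise_arithmetic(self, rng):
        fc = random_fc(rng, 5)
        mirrored = FCMatrix(np.clip(2 * 0.6 - fc.W, 0, 1), fc.region_ids)
        avg = group_average_fc([fc, mirrored])
        iu = np.triu_indices(5, 1)
        expect = (fc.W[iu] + mirrored.W[iu]) / 2
        assert np.allclose(avg.W[iu], expect)

    def test_simulated_cohort_mean_close_to_truth(self, rng):
        truth = random_fc(rng, 5).W
        n_subj, eps = 100, 0.1
        subs = []
        for _ in range(n_subj):
            noise = rng.uniform(-eps, eps, truth.shape)
            noise = (noise + noise.T) / 2
            subs.append(FCMatrix(np.clip(truth + noise, 0, 1)))
        avg = group_average_fc(subs)
        se = eps / np.sqrt(3 * n_subj)  # uniform sd = eps/sqrt(3)
        iu = np.triu_indices(5, 1)
        # clipping can bias entries near 0/1, so compare on interior entries
        interior = (truth[iu] > eps) & (truth[iu] < 1 - eps)
        assert np.all(np.abs(avg.W[iu] - truth[iu])[interior] < 3 * se + 1e-9)

    def test_errors(self, rng):
        with pytest.raises(ConnectomeError):
            group_average_fc([])
        a = random_fc(rng, 4)
        b = FCMatrix(random_fc(rng, 4).W, ("a", "b", "c", "d"))
        with pytest.raises(ConnectomeError, match="region_ids"):
            group_average_fc([a, b])


class TestDissimilarity:
    def test_values_and_involution(self, rng):
        fc = random_fc(rng, 7)
        D = dissimilarity_matrix(fc)
        expected = 1.0 - fc.W
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(D.D, expected)
        back = FCMatrix(1.0 - D.D, fc.region_ids)
        assert np.allclose(back.W, fc.W)
        assert np.all(np.diag(D.D) == 0.0)


class TestWeightLevels:
    def test_constant_offdiagonal_collapses_to_one_level(self):
        W = np.full((4, 4), 0.5)
        np.fill_diagonal(W, 1.0)
        assert weight_levels(FCMatrix(W)) == [0.5]

    def test_dedupe_and_decreasing_order(self):
        W = np.array([[1.0, 0.2, 0.9], [0.2, 1.0, 0.2], [0.9, 0.2, 1.0]])
        assert weight_levels(FCMatrix(W)) == [0.9, 0.2]

    def test_toy_network_has_five_positive_levels(self, toy):
        fc, _ = toy
        levels = weight_levels(fc)
        assert levels == [0.9, 0.8, 0.7, 0.6, 0.5, 0.0]
        assert len([l for l in levels if l > 0]) == 5


class TestThresholdGraph:
    def test_r_zero_gives_complete_graph(self, rng):
        fc = random_fc(rng, 9)
        g = threshold_graph(fc, 0.0).graph
        assert g.number_of_edges() == 9 * 8 // 2

    def test_above_max_weight_gives_isolated_vertices(self, rng):
        fc = random_fc(rng, 6)
        iu = np.triu_indices(6, 1)
        r = float(fc.W[iu].max())
        g = threshold_graph(fc, min(1.0, r + 1e-9)).graph
        assert g.number_of_edges() == 0 and g.number_of_nodes() == 6

    def test_edge_count_matches_direct_enumeration(self, rng):
        fc = random_fc(rng, 11)
        iu = np.triu_indices(11, 1)
        r = float(np.median(fc.W[iu]))
        g = threshold_graph(fc, r).graph
        assert g.number_of_edges() == int((fc.W[iu] >= r).sum())

    def test_tie_at_threshold_includes_edge(self):
        W = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert threshold_graph(FCMatrix(W), 0.4).graph.has_edge(0, 1)

    def test_nesting_across_levels(self, rng):
        fc = random_fc(rng, 8)
        levels = weight_levels(fc)
        prev = None
        for r in levels:  # decreasing weight = growing graph
            edges = set(threshold_graph(fc, r).graph.edges())
            if prev is not None:
                assert prev <= edges
            prev = edges

    def test_out_of_range_threshold_rejected(self, rng):
        with pytest.raises(ConnectomeError):
            threshold_graph(random_fc(rng, 4), 1.5)


class TestGraphBetti:
    def test_empty_graph(self, rng):
        fc = random_fc(rng, 7)
        iu = np.triu_indices(7, 1)
        g = threshold_graph(fc, min(1.0, float(fc.W[iu].max()) + 1e-9))
        assert graph_betti(g) == (7, 0)

    def test_complete_graph_on_five_vertices(self):
        W = np.full((5, 5), 0.8)
        np.fill_diagonal(W, 1.0)
        assert graph_betti(threshold_graph(FCMatrix(W), 0.5)) == (1, 6)

    def test_toy_component_sequence(self, toy):
        fc, _ = toy
        stages = [1.0, 0.9, 0.8, 0.7, 0.6, 0.5]
        b0s = [graph_betti(threshold_graph(fc, r))[0] for r in stages]
        assert b0s == [10, 6, 3, 3, 3, 1]


class TestInducedSubnetwork:
    def test_full_class_is_identity(self, rng):
        fc = random_fc(rng, 6)
        part = make_partition(6, [6], ["ALL"], fc.region_ids)
        sub = induced_subnetwork(fc, part, "ALL")
        assert np.allclose(sub.W, fc.W) and sub.region_ids == fc.region_ids

    def test_singleton_class(self, rng):
        fc = random_fc(rng, 5)
        part = make_partition(5, [1, 4], ["A", "B"], fc.region_ids)
        sub = induced_subnetwork(fc, part, "A")
        assert sub.W.shape == (1, 1) and sub.W[0, 0] == 1.0

    def test_entries_match_direct_indexing(self, rng):
        fc = random_fc(rng, 12)
        part = make_partition(12, [4, 5, 3], ["A", "B", "C"], fc.region_ids)
        idx = part.members("B")
        sub = induced_subnetwork(fc, part, "B")
        for a, i in enumerate(idx):
            for b, j in enumerate(idx):
                assert sub.W[a, b] == fc.W[i, j]

    def test_nested_induction_equals_direct(self, rng):
        fc = random_fc(rng, 10)
        part = make_partition(10, [6, 4], ["A", "B"], fc.region_ids)
        sub = induced_subnetwork(fc, part, "A")
        part2 = make_partition(6, [3, 3], ["A1", "A2"], sub.region_ids)
        nested = induced_subnetwork(sub, part2, "A1")
        direct = fc.W[np.ix_(range(3), range(3))]
        assert np.allclose(nested.W, direct)

    def test_unknown_class_rejected(self, rng):
        fc = random_fc(rng, 4)
        part = make_partition(4, [2, 2], ["A", "B"], fc.region_ids)
        with pytest.raises(ConnectomeError, match="unknown"):
            induced_subnetwork(fc, part, "Z")


class TestConsolidate:
    def test_toy_contracts_to_three_supernodes(self, toy):
        fc, part = toy
        sg = consolidate_supergraph(fc, part)
        assert sg.normalized.n == 3
        assert sg.class_names == ("FN1", "FN2", "FN3")
        # only bridges cross classes: FN1-FN2 and FN2-FN3 both sum to 0.5
        assert sg.raw[0, 1] == pytest.approx(0.5)
        assert sg.raw[1, 2] == pytest.approx(0.5)
        assert sg.raw[0, 2] == 0.0
        assert sg.normalized.W[0, 1] == pytest.approx(1.0)

    def test_constant_cross_weights_normalize_to_one(self):
        W = np.full((4, 4), 0.3)
        np.fill_diagonal(W, 1.0)
        part = make_partition(4, [2, 2], ["A", "B"])
        sg = consolidate_supergraph(FCMatrix(W), part)
        assert sg.normalized.W[0, 1] == pytest.approx(1.0)

    def test_raw_weights_match_nested_loop_sum(self, rng):
        fc = random_fc(rng, 10)
        part = make_partition(10, [4, 3, 3], ["A", "B", "C"], fc.region_ids)
        sg = consolidate_supergraph(fc, part)
        for i, ci in enumerate(part.class_names):
            for j, cj in enumerate(part.class_names):
                if i == j:
                    continue
                want = sum(fc.W[u, v] for u in part.members(ci)
                           for v in part.members(cj))
                assert sg.raw[i, j] == pytest.approx(want)

    def test_normalized_entries_scale_invariant(self, rng):
        base = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        vals = rng.random(len(iu[0])) * 0.3
        base[iu] = vals
        base = base + base.T
        np.fill_diagonal(base, 1.0)
        part = make_partition(6, [3, 3], ["A", "B"])
        a = consolidate_supergraph(FCMatrix(base), part).normalized.W
        scaled = base.copy() * 2.0
        np.fill_diagonal(scaled, 1.0)
        b = consolidate_supergraph(FCMatrix(np.clip(scaled, 0, 1)), part).normalized.W
        assert np.allclose(a, b)

    def test_zero_cross_weights_warn_and_zero(self):
        W = np.eye(4)
        part = make_partition(4, [2, 2], ["A", "B"])
        with pytest.warns(UserWarning, match="zero"):
            sg = consolidate_supergraph(FCMatrix(W), part)
        assert sg.normalized.W[0, 1] == 0.0


class TestPartitionInvariants:
    def test_every_class_nonempty_enforced(self):
        with pytest.raises(ConnectomeError, match="empty"):
            Partition(np.array([0, 0, 0]), ("A", "B"))

    def test_fc_symmetry_enforced(self):
        W = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ConnectomeError, match="symmetric"):
            FCMatrix(W)
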