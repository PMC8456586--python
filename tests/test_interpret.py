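"""Relevance propagation, weight diagnostics, target masks, clustering, reports."""

import numpy as np
import pandas as pd
import pytest

from ontonet import (NetworkParameters, cluster_activation_profiles,
                     connection_norms, forward, init_network,
                     linkage_to_newick, lrp_relevance, ranks_decreasing,
                     sort_connection_weights, target_mask_rank,
                     target_mask_ranks_from_means, top_terms_report)
from ontonet.interpret import lrp_relevance_bruteforce
from ontonet.ontology import LayerSchema

from conftest import make_schema


def _random_biasfree(sizes, seed, n_out=1):
    rng = np.random.default_rng(seed)
    dims = [*sizes, n_out]
    weights = [rng.normal(size=(a, b)) for a, b in zip(dims[:-1], dims[1:])]
    biases = [np.zeros(b) for b in dims[1:]]
    return NetworkParameters(weights, biases)


class TestLRP:
    def test_single_layer_hand_example(self):
        # x=(1,3), w=(2,2), bias 0: z=8, shares 2/8 and 6/8 -> R=(2,6)
        params = NetworkParameters(weights=[np.array([[2.0], [2.0]])],
                                   biases=[np.array([0.0])])
        rel = lrp_relevance(params, np.array([[1.0, 3.0]]), epsilon=1e-12)
        np.testing.assert_allclose(rel[0][0], [2.0, 6.0], rtol=1e-9)
        assert np.isclose(rel[0].sum(), 8.0)

    def test_conservation_on_biasfree_networks(self):
        # relevance sums are constant across layers for bias-free nets
        for seed in range(50):
            params = _random_biasfree((6, 5, 4), seed)
            x = np.random.default_rng(100 + seed).normal(size=(1, 6))
            rel = lrp_relevance(params, x, epsilon=1e-7)
            z = rel[-1].sum()
            for r in rel:
                assert abs(r.sum() - z) <= 1e-4 * max(1.0, abs(z))

    def test_matches_bruteforce_oracle(self):
        for seed in range(5):
            sizes = (8, 20, 12, 5)
            params = _random_biasfree(sizes, seed, n_out=3)
            x = np.random.default_rng(200 + seed).normal(size=8)
            fast = lrp_relevance(params, x[None, :], epsilon=1e-7)
            slow = lrp_relevance_bruteforce(params, x, epsilon=1e-7)
            for f, s in zip(fast, slow):
                np.testing.assert_allclose(f[0], s, atol=1e-10)

    def test_multiclass_seeds_only_predicted_logit(self):
        params = _random_biasfree((4, 6), 1, n_out=3)
        x = np.random.default_rng(0).normal(size=(1, 4))
        acts, probs = forward(params, x)
        z = acts[-1] @ params.weights[-1]
        rel = lrp_relevance(params, x)
        k = probs[0].argmax()
        assert rel[-1][0, k] == z[0, k]
        assert (rel[-1][0, np.arange(3) != k] == 0).all()

    def test_explain_class_zero_negates_binary_logit(self):
        params = _random_biasfree((4, 3), 2)
        x = np.random.default_rng(1).normal(size=(1, 4))
        r1 = lrp_relevance(params, x, explain_class=1)
        r0 = lrp_relevance(params, x, explain_class=0)
        np.testing.assert_allclose(r0[0], -r1[0], rtol=1e-9)


class TestConnectionNorms:
    def _single_layer(self, w):
        return NetworkParameters(
            weights=[np.asarray(w, dtype=float), np.zeros((w.shape[1], 1))],
            biases=[np.zeros(w.shape[1]), np.zeros(1)])

    def test_hand_example(self):
        params = self._single_layer(np.array([[1.0, 2.0], [3.0, 4.0]]))
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        go, nogo, ratio = connection_norms(params, [mask])
        assert go == 2.5 and nogo == 2.5 and ratio == 1.0

    def test_equal_magnitudes_give_unit_ratio(self):
        params = self._single_layer(np.full((3, 3), -0.7))
        mask = np.eye(3)
        assert connection_norms(params, [mask])[2] == 1.0

    def test_zero_nogo_gives_infinite_sentinel(self):
        params = self._single_layer(np.array([[1.0, 0.0], [0.0, 1.0]]))
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        go, nogo, ratio = connection_norms(params, [mask])
        assert nogo == 0.0 and np.isinf(ratio)

    def test_unit_ratio_at_initialization(self):
        schema, masks = make_schema(100, (30, 10), rng=np.random.default_rng(9))
        params = init_network(schema, seed=0)
        ratio = connection_norms(params, masks)[2]
        assert 0.8 < ratio < 1.25


class TestSortWeights:
    def test_sorted_descending_with_index_tiebreak(self):
        params = NetworkParameters(
            weights=[np.array([[1.0, 2.0], [3.0, 4.0]]), np.zeros((2, 1))],
            biases=[np.zeros(2), np.zeros(1)])
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        df = sort_connection_weights(params, [mask], layer=1)
        assert df["abs_weight"].tolist() == [4.0, 3.0, 2.0, 1.0]
        assert df["rank"].tolist() == [1, 2, 3, 4]
        ties = NetworkParameters(
            weights=[np.ones((2, 2)), np.zeros((2, 1))],
            biases=[np.zeros(2), np.zeros(1)])
        df2 = sort_connection_weights(ties, [mask], layer=1)
        assert df2[["row", "col"]].values.tolist() == [[0, 0], [0, 1], [1, 0], [1, 1]]

    def test_trained_go_connections_rank_above_median(self, bench, trained_go_model):
        params = trained_go_model["params"]
        df = sort_connection_weights(params, bench["masks"], layer=1)
        median_rank = len(df) / 2
        go_ranks = df.loc[df["is_go"], "rank"]
        assert (go_ranks < median_rank).mean() >= 0.9


class TestTargetMask:
    def test_rank_from_means_worked_example(self):
        # neuron 1's own-mask activation 0.9 beats 0.7 and 0.8 -> rank 1
        a_bar = np.array([[0.9, 0.7, 0.8],
                          [0.1, 0.5, 0.2],
                          [0.0, 0.0, 0.0]])
        ranks = target_mask_ranks_from_means(a_bar)
        assert ranks[0] == 1
        assert ranks[1] == 1   # 0.5 is the largest entry of its own row
        assert ranks[2] == -1  # zero own-mask activation -> NULL

    def test_lrp_ranks_worked_example(self):
        # mean relevances (1.9, 2.5, 0.3) -> neuron 2 is rank 1
        ranks = ranks_decreasing(np.array([1.9, 2.5, 0.3]))
        assert ranks.tolist() == [2, 1, 3]

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=37)
        assert sorted(ranks_decreasing(v)) == list(range(1, 38))

    def _tiny_setup(self):
        schema = LayerSchema(
            levels=(1,), layer_terms=(("T:A", "T:B"),),
            probe_order=("p0", "p1", "p2"), n_classes=2)
        masks = [np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])]
        params = NetworkParameters(
            weights=[np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]),
                     np.array([[1.0], [1.0]])],
            biases=[np.zeros(2), np.zeros(1)])
        return schema, masks, params

    def test_end_to_end_ranks_and_null(self):
        schema, masks, params = self._tiny_setup()
        X = np.array([[1.0, 1.0, 1.0], [2.0, 0.5, 0.5]])
        report = target_mask_rank(params, schema, masks, X)
        assert report.table["target_mask_rank"].tolist() == [1, 1]
        # kill neuron A's input weight -> zero activation under every mask
        params.weights[0][0, 0] = 0.0
        report = target_mask_rank(params, schema, masks, X)
        assert report.table["target_mask_rank"].tolist()[0] == -1

    def test_duplicate_masks_rejected(self):
        schema, masks, params = self._tiny_setup()
        masks = [np.array([[1.0, 1.0], [0.0, 0.0], [0.0, 0.0]])]
        with pytest.raises(ValueError, match="identical probe sets"):
            target_mask_rank(params, schema, masks, np.ones((2, 3)))
        target_mask_rank(params, schema, masks, np.ones((2, 3)),
                         allow_duplicate_masks=True)

    def test_benchmark_mask_report_shape(self, bench, trained_go_model):
        te = trained_go_model["test_set"]
        report = target_mask_rank(trained_go_model["params"], bench["schema"],
                                  bench["masks"], te.X)
        n1 = bench["schema"].layer_sizes[0]
        assert len(report.table) == n1
        assert sorted(report.table["lrp_rank"]) == list(range(1, n1 + 1))
        valid = report.table["target_mask_rank"]
        assert ((valid == -1) | (valid >= 1)).all()
        # NULL exactly when the own-mask activation is zero
        own = np.diag(report.mean_masked_activations)
        np.testing.assert_array_equal(valid == -1, own == 0)


class TestClustering:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(10, 4))
        b = rng.normal(5, 0.1, size=(10, 4))
        Z, labels = cluster_activation_profiles(np.vstack([a, b]), n_clusters=2)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_two_samples_single_merge(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        Z, _ = cluster_activation_profiles(X)
        assert Z.shape == (1, 4)
        assert np.isclose(Z[0, 2], 5.0)

    def test_permutation_invariance_of_tree(self):
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        perm = rng.permutation(12)
        Z1, _ = cluster_activation_profiles(X)
        Z2, _ = cluster_activation_profiles(X[perm])
        d1 = squareform(cophenet(Z1))
        d2 = squareform(cophenet(Z2))
        inv = np.argsort(perm)
        np.testing.assert_allclose(d1, d2[np.ix_(inv, inv)], atol=1e-10)

    def test_newick_output_parses(self):
        import dendropy

        X = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0]])
        Z, _ = cluster_activation_profiles(X)
        nwk = linkage_to_newick(Z, ["s0", "s1", "s2"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"s0", "s1", "s2"}


class TestTopTerms:
    def _schema(self):
        return LayerSchema(levels=(1,), layer_terms=(("T:A", "T:B", "T:C"),),
                           probe_order=("p",), n_classes=2,
                           term_names={"T:A": "a", "T:B": "b", "T:C": "c"})

    def test_single_sample_sorting(self):
        schema = self._schema()
        rel = [np.zeros((1, 1)), np.array([[0.1, 0.5, 0.2]]), np.zeros((1, 1))]
        rep = top_terms_report(rel, schema, k=2)[1]
        assert rep["term"].tolist() == ["T:B", "T:C"]

    def test_identical_samples_equal_single_sample_report(self):
        schema = self._schema()
        row = np.array([0.3, 0.9, 0.1])
        rel = [np.zeros((4, 1)), np.tile(row, (4, 1)), np.zeros((4, 1))]
        rep_all = top_terms_report(rel, schema, k=3)[1]
        rel1 = [r[:1] for r in rel]
        rep_one = top_terms_report(rel1, schema, k=3)[1]
        pd.testing.assert_frame_equal(rep_all, rep_one)

    def test_k_larger_than_layer_warns_and_truncates(self):
        schema = self._schema()
        rel = [np.zeros((1, 1)), np.array([[0.1, 0.5, 0.2]]), np.zeros((1, 1))]
        with pytest.warns(UserWarning, match="exceeds"):
            rep = top_terms_report(rel, schema, k=10)[1]
        assert len(rep) == 3

    def test_empty_subset_rejected(self):
        schema = self._schema()
        rel = [np.zeros((2, 1)), np.ones((2, 3)), np.zeros((2, 1))]
        with pytest.raises(ValueError, match="non-empty"):
            top_terms_report(rel, schema, sample_subset=[], k=1)
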