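import numpy as np
import pytest

from perturbprop import (
    DynamicalModel,
    GCNConfig,
    GCNEnhancer,
    InfluenceNetwork,
    assemble_full_graph,
    assemble_sparse_graph,
    corpus_n_classes,
    gcn_layer,
    generate_ensemble,
    labels_to_enhancement,
    node_features,
    node_labels,
    train_gcn,
)
from perturbprop.gcn import GraphBatch, predict_labels, load_params, save_params


def _net(n, edges, model_id=""):
    return InfluenceNetwork(
        n_nodes=n,
        edges={(s, t): (sign, w) for s, t, sign, w in edges},
        model_id=model_id,
    )


def _model(jac, model_id="m"):
    jac = np.asarray(jac, dtype=float)
    n = jac.shape[0]
    return DynamicalModel(
        species=[f"x{i}" for i in range(n)],
        steady_state=np.ones(n),
        jacobian=jac,
        model_id=model_id,
    )


class TestLabels:
    def test_two_species_label_from_single_offdiagonal(self):
        # both off-diagonals nonzero: each node's label is the scaled rank
        # of its single incoming entry
        m = _model([[-3.0, 1.0], [2.0, -4.0]])
        labs = node_labels(m, n_classes=4)
        assert labs.shape == (2,)
        assert np.all((labs >= 1) & (labs <= 4))

    def test_node_without_incoming_interaction_gets_class_one(self):
        m = _model([[-1.0, 0.0, 0.0], [1.0, -2.0, 0.0], [0.5, 0.2, -3.0]])
        labs = node_labels(m, n_classes=5)
        assert labs[0] == 1

    def test_matches_brute_force_median_over_support(self):
        rng = np.random.default_rng(8)
        jac = rng.normal(size=(9, 9)) * (rng.random((9, 9)) < 0.4)
        np.fill_diagonal(jac, -10.0)
        m = _model(jac)
        labs = node_labels(m, n_classes=5)
        from perturbprop import enhancement_factor

        scaled = enhancement_factor(m).scaled_impact
        for i in range(9):
            support = [
                j for j in range(9) if j != i and jac[i, j] != 0
            ]
            if not support:
                assert labs[i] == 1
                continue
            med = np.median([scaled[i, j] for j in support])
            assert labs[i] == min(5, max(1, int(np.floor(med + 0.5))))


class TestFeatures:
    def test_isolated_node_has_zero_degrees_and_clustering(self):
        f = node_features(_net(3, [(0, 1, 1, 1.0)]))
        assert f[2, 0] == 0 and f[2, 1] == 0 and f[2, 3] == 0
        assert f[2, 6] == 1.0  # isolated-target indicator

    def test_complete_graph_clustering_is_one(self):
        edges = [
            (i, j, 1, 1.0) for i in range(4) for j in range(4) if i != j
        ]
        f = node_features(_net(4, edges))
        np.testing.assert_allclose(f[:, 3], 1.0)

    def test_directed_out_star_degrees(self):
        n = 5
        f = node_features(_net(n, [(0, k, 1, 1.0) for k in range(1, n)]))
        assert f[0, 1] == n - 1  # center out-degree
        assert np.all(f[1:, 1] == 0)  # leaves have no out-edges


class TestAssembly:
    @pytest.fixture
    def two_nets(self):
        a = _net(3, [(0, 1, 1, 1.0), (1, 2, 1, 1.0)], model_id="a")
        b = _net(
            4,
            [(0, 1, 1, 1.0), (1, 2, -1, 1.0), (2, 3, 1, 1.0), (3, 0, 1, 1.0)],
            model_id="b",
        )
        return [a, b], [np.array([1, 2, 1]), np.array([2, 2, 1, 1])]

    def test_full_graph_adds_exactly_one_center(self, two_nets):
        nets, labels = two_nets
        batch = assemble_full_graph(nets, labels, n_classes=3, seed=0)
        assert batch.adjacency.shape == (8, 8)
        center = batch.center_index
        assert center == 7
        assert batch.adjacency[center].sum() == 2  # one edge per network
        assert batch.labels[center] == 0
        assert not batch.train_mask[center] and not batch.test_mask[center]

    def test_center_attaches_to_hub_with_lowest_index_on_ties(self):
        # chain 0-1-2: node 1 has degree 2, others 1 -> hub is 1
        net = _net(3, [(0, 1, 1, 1.0), (1, 2, 1, 1.0)], model_id="a")
        batch = assemble_full_graph([net], [np.array([1, 1, 1])], 3, seed=0)
        assert batch.adjacency[batch.center_index, 1] == 1.0
        # symmetric pair 0<->1: tie between nodes 0 and 1 -> node 0
        net2 = _net(2, [(0, 1, 1, 1.0), (1, 0, 1, 1.0)], model_id="b")
        batch2 = assemble_full_graph([net2], [np.array([1, 1])], 3, seed=0)
        assert batch2.adjacency[batch2.center_index, 0] == 1.0
        assert batch2.adjacency[batch2.center_index, 1] == 0.0

    def test_sparse_graph_is_block_diagonal_with_one_hot_pooling(self, two_nets):
        nets, labels = two_nets
        batch = assemble_sparse_graph(nets, labels, n_classes=3, seed=0)
        assert batch.adjacency.shape == (7, 7)
        assert np.all(batch.adjacency[:3, 3:] == 0)
        assert np.all(batch.adjacency[3:, :3] == 0)
        np.testing.assert_array_equal(batch.pooling.sum(axis=1), np.ones(7))
        np.testing.assert_array_equal(
            batch.pooling.sum(axis=0), [3, 4]
        )

    def test_masks_split_whole_models(self, two_nets):
        nets, labels = two_nets
        batch = assemble_sparse_graph(nets, labels, 3, split=0.5, seed=1)
        for mid, lo, hi in batch.provenance:
            block_train = batch.train_mask[lo:hi]
            assert block_train.all() or (~block_train).all()
        assert not (batch.train_mask & batch.test_mask).any()


class TestLayer:
    def test_edgeless_graph_reduces_to_dense_layer(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(4, 3))
        w = rng.normal(size=(3, 2))
        out = gcn_layer(h, np.zeros((4, 4)), w)
        np.testing.assert_allclose(out, np.maximum(h @ w, 0.0))

    def test_two_node_complete_graph_averages(self):
        out = gcn_layer(np.eye(2), np.array([[0.0, 1.0], [1.0, 0.0]]), np.eye(2),
                        activation="identity")
        np.testing.assert_allclose(out, 0.5 * np.ones((2, 2)))

    def test_relu_clamps_negative_products(self):
        h = np.ones((3, 2))
        w = -np.ones((2, 2))
        out = gcn_layer(h, np.zeros((3, 3)), w, activation="relu")
        np.testing.assert_array_equal(out, np.zeros((3, 2)))

    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        out = gcn_layer(
            rng.normal(size=(5, 3)),
            (rng.random((5, 5)) < 0.4).astype(float),
            rng.normal(size=(3, 4)),
            activation="softmax",
        )
        np.testing.assert_allclose(out.sum(axis=1), 1.0)


def _separable_batch(n_per_class=30, n_classes=3, seed=0):
    """Labels perfectly determined by one feature; no edges."""
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    x = np.zeros((n, 2))
    x[:, 0] = y + 0.05 * rng.normal(size=n)
    x[:, 1] = rng.normal(size=n)
    order = rng.permutation(n)
    train = np.zeros(n, dtype=bool)
    train[order[: int(0.7 * n)]] = True
    return GraphBatch(
        features=x,
        adjacency=np.zeros((n, n)),
        labels=y,
        train_mask=train,
        test_mask=~train,
        n_classes=n_classes,
        provenance=[("all", 0, n)],
    )


class TestTraining:
    def test_learns_separable_task(self):
        batch = _separable_batch()
        params, history = train_gcn(batch, GCNConfig(seed=0))
        pred = predict_labels(params, batch)
        acc = np.mean(pred[batch.train_mask] == batch.labels[batch.train_mask])
        assert acc >= 0.95

    def test_identical_seeds_identical_losses(self):
        batch = _separable_batch()
        _, h1 = train_gcn(batch, GCNConfig(seed=3, max_epochs=20))
        _, h2 = train_gcn(batch, GCNConfig(seed=3, max_epochs=20))
        assert h1 == h2

    def test_loss_decreases_on_separable_data(self):
        batch = _separable_batch()
        _, history = train_gcn(batch, GCNConfig(seed=1))
        assert history[-1] <= history[0]

    def test_absent_class_warns(self):
        batch = _separable_batch(n_per_class=10, n_classes=3)
        batch.train_mask[batch.labels == 3] = False
        with pytest.warns(UserWarning, match="absent"):
            train_gcn(batch, GCNConfig(seed=0, max_epochs=2))

    def test_params_roundtrip(self, tmp_path):
        batch = _separable_batch(n_per_class=5)
        params, _ = train_gcn(batch, GCNConfig(seed=0, max_epochs=2))
        p = tmp_path / "params.json"
        save_params(params, p)
        again = load_params(p)
        for k in params:
            np.testing.assert_array_equal(params[k], again[k])


class TestReconstruction:
    def test_uniform_labels_give_all_ones(self):
        e = labels_to_enhancement(np.full(4, 3))
        np.testing.assert_array_equal(e, np.ones((4, 4)))

    def test_ratio_antisymmetry(self):
        rng = np.random.default_rng(7)
        labs = rng.integers(1, 6, size=10)
        e = labels_to_enhancement(labs)
        np.testing.assert_allclose(e * e.T, np.ones((10, 10)))
        np.testing.assert_allclose(np.diag(e), 1.0)

    def test_exact_recovery_reproduces_normalized_factor(self):
        # constant-row scaled matrix: E_ij = r_i / r_j exactly
        r = np.array([2.0, 4.0, 1.0])
        scaled = np.tile(r[:, None], (1, 3))
        from perturbprop import normalize_scaled

        np.testing.assert_allclose(
            labels_to_enhancement(r), normalize_scaled(scaled)
        )


@pytest.fixture(scope="module")
def fitted():
    models = generate_ensemble(10, seed=2, n_min=5, n_max=15)
    return GCNEnhancer(
        models, regime="sparse", config=GCNConfig(seed=0, max_epochs=30),
        split=0.7,
    ).fit()


class TestEnhancerObject:
    def test_summary_reports_fit_diagnostics(self, fitted):
        text = fitted.summary()
        assert "test accuracy" in text and "majority baseline" in text
        assert "sparse" in text

    def test_predicted_labels_match_model_sizes(self, fitted):
        for mid, lo, hi in fitted.batch.provenance:
            assert fitted.predicted_labels(mid).shape == (hi - lo,)

    def test_enhancement_prediction_is_valid_factor(self, fitted):
        mid = fitted.batch.provenance[0][0]
        e = fitted.predict_enhancement(mid)
        assert np.all(e > 0)
        np.testing.assert_allclose(np.diag(e), 1.0)

    def test_class_count_covers_largest_model(self):
        models = generate_ensemble(5, seed=3, n_min=17, n_max=32)
        # every size n in 17..32 has ceil(log2(n)) = 5
        assert corpus_n_classes(models) == 6
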