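"""Graph-convolutional prediction of per-node scaled-impact labels.

The enhancement factor is learnable: a node's typical scaled-impact value
(the median of its row of the scaled impact matrix) becomes its class
label, and a two-layer graph convolutional network predicts that class
from purely topological node features.  Predicted labels are recombined
into an estimated enhancement factor by the same diagonal-normalization
ratio the exact construction uses: ``E_hat[i, j] = label(i) / label(j)``.

Two batching regimes are provided:

full graph
    all influence networks united into one graph plus a single extra
    center node linked to the highest-degree node of each member network,
    letting information flow between networks.
sparse graph
    a block-diagonal adjacency (one block per network) and a one-hot
    pooling matrix assigning each node to its network; the pooling matrix
    is used to append each node's graph-mean feature vector, giving the
    network-local context the center node cannot provide.

The layer stack follows the standard spectral rule
``H' = sigma(D^{-1/2} (A + I) D^{-1/2} H W)`` with ReLU hidden activation
and a softmax output, trained with Adam on a masked cross-entropy loss.
The implementation is pure numpy/scipy: forward pass, analytic backward
pass and the Adam update are written out explicitly, which keeps the
package dependency-light and bitwise reproducible under a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .enhancement import enhancement_factor
from .models import (
    DynamicalModel,
    InfluenceNetwork,
    SensitivityMatrix,
    StructuralError,
    build_influence_network,
)

# ---------------------------------------------------------------------------
# labels and features


def corpus_n_classes(models: Sequence[DynamicalModel]) -> int:
    """Label alphabet size: ceil(log2(N_max)) + 1 over the corpus, the
    largest scaled-impact value any member model can produce."""
    n_max = max(m.n_species for m in models)
    return int(n_max - 1).bit_length() + 1


def node_labels(
    model: DynamicalModel, n_classes: int, support_only: bool = True
) -> np.ndarray:
    """Per-node class: median of the node's row of the scaled impact
    matrix over columns j != i, rounded half-up, clipped to 1..n_classes.

    With ``support_only`` (default) the median runs over the columns where
    the node actually receives an interaction (``J[i, j] != 0``); on sparse
    Jacobians the unrestricted median collapses to the shared zero rank for
    nearly every node, leaving nothing to learn.  Nodes with no incoming
    interaction get label 1.
    """
    n = model.n_species
    if n == 1:
        return np.array([1])
    scaled = enhancement_factor(model).scaled_impact
    labels = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if support_only:
            keep &= model.jacobian[i] != 0
        if not keep.any():
            labels[i] = 1
            continue
        med = float(np.median(scaled[i, keep]))
        labels[i] = int(np.floor(med + 0.5))
    return np.clip(labels, 1, n_classes)


def node_features(network: InfluenceNetwork) -> np.ndarray:
    """Default topological descriptors, one row per node (D = 8).

    Columns: in-degree, out-degree, log(1 + N), local clustering
    coefficient (undirected projection), fraction of negative incident
    edges, mean inverse out-distance to all other nodes (unreachable
    contributing zero), an isolated-target indicator (in-degree == 0), and
    the integer size scale ``ceil(log2(N))`` — the last two survive the
    neighborhood averaging of the convolution, which otherwise blurs
    per-node degree information.  Standardization happens at batch
    assembly.
    """
    n = network.n_nodes
    g = network.to_networkx(directed=True)
    gu = g.to_undirected()
    clustering = nx.clustering(gu)
    in_deg = np.zeros(n)
    out_deg = np.zeros(n)
    neg_inc = np.zeros(n)
    tot_inc = np.zeros(n)
    for (src, tgt), (sign, _w) in network.edges.items():
        out_deg[src] += 1
        in_deg[tgt] += 1
        for node in (src, tgt):
            tot_inc[node] += 1
            if sign < 0:
                neg_inc[node] += 1
    frac_neg = np.divide(neg_inc, tot_inc, out=np.zeros(n), where=tot_inc > 0)
    inv_dist = np.zeros(n)
    if n > 1:
        for src, dists in nx.shortest_path_length(g):
            inv_dist[src] = sum(
                1.0 / d for tgt, d in dists.items() if tgt != src
            ) / (n - 1)
    feats = np.column_stack(
        [
            in_deg,
            out_deg,
            np.full(n, np.log1p(n)),
            np.array([clustering[i] for i in range(n)], dtype=float),
            frac_neg,
            inv_dist,
            (in_deg == 0).astype(float),
            np.full(n, float(max(n - 1, 1).bit_length())),
        ]
    )
    return feats


# ---------------------------------------------------------------------------
# batch assembly


@dataclass
class GraphBatch:
    """Assembled GCN input over a corpus of influence networks.

    ``labels`` are 1-based classes (0 marks the unlabeled center node in
    the full regime).  ``pooling`` is the one-hot node-to-model assignment
    (absent in the full regime).  ``provenance`` records, per member model,
    its id and half-open node-index range in the batch.
    """

    features: np.ndarray  # (N_total, D), standardized
    adjacency: np.ndarray  # (N_total, N_total), symmetric nonnegative
    labels: np.ndarray  # (N_total,), 1..C, 0 = unlabeled
    train_mask: np.ndarray  # bool
    test_mask: np.ndarray  # bool
    n_classes: int
    provenance: list[tuple[str, int, int]]
    pooling: Optional[np.ndarray] = None  # (N_total, M) one-hot
    center_index: Optional[int] = None
    train_model_ids: list[str] = field(default_factory=list)
    test_model_ids: list[str] = field(default_factory=list)

    def node_range(self, model_id: str) -> tuple[int, int]:
        for mid, lo, hi in self.provenance:
            if mid == model_id:
                return lo, hi
        raise KeyError(model_id)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _split_models(
    networks: Sequence[InfluenceNetwork], split: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole models to train/test.  The shuffle is applied to the
    models ordered by id, so membership depends only on the model
    identities and the seed, never on input order."""
    n_models = len(networks)
    by_id = np.argsort([net.model_id for net in networks], kind="stable")
    rng = np.random.default_rng(seed)
    order = by_id[rng.permutation(n_models)]
    n_train = int(round(split * n_models))
    n_train = min(max(n_train, 1), n_models - 1) if n_models > 1 else 1
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def _hub(network: InfluenceNetwork) -> int:
    """Highest total-degree node; ties broken by lowest index."""
    deg = np.zeros(network.n_nodes)
    for (src, tgt), _ in network.edges.items():
        deg[src] += 1
        deg[tgt] += 1
    return int(np.argmax(deg))


def _blocks(
    networks: Sequence[InfluenceNetwork],
    labels: Sequence[np.ndarray],
):
    sizes = [net.n_nodes for net in networks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = int(offsets[-1])
    feats = np.vstack([node_features(net) for net in networks])
    y = np.concatenate([np.asarray(l) for l in labels])
    if y.shape[0] != total:
        raise StructuralError("labels do not match network sizes")
    adj = np.zeros((total, total))
    for k, net in enumerate(networks):
        a = net.adjacency()
        a = np.maximum(a, a.T)  # symmetric unsigned blocks for the GCN
        lo = offsets[k]
        adj[lo : lo + sizes[k], lo : lo + sizes[k]] = a
    prov = [
        (net.model_id, int(offsets[k]), int(offsets[k + 1]))
        for k, net in enumerate(networks)
    ]
    return feats, adj, y, offsets, prov


def _masks(
    networks, offsets, total, split, seed
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    train_idx, test_idx = _split_models(networks, split, seed)
    train_mask = np.zeros(total, dtype=bool)
    test_mask = np.zeros(total, dtype=bool)
    for k in train_idx:
        train_mask[offsets[k] : offsets[k + 1]] = True
    for k in test_idx:
        test_mask[offsets[k] : offsets[k + 1]] = True
    return (
        train_mask,
        test_mask,
        [networks[k].model_id for k in train_idx],
        [networks[k].model_id for k in test_idx],
    )


def assemble_full_graph(
    networks: Sequence[InfluenceNetwork],
    labels: Sequence[np.ndarray],
    n_classes: int,
    split: float = 0.8,
    seed: int = 0,
) -> GraphBatch:
    """Union of all networks plus one extra center node linked (weight 1,
    undirected) to each member network's hub.  The center gets mean
    features and no label; masks split whole models."""
    if not networks:
        raise StructuralError("need at least one network")
    feats, adj, y, offsets, prov = _blocks(networks, labels)
    total = int(offsets[-1])
    center = total
    big = np.zeros((total + 1, total + 1))
    big[:total, :total] = adj
    for k, net in enumerate(networks):
        h = int(offsets[k]) + _hub(net)
        big[center, h] = 1.0
        big[h, center] = 1.0
    feats = np.vstack([feats, feats.mean(axis=0)])
    feats = _standardize(feats)
    y = np.concatenate([y, [0]])
    train_mask, test_mask, train_ids, test_ids = _masks(
        networks, offsets, total + 1, split, seed
    )
    return GraphBatch(
        features=feats,
        adjacency=big,
        labels=y,
        train_mask=train_mask,
        test_mask=test_mask,
        n_classes=n_classes,
        provenance=prov,
        center_index=center,
        train_model_ids=train_ids,
        test_model_ids=test_ids,
    )


def assemble_sparse_graph(
    networks: Sequence[InfluenceNetwork],
    labels: Sequence[np.ndarray],
    n_classes: int,
    split: float = 0.8,
    seed: int = 0,
) -> GraphBatch:
    """Block-diagonal adjacency with a one-hot pooling matrix; the pooling
    is applied to append per-graph mean features to every node."""
    if not networks:
        raise StructuralError("need at least one network")
    feats, adj, y, offsets, prov = _blocks(networks, labels)
    total = int(offsets[-1])
    m = len(networks)
    pooling = np.zeros((total, m))
    for k in range(m):
        pooling[offsets[k] : offsets[k + 1], k] = 1.0
    counts = pooling.sum(axis=0)
    graph_mean = (pooling.T @ feats) / counts[:, None]
    feats = np.hstack([feats, pooling @ graph_mean])
    feats = _standardize(feats)
    train_mask, test_mask, train_ids, test_ids = _masks(
        networks, offsets, total, split, seed
    )
    return GraphBatch(
        features=feats,
        adjacency=adj,
        labels=y,
        train_mask=train_mask,
        test_mask=test_mask,
        n_classes=n_classes,
        provenance=prov,
        pooling=pooling,
        train_model_ids=train_ids,
        test_model_ids=test_ids,
    )


# ---------------------------------------------------------------------------
# layers and training


def gcn_layer(
    h: np.ndarray,
    a: np.ndarray,
    w: np.ndarray,
    activation: Callable[[np.ndarray], np.ndarray] | str = "relu",
) -> np.ndarray:
    """One spectral graph-convolution layer.

    ``A_hat = A + I``, ``D_hat = diag(rowsum(A_hat))``, output
    ``activation(D_hat^{-1/2} A_hat D_hat^{-1/2} H W)``.  ``activation``
    may be 'relu', 'softmax', 'identity' or any callable.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("adjacency must be nonnegative")
    a_hat = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_hat.sum(axis=1))
    z = (d_inv_sqrt[:, None] * a_hat * d_inv_sqrt[None, :]) @ h @ w
    if callable(activation):
        return activation(z)
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "softmax":
        return _softmax(z)
    if activation == "identity":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _norm_operator(a: np.ndarray) -> sp.csr_matrix:
    a_hat = sp.csr_matrix(a) + sp.eye(a.shape[0], format="csr")
    d_inv_sqrt = 1.0 / np.sqrt(np.asarray(a_hat.sum(axis=1)).ravel())
    d = sp.diags(d_inv_sqrt)
    return (d @ a_hat @ d).tocsr()


@dataclass
class GCNConfig:
    """Training hyperparameters of the two-layer stack."""

    hidden_dim: int = 16
    learning_rate: float = 0.01
    dropout: float = 0.5
    max_epochs: int = 200
    weight_decay: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_gcn(batch: GraphBatch, config: GCNConfig | None = None):
    """Train the two-layer GCN on the batch's train mask.

    Returns ``(params, loss_history)`` where ``params`` is a dict of the
    two weight matrices and biases.  Classes absent from the training mask
    get weight zero in the cross-entropy (with a warning).  Fully
    deterministic under ``config.seed``.
    """
    if config is None:
        config = GCNConfig()
    rng = np.random.default_rng(config.seed)
    x = batch.features
    c = batch.n_classes
    n, d = x.shape
    op = _norm_operator(batch.adjacency)

    def glorot(fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    w1 = glorot(d, config.hidden_dim)
    b1 = np.zeros(config.hidden_dim)
    w2 = glorot(config.hidden_dim, c)
    b2 = np.zeros(c)

    train = batch.train_mask
    y = batch.labels
    y_idx = np.where(train, np.maximum(y - 1, 0), 0)
    y_onehot = np.zeros((n, c))
    y_onehot[np.arange(n), y_idx] = 1.0
    y_onehot[~train] = 0.0

    class_present = np.zeros(c, dtype=bool)
    class_present[np.unique(y[train]) - 1] = True
    if not class_present.all():
        missing = np.where(~class_present)[0] + 1
        warnings.warn(f"classes {missing.tolist()} absent from training mask")
    node_w = np.where(train, class_present[y_idx].astype(float), 0.0)
    w_sum = node_w.sum()

    opt = _Adam(
        [w1.shape, b1.shape, w2.shape, b2.shape], lr=config.learning_rate
    )
    keep = 1.0 - config.dropout
    a1 = op @ x  # fixed across epochs
    history = []
    for _epoch in range(config.max_epochs):
        z1 = a1 @ w1 + b1
        h1 = np.maximum(z1, 0.0)
        if config.dropout > 0:
            mask = (rng.random(h1.shape) < keep) / keep
            h1d = h1 * mask
        else:
            mask = None
            h1d = h1
        a2 = op @ h1d
        z2 = a2 @ w2 + b2
        p = _softmax(z2)
        logp = np.log(np.clip(p[np.arange(n), y_idx], 1e-12, None))
        loss = -(node_w * logp).sum() / w_sum
        loss += 0.5 * config.weight_decay * float(np.sum(w1 * w1))
        history.append(float(loss))

        g2 = (p - y_onehot) * (node_w / w_sum)[:, None]
        gw2 = a2.T @ g2
        gb2 = g2.sum(axis=0)
        gh1d = op.T @ (g2 @ w2.T)
        if mask is not None:
            gh1d = gh1d * mask
        gz1 = gh1d * (z1 > 0)
        gw1 = a1.T @ gz1 + config.weight_decay * w1
        gb1 = gz1.sum(axis=0)
        opt.step([w1, b1, w2, b2], [gw1, gb1, gw2, gb2])

    params = {"w1": w1, "b1": b1, "w2": w2, "b2": b2}
    return params, history


def gcn_forward(params: dict, op_or_adj, x: np.ndarray) -> np.ndarray:
    """Class probabilities (no dropout at inference)."""
    if sp.issparse(op_or_adj):
        op = op_or_adj
    else:
        op = _norm_operator(np.asarray(op_or_adj))
    h1 = np.maximum(op @ x @ params["w1"] + params["b1"], 0.0)
    return _softmax(op @ h1 @ params["w2"] + params["b2"])


def predict_labels(params: dict, batch: GraphBatch) -> np.ndarray:
    """Predicted 1-based class per node; argmax ties resolve to the lowest
    class index (numpy argmax convention)."""
    probs = gcn_forward(params, batch.adjacency, batch.features)
    return np.argmax(probs, axis=1) + 1


def labels_to_enhancement(labels: np.ndarray, model_id: str = "") -> np.ndarray:
    """Ratio reconstruction E_hat[i, j] = label(i) / label(j), diagonal 1 —
    diagonal normalization applied to predicted per-node scaled values."""
    l = np.asarray(labels, dtype=float)
    return l[:, None] / l[None, :]


def save_params(params: dict, path) -> None:
    out = {k: {"shape": list(v.shape), "data": v.ravel().tolist()}
           for k, v in params.items()}
    Path(path).write_text(json.dumps(out))


def load_params(path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {
        k: np.asarray(v["data"], dtype=float).reshape(v["shape"])
        for k, v in raw.items()
    }


# ---------------------------------------------------------------------------
# model / results objects


class GCNEnhancer:
    """Enhancement-factor learner over a corpus of dynamical models.

    Parameters
    ----------
    models : sequence of DynamicalModel
        The corpus; labels are derived from each model's Jacobian, features
        from its influence network only.
    regime : {'sparse', 'full'}
        Batching strategy (block-diagonal + pooling vs center-node union).
    config : GCNConfig, optional
    split : float
        Fraction of *models* (whole networks) assigned to training.

    Examples
    --------
    >>> from perturbprop.synthetic import generate_ensemble
    >>> models = generate_ensemble(20, seed=0)
    >>> res = GCNEnhancer(models, regime="sparse").fit()
    >>> res.test_accuracy > 0  # doctest: +SKIP
    True
    """

    def __init__(
        self,
        models: Sequence[DynamicalModel],
        regime: str = "sparse",
        config: Optional[GCNConfig] = None,
        split: float = 0.8,
        threshold: float = 0.0,
    ) -> None:
        if regime not in ("sparse", "full"):
            raise ValueError(f"unknown regime {regime!r}")
        self.models = list(models)
        self.regime = regime
        self.config = config or GCNConfig()
        self.split = split
        self.n_classes = corpus_n_classes(self.models)
        self.networks = [build_influence_network(m, threshold) for m in self.models]
        self.labels = [node_labels(m, self.n_classes) for m in self.models]
        assemble = (
            assemble_sparse_graph if regime == "sparse" else assemble_full_graph
        )
        self.batch = assemble(
            self.networks,
            self.labels,
            self.n_classes,
            split=split,
            seed=self.config.seed,
        )

    def fit(self) -> "GCNEnhancerResults":
        params, history = train_gcn(self.batch, self.config)
        return GCNEnhancerResults(self, params, history)


class GCNEnhancerResults:
    """Fitted GCN enhancer: parameters, diagnostics and reconstruction."""

    def __init__(self, model: GCNEnhancer, params: dict, loss_history: list):
        self.model = model
        self.params = params
        self.loss_history = loss_history
        self.batch = model.batch
        self._pred = predict_labels(params, self.batch)

    # -- diagnostics -------------------------------------------------------
    def _accuracy(self, mask: np.ndarray) -> float:
        return float(np.mean(self._pred[mask] == self.batch.labels[mask]))

    @property
    def train_accuracy(self) -> float:
        return self._accuracy(self.batch.train_mask)

    @property
    def test_accuracy(self) -> float:
        return self._accuracy(self.batch.test_mask)

    @property
    def majority_baseline(self) -> float:
        """Test accuracy of always predicting the most frequent training
        class."""
        y = self.batch.labels
        train_y = y[self.batch.train_mask]
        vals, counts = np.unique(train_y, return_counts=True)
        majority = vals[np.argmax(counts)]
        return float(np.mean(y[self.batch.test_mask] == majority))

    # -- reconstruction ----------------------------------------------------
    def predicted_labels(self, model_id: str) -> np.ndarray:
        lo, hi = self.batch.node_range(model_id)
        return self._pred[lo:hi]

    def predict_enhancement(self, model_id: str) -> np.ndarray:
        """Estimated enhancement factor for one member model."""
        return labels_to_enhancement(self.predicted_labels(model_id), model_id)

    def enhanced_sensitivity(
        self, model_id: str, base: SensitivityMatrix
    ) -> SensitivityMatrix:
        from .enhancement import apply_enhancement

        return apply_enhancement(self.predict_enhancement(model_id), base)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "GCN enhancement-factor model",
            "=" * 40,
            f"regime:            {self.model.regime}",
            f"models:            {len(self.model.models)} "
            f"({len(self.batch.train_model_ids)} train / "
            f"{len(self.batch.test_model_ids)} test)",
            f"nodes:             {self.batch.features.shape[0]}",
            f"features:          {self.batch.features.shape[1]}",
            f"classes:           {self.batch.n_classes}",
            f"hidden dim:        {cfg.hidden_dim}",
            f"epochs:            {len(self.loss_history)} "
            f"(lr {cfg.learning_rate}, dropout {cfg.dropout})",
            f"seed:              {cfg.seed}",
            "-" * 40,
            f"final train loss:  {self.loss_history[-1]:.4f}",
            f"train accuracy:    {self.train_accuracy:.3f}",
            f"test accuracy:     {self.test_accuracy:.3f}",
            f"majority baseline: {self.majority_baseline:.3f}",
        ]
        return "\n".join(lines)
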