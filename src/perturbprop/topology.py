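"""Topology-only sensitivity predictors (first-neighbor, distance,
propagation).

These models see only the influence network — which species affects which,
optionally with direction and sign — and never the kinetic magnitudes.
Each returns a full sensitivity matrix whose within-column ordering is what
the rank-based evaluation consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .models import InfluenceNetwork, SensitivityMatrix, ValidationError


@dataclass
class TopologyModelConfig:
    variant: str = "propagation"  # first_neighbor | distance | propagation
    directed: bool = True
    signed: bool = False  # propagation only
    alpha: float = 0.9  # propagation restart weight

    def __post_init__(self) -> None:
        if self.variant not in ("first_neighbor", "distance", "propagation"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.signed and self.variant != "propagation":
            raise ValidationError("signed applies to the propagation model only")


def _adjacency(network: InfluenceNetwork, directed: bool, signed: bool) -> np.ndarray:
    """Unweighted adjacency with A[i, j] the entry for edge j -> i.

    Undirected variants symmetrize: an edge in either direction links both
    ways (a negative sign wins ties when signed, as suppression dominates).
    """
    a = np.zeros((network.n_nodes, network.n_nodes))
    for (src, tgt), (sign, _w) in network.edges.items():
        val = float(sign) if signed else 1.0
        a[tgt, src] = val
        if not directed:
            if a[src, tgt] == 0.0 or val < 0:
                a[src, tgt] = val
    return a


def first_neighbor_model(
    network: InfluenceNetwork, directed: bool = True
) -> SensitivityMatrix:
    """Perturbation reaches only direct neighbors of the source: S_ij = 1
    iff edge j -> i exists (any direction when undirected), diagonal 1."""
    s = _adjacency(network, directed, signed=False)
    np.fill_diagonal(s, 1.0)
    tag = "first_neighbor" + ("" if directed else "_undirected")
    return SensitivityMatrix(values=s, model_id=network.model_id, method=tag)


def distance_model(
    network: InfluenceNetwork, directed: bool = True
) -> SensitivityMatrix:
    """Perturbation strength inversely proportional to hop distance.

    ``S_ij = 1 / (1 + d(j -> i))`` with ``d`` the unweighted shortest-path
    count from the source ``j``; unreachable pairs get exactly 0 (ranked
    tied-lowest downstream) and the diagonal (d = 0) is 1.
    """
    g = network.to_networkx(directed=True)
    if not directed:
        g = g.to_undirected()
    n = network.n_nodes
    s = np.zeros((n, n))
    for src, dists in nx.shortest_path_length(g):
        for tgt, d in dists.items():
            s[tgt, src] = 1.0 / (1.0 + d)
    np.fill_diagonal(s, 1.0)
    tag = "distance" + ("" if directed else "_undirected")
    return SensitivityMatrix(values=s, model_id=network.model_id, method=tag)


def propagation_kernel(
    network: InfluenceNetwork,
    alpha: float = 0.9,
    directed: bool = True,
    signed: bool = False,
) -> np.ndarray:
    """Raw network-propagation operator ``(1 - a)(I - a W)^{-1}``.

    ``W = D_out^{-1/2} A D_in^{-1/2}`` is the symmetric-degree-normalized
    walk matrix of the (optionally signed) unweighted adjacency; zero-degree
    nodes get normalizer 1.  Column j is the stationary heat of a restart
    walk injected at j.
    """
    a = _adjacency(network, directed, signed)
    n = network.n_nodes
    d_in = np.sum(np.abs(a), axis=0)  # out-strength of source columns
    d_out = np.sum(np.abs(a), axis=1)  # in-strength of target rows
    d_in[d_in == 0] = 1.0
    d_out[d_out == 0] = 1.0
    w = a / np.sqrt(d_out)[:, None] / np.sqrt(d_in)[None, :]
    m = np.eye(n) - alpha * w
    try:
        inv = np.linalg.solve(m, np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "(I - alpha W) is singular; try a smaller alpha"
        ) from exc
    return (1.0 - alpha) * inv


def propagation_model(
    network: InfluenceNetwork, config: TopologyModelConfig | None = None
) -> SensitivityMatrix:
    """Degree-weighted propagation with restart; columns rescaled so the
    diagonal is 1 (matching the shared diagonal convention)."""
    if config is None:
        config = TopologyModelConfig(variant="propagation")
    k = propagation_kernel(
        network, alpha=config.alpha, directed=config.directed, signed=config.signed
    )
    diag = np.diag(k).copy()
    safe = np.where(np.abs(diag) < 1e-12, 1.0, diag)
    s = k / safe[None, :]
    np.fill_diagonal(s, 1.0)
    tag = "propagation"
    if config.signed:
        tag += "_signed"
    if not config.directed:
        tag += "_undirected"
    return SensitivityMatrix(values=s, model_id=network.model_id, method=tag)
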