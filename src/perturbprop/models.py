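"""Core domain types and ground-truth sensitivity computation.

A dynamical model is a system of ODEs ``dx/dt = f(x)`` describing species
concentrations; around a stable steady state ``x*`` the system is summarised
by its Jacobian ``J`` with ``J[i, j] = df_i/dx_j`` evaluated at ``x*``.  The
sensitivity matrix ``S`` with ``S[i, j] = dx_i/dx_j`` records how the steady
state of species ``i`` shifts when species ``j`` is held at a displaced
value; it is the ground truth every topology-only predictor is scored
against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp


class StructuralError(ValueError):
    """Shapes or graph structure inconsistent with the contract."""


class ValidationError(ValueError):
    """Values (NaN/Inf, out-of-range) violate an invariant."""


@dataclass
class DynamicalModel:
    """A dynamical system at steady state.

    Parameters
    ----------
    species : list of str
        Ordered species names; positional index is the internal identifier.
    steady_state : (N,) array
        Nonnegative steady-state concentrations (arbitrary units).
    jacobian : (N, N) array
        ``jacobian[i, j] = df_i/dx_j`` in units 1/time, evaluated at the
        steady state.
    rhs : callable, optional
        Evaluable rate function ``f(x) -> dx/dt``; present for generated
        models, absent for imported Jacobians.
    model_id : str
    """

    species: list[str]
    steady_state: np.ndarray
    jacobian: np.ndarray
    rhs: Optional[Callable[[np.ndarray], np.ndarray]] = None
    model_id: str = ""

    def __post_init__(self) -> None:
        self.steady_state = np.asarray(self.steady_state, dtype=float)
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        n = len(self.species)
        if self.jacobian.ndim != 2 or self.jacobian.shape != (n, n):
            raise StructuralError(
                f"jacobian shape {self.jacobian.shape} does not match "
                f"{n} species"
            )
        if self.steady_state.shape != (n,):
            raise StructuralError(
                f"steady_state length {self.steady_state.shape} does not "
                f"match {n} species"
            )
        if not np.all(np.isfinite(self.jacobian)):
            raise ValidationError("jacobian contains NaN or Inf")
        if not np.all(np.isfinite(self.steady_state)):
            raise ValidationError("steady_state contains NaN or Inf")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def is_steady(self, tol: float = 1e-8) -> bool:
        """Check the steady-state residual ``||f(x*)||_inf <= tol``."""
        if self.rhs is None:
            return True
        return float(np.max(np.abs(self.rhs(self.steady_state)))) <= tol

    def is_stable(self) -> bool:
        """True if every Jacobian eigenvalue has negative real part."""
        return float(np.max(np.linalg.eigvals(self.jacobian).real)) < 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DynamicalModel):
            return NotImplemented
        return (
            self.species == other.species
            and self.model_id == other.model_id
            and np.array_equal(self.steady_state, other.steady_state)
            and np.array_equal(self.jacobian, other.jacobian)
        )


@dataclass
class InfluenceNetwork:
    """Directed signed graph read off the Jacobian sparsity pattern.

    An edge ``j -> i`` exists iff ``J[i, j] != 0`` and ``i != j``; its sign
    is ``sign(J[i, j])`` and its weight ``|J[i, j]|``.  Node names are
    carried over from the originating model.
    """

    n_nodes: int
    edges: dict[tuple[int, int], tuple[int, float]]  # (src, tgt) -> (sign, w)
    node_names: list[str] = field(default_factory=list)
    directed: bool = True
    model_id: str = ""

    def __post_init__(self) -> None:
        if not self.node_names:
            self.node_names = [f"n{i}" for i in range(self.n_nodes)]
        for (src, tgt), (sign, w) in self.edges.items():
            if src == tgt:
                raise StructuralError("self-loops are excluded")
            if sign not in (-1, 1) or w <= 0:
                raise ValidationError(f"bad edge ({src},{tgt}): {sign}, {w}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, signed: bool = False, weighted: bool = False) -> np.ndarray:
        """Dense adjacency with ``A[i, j]`` the entry for edge ``j -> i``."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (src, tgt), (sign, w) in self.edges.items():
            val = w if weighted else 1.0
            a[tgt, src] = sign * val if signed else val
        return a

    def to_networkx(self, directed: bool = True):
        import networkx as nx

        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for (src, tgt), (sign, w) in self.edges.items():
            g.add_edge(src, tgt, sign=sign, weight=w)
        return g


@dataclass
class SensitivityMatrix:
    """N x N response matrix; ``values[i, j]`` = response of species ``i``
    to a sustained perturbation at source ``j``.  Diagonal is 1 by
    convention for every method, so self-response never distorts rank
    comparisons."""

    values: np.ndarray
    model_id: str = ""
    method: str = "biochemical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise StructuralError(f"sensitivity matrix not square: {self.values.shape}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def build_influence_network(
    model: DynamicalModel, threshold: float = 0.0
) -> InfluenceNetwork:
    """Map the Jacobian's off-diagonal sparsity pattern to a signed digraph.

    Entries with ``|J[i, j]| <= threshold`` are treated as zero.  The edge
    for ``J[i, j] = df_i/dx_j`` is oriented ``j -> i`` (influence flows from
    the differentiated-with-respect-to species to the rate's species).
    """
    if threshold < 0:
        raise ValidationError("threshold must be nonnegative")
    j = model.jacobian
    n = model.n_species
    edges: dict[tuple[int, int], tuple[int, float]] = {}
    for i in range(n):
        for k in range(n):
            if i == k:
                continue
            v = j[i, k]
            if abs(v) > threshold:
                edges[(k, i)] = (1 if v > 0 else -1, abs(v))
    return InfluenceNetwork(
        n_nodes=n, edges=edges, node_names=list(model.species),
        model_id=model.model_id,
    )


def ground_truth_sensitivity(model: DynamicalModel) -> SensitivityMatrix:
    """Linear-response sensitivity from the Jacobian.

    Column ``j`` answers: if species ``j`` is clamped at a displaced value,
    where does the rest of the system settle?  By the implicit function
    theorem the first-order response solves the reduced linear system
    ``J[~j, ~j] @ dx[~j] = -J[~j, j]``, and ``S[i, j] = dx_i`` for
    ``i != j`` with ``S[j, j] = 1``.

    A singular reduced Jacobian makes that column undefined; it is filled
    with NaN and a warning is issued (mirrors attrition of unusable models
    in curated corpora).
    """
    j = model.jacobian
    n = model.n_species
    s = np.ones((n, n))
    for col in range(n):
        keep = np.arange(n) != col
        a = j[np.ix_(keep, keep)]
        b = -j[keep, col]
        try:
            dx = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            warnings.warn(
                f"model {model.model_id!r}: reduced Jacobian singular for "
                f"source {col}; column set to NaN"
            )
            s[keep, col] = np.nan
            continue
        s[keep, col] = dx
    return SensitivityMatrix(values=s, model_id=model.model_id, method="biochemical")


def ode_perturbation_oracle(
    model: DynamicalModel,
    source: int,
    delta: Optional[float] = None,
    rel_tol: float = 1e-10,
    max_time: float = 1e7,
) -> np.ndarray:
    """Brute-force sensitivity column by direct ODE integration.

    Clamps ``x[source]`` at ``x*[source] + delta``, integrates the remaining
    equations to their new steady state, and returns
    ``(x_new - x*) / delta`` componentwise (source component is 1 by
    construction).  Independent of :func:`ground_truth_sensitivity`: for
    linear systems the two are analytically identical.
    """
    if model.rhs is None:
        raise ValidationError("oracle requires an evaluable rhs")
    x0 = model.steady_state.copy()
    if delta is None:
        delta = max(1e-4 * abs(x0[source]), 1e-6)
    n = model.n_species
    keep = np.arange(n) != source
    clamped = x0.copy()
    clamped[source] += delta

    def reduced(t: float, y: np.ndarray) -> np.ndarray:
        x = clamped.copy()
        x[keep] = y
        return model.rhs(x)[keep]

    y = x0[keep].copy()
    t_span = 50.0
    total = 0.0
    while total < max_time:
        sol = solve_ivp(
            reduced, (0.0, t_span), y, method="LSODA",
            rtol=1e-12, atol=1e-14,
        )
        y_new = sol.y[:, -1]
        scale = np.maximum(np.abs(y_new), 1e-12)
        if np.max(np.abs(y_new - y) / scale) < rel_tol:
            y = y_new
            break
        y = y_new
        total += t_span
        t_span *= 2.0
    else:
        raise RuntimeError(
            f"perturbation integration did not converge for source {source}"
        )
    out = np.empty(n)
    out[source] = 1.0
    out[keep] = (y - x0[keep]) / delta
    return out


def sensitivity_via_oracle(model: DynamicalModel, **kwargs) -> SensitivityMatrix:
    """Full sensitivity matrix from the ODE oracle, column by column."""
    n = model.n_species
    s = np.empty((n, n))
    for col in range(n):
        s[:, col] = ode_perturbation_oracle(model, col, **kwargs)
    return SensitivityMatrix(values=s, model_id=model.model_id, method="ode_oracle")
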