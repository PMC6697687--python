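"""Rank-correlation scoring, corpus benchmarking and property analysis.

Accuracy of a predicted sensitivity matrix is the Spearman rank correlation
``rho = cov(rg_X, rg_Y) / (sigma_rg_X * sigma_rg_Y)`` computed column by
column (each column is one perturbation source) on the off-diagonal entries
— the fixed unit diagonal carries no information — and averaged over the
columns where it is defined.  Constant columns are skipped and counted
rather than scored as zero, so degenerate tiny models cannot silently bias
corpus means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enhancement import apply_enhancement, upper_bound_scores
from .models import (
    DynamicalModel,
    InfluenceNetwork,
    SensitivityMatrix,
    build_influence_network,
    ground_truth_sensitivity,
)
from .topology import (
    TopologyModelConfig,
    distance_model,
    first_neighbor_model,
    propagation_model,
)


def _column_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho of two vectors via midrank transform and the
    covariance formula; NaN if either vector is constant."""
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        return np.nan
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return np.nan
    cov = np.mean((rx - rx.mean()) * (ry - ry.mean()))
    return float(cov / (sx * sy))


def spearman_score(
    s_pred: np.ndarray, s_true: np.ndarray, return_n_columns: bool = False
):
    """Mean column-wise Spearman correlation, diagonal excluded.

    Parameters
    ----------
    s_pred, s_true : (N, N) arrays (or SensitivityMatrix)
    return_n_columns : bool
        Also return the number of columns with a defined correlation.
    """
    if isinstance(s_pred, SensitivityMatrix):
        s_pred = s_pred.values
    if isinstance(s_true, SensitivityMatrix):
        s_true = s_true.values
    s_pred = np.asarray(s_pred, dtype=float)
    s_true = np.asarray(s_true, dtype=float)
    if s_pred.shape != s_true.shape:
        raise ValueError(f"shape mismatch {s_pred.shape} vs {s_true.shape}")
    n = s_pred.shape[0]
    if n < 3:
        raise ValueError("need at least 3 species for a column correlation")
    rhos = []
    for j in range(n):
        keep = np.arange(n) != j
        rho = _column_rho(s_pred[keep, j], s_true[keep, j])
        if not np.isnan(rho):
            rhos.append(rho)
    if not rhos:
        warnings.warn("all columns constant; score undefined")
        score = np.nan
    else:
        score = float(np.mean(rhos))
    if return_n_columns:
        return score, len(rhos)
    return score


# ---------------------------------------------------------------------------
# benchmarking

STANDARD_METHODS = (
    "biochemical",
    "propagation_signed_directed",
    "propagation_directed",
    "propagation_undirected",
    "distance_directed",
    "distance_undirected",
    "first_neighbor_directed",
    "first_neighbor_undirected",
    "upper_bound_bio_impact",
    "upper_bound_scaled_impact",
)


@dataclass
class BenchmarkReport:
    """Per-model, per-method score table plus corpus means."""

    scores: pd.DataFrame  # index model_id, one column per method

    @property
    def means(self) -> pd.Series:
        return self.scores.mean(skipna=True)

    @property
    def counts(self) -> pd.Series:
        return self.scores.notna().sum()

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="model_id")


def _method_score(
    method: str,
    model: DynamicalModel,
    network: InfluenceNetwork,
    truth: SensitivityMatrix,
    alpha: float,
) -> float:
    # Unsigned predictors estimate influence strength only, so they are
    # scored against |truth|; the signed propagation model, which carries
    # sign information, is scored against the signed truth.
    abs_truth = np.abs(truth.values)
    if method == "biochemical":
        return spearman_score(truth.values, truth.values)
    if method.startswith("propagation"):
        cfg = TopologyModelConfig(
            variant="propagation",
            directed="undirected" not in method,
            signed="signed" in method,
            alpha=alpha,
        )
        ref = truth.values if cfg.signed else abs_truth
        return spearman_score(propagation_model(network, cfg).values, ref)
    if method.startswith("distance"):
        s = distance_model(network, directed="undirected" not in method)
        return spearman_score(s.values, abs_truth)
    if method.startswith("first_neighbor"):
        s = first_neighbor_model(network, directed="undirected" not in method)
        return spearman_score(s.values, abs_truth)
    if method.startswith("upper_bound"):
        base = distance_model(network, directed=True)
        bio, scaled = upper_bound_scores(model, base)
        return bio if method == "upper_bound_bio_impact" else scaled
    raise ValueError(f"unknown method {method!r}")


def benchmark_models(
    models: Sequence[DynamicalModel],
    methods: Sequence[str] = STANDARD_METHODS,
    alpha: float = 0.9,
    gcn_results: Optional[dict] = None,
    threshold: float = 0.0,
) -> BenchmarkReport:
    """Score every requested method against ground truth on every model.

    Per-model failures (singular ground truth, degenerate networks) are
    recorded as NaN and never abort the corpus.  ``gcn_results`` maps a
    column name to a fitted :class:`~perturbprop.gcn.GCNEnhancerResults`;
    GCN-enhanced scores are reported on that fit's held-out test models
    only (in-sample models get NaN).
    """
    rows: dict[str, dict[str, float]] = {}
    for model in models:
        network = build_influence_network(model, threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            truth = ground_truth_sensitivity(model)
        row: dict[str, float] = {}
        for method in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row[method] = _method_score(method, model, network, truth, alpha)
            except Exception:
                row[method] = np.nan
        if gcn_results:
            for name, res in gcn_results.items():
                row[name] = np.nan
                if model.model_id in res.batch.test_model_ids:
                    base = distance_model(network, directed=True)
                    enhanced = res.enhanced_sensitivity(model.model_id, base)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        row[name] = spearman_score(
                            enhanced.values, np.abs(truth.values)
                        )
        rows[model.model_id] = row
    columns = list(methods) + (list(gcn_results) if gcn_results else [])
    scores = pd.DataFrame.from_dict(rows, orient="index").reindex(
        index=[m.model_id for m in models], columns=columns
    )
    scores.index.name = "model_id"
    return BenchmarkReport(scores=scores)


def pairwise_accuracy_table(report: BenchmarkReport) -> pd.DataFrame:
    """Long-form per-model score pairs for every unordered method pair
    (the data behind pairwise scatter/diagonal accuracy panels)."""
    methods = list(report.scores.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    records = []
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            for mid, row in report.scores.iterrows():
                records.append(
                    {
                        "model_id": mid,
                        "method_a": ma,
                        "method_b": mb,
                        "score_a": row[ma],
                        "score_b": row[mb],
                    }
                )
    return pd.DataFrame.from_records(records)


def sensitivity_heatmap_export(s: SensitivityMatrix | np.ndarray, path) -> None:
    """Write a sensitivity matrix as CSV plus a rendered heatmap (PNG with
    a monotone colormap where lighter = stronger influence)."""
    from pathlib import Path

    from .io import write_matrix_csv

    values = s.values if isinstance(s, SensitivityMatrix) else np.asarray(s)
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    png_path = path.with_suffix(".png")
    names = [f"s{i}" for i in range(values.shape[0])]
    write_matrix_csv(values, names, csv_path)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, cmap="viridis")  # monotone, light = high
    fig.colorbar(im, ax=ax, label="influence")
    ax.set_xlabel("perturbation source")
    ax.set_ylabel("responding species")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# network properties

PROPERTY_NAMES = (
    "model_size",
    "mean_log10_jacobian",
    "n_strongly_connected_components",
    "mean_burt_constraint",
    "edge_density",
    "mean_shortest_path",
)


@dataclass
class PropertyProfile:
    model_id: str
    model_size: int
    mean_log10_jacobian: float
    n_strongly_connected_components: int
    mean_burt_constraint: float
    edge_density: float
    mean_shortest_path: float

    def as_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "model_size": self.model_size,
            "mean_log10_jacobian": self.mean_log10_jacobian,
            "n_strongly_connected_components": self.n_strongly_connected_components,
            "mean_burt_constraint": self.mean_burt_constraint,
            "edge_density": self.edge_density,
            "mean_shortest_path": self.mean_shortest_path,
        }


def network_properties(
    model: DynamicalModel, network: Optional[InfluenceNetwork] = None
) -> PropertyProfile:
    """Topological/kinetic descriptors of one model.

    Mean Jacobian value is the mean of log10 of the nonzero entry
    magnitudes; Burt's constraint is computed per node on the undirected
    unweighted projection and averaged (isolated nodes, where it is
    undefined, are skipped); mean shortest path averages over ordered
    reachable pairs and is NaN when no such pair exists.
    """
    if network is None:
        network = build_influence_network(model)
    n = network.n_nodes
    g = network.to_networkx(directed=True)
    gu = g.to_undirected()
    nz = np.abs(model.jacobian[model.jacobian != 0])
    mean_log_jac = float(np.mean(np.log10(nz))) if nz.size else np.nan
    n_scc = nx.number_strongly_connected_components(g)
    constraint = nx.constraint(gu)
    vals = [v for v in constraint.values() if v == v]  # drop NaN (isolated)
    mean_constraint = float(np.mean(vals)) if vals else np.nan
    density = network.n_edges / (n * (n - 1)) if n > 1 else np.nan
    path_lengths = [
        d
        for _src, dists in nx.shortest_path_length(g)
        for tgt, d in dists.items()
        if d > 0
    ]
    mean_path = float(np.mean(path_lengths)) if path_lengths else np.nan
    return PropertyProfile(
        model_id=model.model_id,
        model_size=n,
        mean_log10_jacobian=mean_log_jac,
        n_strongly_connected_components=n_scc,
        mean_burt_constraint=mean_constraint,
        edge_density=density,
        mean_shortest_path=mean_path,
    )


def property_profiles(models: Sequence[DynamicalModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [network_properties(m).as_dict() for m in models]
    ).set_index("model_id")


def property_accuracy_correlation(
    profiles: pd.DataFrame,
    report: BenchmarkReport,
    n_random: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spearman correlation of each network property with each method's
    per-model accuracy, plus a random-expectation band.

    The band half-width is twice the standard deviation of the
    correlations obtained when the property is replaced by uniform random
    values, ``n_random`` repetitions with a fixed seed — an approximate
    95% span of what a meaningless property would produce by chance at
    this corpus size.
    """
    if len(profiles) < 5:
        raise ValueError("need at least 5 models")
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    rng = np.random.default_rng(seed)
    records = []
    for method in report.scores.columns:
        acc = report.scores[method].reindex(profiles.index).to_numpy()
        ok = ~np.isnan(acc)
        null = np.array(
            [
                _column_rho(rng.uniform(size=ok.sum()), acc[ok])
                for _ in range(n_random)
            ]
        )
        band = 2.0 * float(np.nanstd(null))
        for prop in profiles.columns:
            vals = profiles[prop].to_numpy(dtype=float)
            keep = ok & ~np.isnan(vals)
            rho = (
                _column_rho(vals[keep], acc[keep]) if keep.sum() >= 3 else np.nan
            )
            records.append(
                {
                    "property": prop,
                    "method": method,
                    "rho": rho,
                    "random_band": band,
                }
            )
    return pd.DataFrame.from_records(records)
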