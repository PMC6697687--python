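"""Plain-text I/O for models, networks and matrices.

Formats
-------
Model bundle (JSON): keys ``species`` (list of names), ``steady_state``
(list of floats), ``jacobian`` (row-major nested lists), ``model_id``.
Round-trips bit-exactly (JSON floats are exact IEEE-754 reprs).

Matrix (CSV): row-major values with a header row of species names.

Network (TSV): one edge per line, columns ``source_name``, ``target_name``,
``sign``, ``weight``.  A duplicate (source, target) edge is legal in the
dialect: the last occurrence wins and a warning is logged.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np

from .models import DynamicalModel, InfluenceNetwork, StructuralError

PathLike = Union[str, Path]


def write_model(model: DynamicalModel, path: PathLike) -> None:
    bundle = {
        "model_id": model.model_id,
        "species": model.species,
        "steady_state": model.steady_state.tolist(),
        "jacobian": model.jacobian.tolist(),
    }
    Path(path).write_text(json.dumps(bundle, indent=1))


def read_model(path: PathLike) -> DynamicalModel:
    try:
        bundle = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise StructuralError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    for key in ("species", "steady_state", "jacobian"):
        if key not in bundle:
            raise StructuralError(f"{path}: missing key {key!r}")
    jac = np.asarray(bundle["jacobian"], dtype=float)
    n = len(bundle["species"])
    if jac.shape != (n, n):
        raise StructuralError(
            f"{path}: jacobian shape {jac.shape} does not match {n} species"
        )
    return DynamicalModel(
        species=list(bundle["species"]),
        steady_state=np.asarray(bundle["steady_state"], dtype=float),
        jacobian=jac,
        model_id=bundle.get("model_id", Path(path).stem),
    )


def write_matrix_csv(values: np.ndarray, names: list[str], path: PathLike) -> None:
    values = np.asarray(values, dtype=float)
    lines = [",".join(names)]
    for row in values:
        lines.append(",".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix_csv(path: PathLike) -> tuple[np.ndarray, list[str]]:
    lines = Path(path).read_text().strip().splitlines()
    names = lines[0].split(",")
    n = len(names)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        vals = line.split(",")
        if len(vals) != n:
            raise StructuralError(
                f"{path}: line {lineno} has {len(vals)} columns, expected {n}"
            )
        rows.append([float(v) for v in vals])
    mat = np.asarray(rows, dtype=float)
    if mat.shape != (n, n):
        raise StructuralError(
            f"{path}: matrix shape {mat.shape} does not match header of {n} names"
        )
    return mat, names


def write_network(network: InfluenceNetwork, path: PathLike) -> None:
    lines = ["source_name\ttarget_name\tsign\tweight"]
    for (src, tgt), (sign, w) in sorted(network.edges.items()):
        lines.append(
            f"{network.node_names[src]}\t{network.node_names[tgt]}"
            f"\t{int(sign)}\t{float(w)!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_network(path: PathLike) -> InfluenceNetwork:
    lines = Path(path).read_text().strip().splitlines()
    header = lines[0].split("\t")
    if header[:4] != ["source_name", "target_name", "sign", "weight"]:
        raise StructuralError(f"{path}: unexpected header {header}")
    names: list[str] = []
    index: dict[str, int] = {}
    edges: dict[tuple[int, int], tuple[int, float]] = {}

    def node(name: str) -> int:
        if name not in index:
            index[name] = len(names)
            names.append(name)
        return index[name]

    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 4:
            raise StructuralError(
                f"{path}: line {lineno} has {len(parts)} fields, expected 4"
            )
        src, tgt = node(parts[0]), node(parts[1])
        key = (src, tgt)
        if key in edges:
            warnings.warn(f"{path}: duplicate edge at line {lineno}; last wins")
        edges[key] = (int(parts[2]), float(parts[3]))
    return InfluenceNetwork(n_nodes=len(names), edges=edges, node_names=names)
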