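"""Readers and writers for all artifacts.

All files are tab-delimited UTF-8 text with '.' decimal separators and
full-precision floats (``%.17g``), so write -> read round-trips are
bit-exact.  Three dialects exist:

* time series: header row of region names, one data row per time point;
* square matrix: ``region`` header column plus one named row per region;
* edge list: optional ``# nodes: a,b,c`` declaration line, then a
  ``source``/``target``/``weight`` header and one row per directed edge
  (absent edges are zero; direction is source -> target, matching matrix
  entry ``(m, i)`` = influence of ``m`` on ``i``).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import yaml

from .estimator import TrainingTrace
from .types import CausalGates, DirectedConnectome, GroundTruthNetwork, \
    RoiTimeSeries

__all__ = [
    "read_timeseries", "write_timeseries",
    "read_connectome", "write_connectome_matrix", "write_edge_list",
    "write_trace", "save_model", "load_model",
    "ParseError", "resolve_config",
]

logger = logging.getLogger(__name__)

_FMT = "%.17g"


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


def _fmt_row(values: np.ndarray) -> str:
    return "\t".join(_FMT % x for x in values)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def write_timeseries(ts: RoiTimeSeries, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(ts.region_names) + "\n")
        for row in ts.values:
            fh.write(_fmt_row(row) + "\n")


def read_timeseries(path: Union[str, Path]) -> RoiTimeSeries:
    """Parse a header-bearing time-series TSV, validating shape,
    finiteness and region-name uniqueness; errors cite 1-based line
    numbers (the header is line 1)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    names = lines[0].split("\t")
    if len(set(names)) != len(names):
        raise ParseError(f"{path}: line 1: duplicate region names")
    v = len(names)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != v:
            raise ParseError(
                f"{path}: line {lineno}: expected {v} columns, "
                f"got {len(cells)}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric cell ({exc})"
            ) from None
    values = np.asarray(rows)
    if values.size and not np.all(np.isfinite(values)):
        raise ParseError(f"{path}: non-finite values present")
    ts = RoiTimeSeries(values=values, region_names=names)
    logger.info("read %s: %d time points x %d regions", path, ts.t, ts.v)
    return ts


# ---------------------------------------------------------------------------
# connectomes / gates / ground truth
# ---------------------------------------------------------------------------

_MatrixLike = Union[DirectedConnectome, CausalGates, GroundTruthNetwork,
                    np.ndarray]


def _matrix_and_names(obj: _MatrixLike,
                      region_names: Sequence[str] | None):
    if isinstance(obj, DirectedConnectome):
        return obj.weights, obj.region_names
    if isinstance(obj, CausalGates):
        return obj.gates, obj.region_names
    if isinstance(obj, GroundTruthNetwork):
        return obj.adjacency, obj.region_names
    matrix = np.asarray(obj, dtype=float)
    if region_names is None:
        from .types import default_region_names
        region_names = default_region_names(matrix.shape[0])
    return matrix, list(region_names)


def write_connectome_matrix(obj: _MatrixLike, path: Union[str, Path],
                            region_names: Sequence[str] | None = None
                            ) -> None:
    """Square-matrix TSV: ``region`` header column, one named row per
    region."""
    matrix, names = _matrix_and_names(obj, region_names)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("region\t" + "\t".join(names) + "\n")
        for name, row in zip(names, matrix):
            fh.write(name + "\t" + _fmt_row(row) + "\n")


def write_edge_list(obj: _MatrixLike, path: Union[str, Path],
                    region_names: Sequence[str] | None = None) -> None:
    """Three-column edge list with a node-set declaration so empty graphs
    round-trip."""
    matrix, names = _matrix_and_names(obj, region_names)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# nodes: " + ",".join(names) + "\n")
        fh.write("source\ttarget\tweight\n")
        for m, src in enumerate(names):
            for i, tgt in enumerate(names):
                if matrix[m, i] != 0:
                    fh.write(f"{src}\t{tgt}\t{_FMT % matrix[m, i]}\n")


def read_connectome(path: Union[str, Path],
                    directed: bool = True) -> DirectedConnectome:
    """Load either dialect (auto-detected from the header) to the same
    in-memory object."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")

    declared_nodes: list[str] | None = None
    start = 0
    if lines[0].startswith("# nodes:"):
        declared_nodes = [s.strip()
                          for s in lines[0][len("# nodes:"):].split(",")
                          if s.strip()]
        start = 1
    header = lines[start].split("\t") if start < len(lines) else []

    if header[:3] == ["source", "target", "weight"]:
        if declared_nodes is None:
            raise ParseError(
                f"{path}: edge list lacks a '# nodes:' declaration"
            )
        index = {name: j for j, name in enumerate(declared_nodes)}
        v = len(declared_nodes)
        weights = np.zeros((v, v))
        for lineno, line in enumerate(lines[start + 1:], start=start + 2):
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns"
                )
            src, tgt, w = cells
            if src not in index or tgt not in index:
                raise ParseError(
                    f"{path}: line {lineno}: undeclared node "
                    f"{src if src not in index else tgt!r}"
                )
            try:
                weights[index[src], index[tgt]] = float(w)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric weight {w!r}"
                ) from None
        np.fill_diagonal(weights, 0.0)
        return DirectedConnectome(weights=weights,
                                  region_names=declared_nodes,
                                  directed=directed, method_tag="file")

    if header and header[0] == "region":
        names = header[1:]
        v = len(names)
        weights = np.zeros((v, v))
        body = [ln for ln in lines[start + 1:] if ln.strip()]
        if len(body) != v:
            raise ParseError(
                f"{path}: matrix is not square: {v} columns but "
                f"{len(body)} rows"
            )
        for row_idx, line in enumerate(body):
            cells = line.split("\t")
            if len(cells) != v + 1:
                raise ParseError(
                    f"{path}: line {start + 2 + row_idx}: expected "
                    f"{v + 1} columns, got {len(cells)}"
                )
            try:
                weights[row_idx] = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {start + 2 + row_idx}: "
                    f"non-numeric cell ({exc})"
                ) from None
        np.fill_diagonal(weights, 0.0)
        return DirectedConnectome(weights=weights, region_names=names,
                                  directed=directed, method_tag="file")

    raise ParseError(
        f"{path}: unrecognized header (expected a 'region' matrix header "
        "or a source/target/weight edge list)"
    )


# ---------------------------------------------------------------------------
# traces, models, configs
# ---------------------------------------------------------------------------

def write_trace(trace: TrainingTrace, path: Union[str, Path]) -> None:
    """Per-epoch loss-component TSV (epoch, g_loss, d_loss, recon,
    sparsity, kl)."""
    frame = trace.to_frame()
    frame.to_csv(path, sep="\t", index=False, float_format=_FMT)


def save_model(params: dict, cfg_dict: dict,
               path: Union[str, Path]) -> None:
    """Portable JSON container for trained classifier parameters with a
    config echo."""
    payload = {
        "format": "bcen-hrgnn-model-v1",
        "config": cfg_dict,
        "params": {k: np.asarray(v).tolist() for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: Union[str, Path]) -> tuple[dict, dict]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != "bcen-hrgnn-model-v1":
        raise ParseError(f"{path}: not a recognized model container")
    params = {k: np.asarray(v, dtype=float)
              for k, v in payload["params"].items()}
    return params, payload["config"]


def resolve_config(cli_values: dict, config_path: Union[str, Path, None],
                   allowed: set[str]) -> dict:
    """Merge a YAML config file with CLI values (CLI overrides the file);
    unknown file keys are rejected by name."""
    merged: dict = {}
    if config_path is not None:
        loaded = yaml.safe_load(Path(config_path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{config_path}: config must be a mapping")
        for key in loaded:
            if key not in allowed:
                raise ValueError(
                    f"{config_path}: unknown config key {key!r}"
                )
        merged.update(loaded)
    merged.update({k: v for k, v in cli_values.items() if v is not None})
    return merged


def echo_config(cfg: dict, path: Union[str, Path]) -> None:
    """Write the fully-resolved configuration next to a run's outputs."""
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True),
                          encoding="utf-8")
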