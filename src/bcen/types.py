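"""Core containers shared across the estimation, classification and I/O layers.

Conventions
-----------
Directed edges are stored source-major: entry ``(m, i)`` of an adjacency or
gate matrix is the influence of region ``m`` on region ``i``.  Time series are
stored time-major: row ``tau`` of a :class:`RoiTimeSeries` is one acquisition
volume across all regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "GroundTruthNetwork",
    "CausalGates",
    "DirectedConnectome",
    "BrainGraph",
    "default_region_names",
]


def default_region_names(v: int, prefix: str = "ROI") -> list[str]:
    """Generate placeholder region identifiers ``ROI001 .. ROIv``."""
    width = max(3, len(str(v)))
    return [f"{prefix}{j + 1:0{width}d}" for j in range(v)]


def _as_float_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got ndim={arr.ndim}")
    return arr


@dataclass
class RoiTimeSeries:
    """A ``t x v`` matrix of per-region signals (rows = time points)."""

    values: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = _as_float_matrix(self.values, "values")
        t, v = self.values.shape
        if t < 2 or v < 2:
            raise ValueError(f"need t >= 2 and v >= 2, got t={t}, v={v}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        if not self.region_names:
            self.region_names = default_region_names(v)
        if len(self.region_names) != v:
            raise ValueError(
                f"{len(self.region_names)} region names for {v} columns"
            )
        if len(set(self.region_names)) != v:
            raise ValueError("region names must be unique")

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def v(self) -> int:
        return self.values.shape[1]


@dataclass
class GroundTruthNetwork:
    """Known directed graph used by the simulator and recovery scoring.

    ``adjacency[m, i]`` is the weight of the directed edge ``m -> i``; the
    diagonal is structurally zero (no self-loops).
    """

    adjacency: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = _as_float_matrix(self.adjacency, "adjacency")
        v, v2 = self.adjacency.shape
        if v != v2:
            raise ValueError(f"adjacency must be square, got {v}x{v2}")
        if v < 2:
            raise ValueError(f"need v >= 2, got v={v}")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be exactly zero")
        if not self.region_names:
            self.region_names = default_region_names(v)
        if len(self.region_names) != v:
            raise ValueError("region_names length mismatch")

    @property
    def v(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.adjacency))


@dataclass
class CausalGates:
    """The ``v x v`` matrix of learned directional-influence weights.

    Column ``i`` is the gate vector of region ``i``'s generative module; the
    diagonal is a structural zero (a region never gates its own prediction).
    """

    gates: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gates = _as_float_matrix(self.gates, "gates")
        v, v2 = self.gates.shape
        if v != v2:
            raise ValueError(f"gates must be square, got {v}x{v2}")
        if not self.region_names:
            self.region_names = default_region_names(v)
        if len(self.region_names) != v:
            raise ValueError("region_names length mismatch")

    @property
    def v(self) -> int:
        return self.gates.shape[0]


@dataclass
class DirectedConnectome:
    """A weighted (possibly directed) brain network with zero diagonal."""

    weights: np.ndarray
    region_names: list[str] = field(default_factory=list)
    directed: bool = True
    method_tag: str = ""

    def __post_init__(self) -> None:
        self.weights = _as_float_matrix(self.weights, "weights")
        v, v2 = self.weights.shape
        if v != v2:
            raise ValueError(f"weights must be square, got {v}x{v2}")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("connectome diagonal must be zero")
        if not self.directed and not np.allclose(self.weights, self.weights.T):
            raise ValueError("connectome flagged undirected but asymmetric")
        if not self.region_names:
            self.region_names = default_region_names(v)
        if len(self.region_names) != v:
            raise ValueError("region_names length mismatch")

    @property
    def v(self) -> int:
        return self.weights.shape[0]


@dataclass
class BrainGraph:
    """One classification unit: a connectome plus node features and a label."""

    adjacency: np.ndarray
    node_features: np.ndarray
    label: Optional[int] = None
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = _as_float_matrix(self.adjacency, "adjacency")
        self.node_features = _as_float_matrix(self.node_features, "node_features")
        v, v2 = self.adjacency.shape
        if v != v2:
            raise ValueError("adjacency must be square")
        if self.node_features.shape[0] != v:
            raise ValueError(
                f"node_features has {self.node_features.shape[0]} rows "
                f"for {v} nodes"
            )
        if not (np.all(np.isfinite(self.adjacency))
                and np.all(np.isfinite(self.node_features))):
            raise ValueError("graph contains non-finite entries")
        if not self.region_names:
            self.region_names = default_region_names(v)

    @property
    def v(self) -> int:
        return self.adjacency.shape[0]

    @property
    def d(self) -> int:
        return self.node_features.shape[1]
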