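"""Synthetic directed networks, nonlinear VAR time series, and labelled
two-class graph populations.

This module provides the ground truth against which both stages of the
pipeline are validated: the connectivity estimator must recover the directed
graph that generated a time series, and the graph classifier must separate
two populations of connectomes that differ in a small, known set of edges.

The generative model is a lag-``l`` vector autoregression with optional
elementwise nonlinearity,

    X[tau, i] = phi( sum_m A[m, i] * X[tau - l, m] ) + eps,   eps ~ N(0, sd^2)

where ``A`` is a sparse directed coupling matrix with zero diagonal and
``phi`` is either the identity or ``tanh``.  Under the identity nonlinearity
the process is stationary when the spectral radius of ``A`` is below one; a
guard rescales stronger couplings to radius 0.95 and logs a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import BrainGraph, GroundTruthNetwork, RoiTimeSeries

__all__ = [
    "SimulationConfig",
    "sample_directed_graph",
    "simulate_nonlinear_var",
    "make_group_dataset",
    "SPECTRAL_RADIUS_CAP",
]

logger = logging.getLogger(__name__)

#: Couplings with a larger spectral radius are rescaled to this value to keep
#: the identity-nonlinearity VAR stationary.
SPECTRAL_RADIUS_CAP = 0.95

_NONLINEARITIES = ("identity", "tanh")


@dataclass
class SimulationConfig:
    """Settings for :func:`simulate_nonlinear_var`.

    ``n_timepoints`` defaults to 135, the number of volumes retained per
    subject after scrubbing in typical resting-state acquisitions.
    """

    n_regions: int
    n_timepoints: int = 135
    edge_density: float = 0.25
    coupling_scale: float = 1.0
    noise_sd: float = 0.1
    nonlinearity: str = "identity"
    lag: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError(f"n_regions must be >= 2, got {self.n_regions}")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError(
                f"edge_density must lie in [0, 1], got {self.edge_density}"
            )
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        if self.n_timepoints <= self.lag:
            raise ValueError(
                f"n_timepoints ({self.n_timepoints}) must exceed lag ({self.lag})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.coupling_scale <= 0:
            raise ValueError("coupling_scale must be > 0")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(
                f"nonlinearity must be one of {_NONLINEARITIES}, "
                f"got {self.nonlinearity!r}"
            )


def sample_directed_graph(v: int, density: float, coupling_scale: float = 1.0,
                          seed: int = 0) -> GroundTruthNetwork:
    """Draw a sparse directed graph with Bernoulli edges and bounded weights.

    Each ordered off-diagonal pair ``(m, i)`` carries an edge independently
    with probability ``density``.  Edge weights are uniform on
    ``+/- [0.5, 1.0] * coupling_scale`` — bounded away from zero so that true
    edges remain identifiable from short time series.
    """
    if v < 2:
        raise ValueError(f"v must be >= 2, got {v}")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    rng = np.random.default_rng(seed)
    present = rng.random((v, v)) < density
    magnitude = rng.uniform(0.5, 1.0, size=(v, v)) * coupling_scale
    sign = rng.choice([-1.0, 1.0], size=(v, v))
    adjacency = np.where(present, sign * magnitude, 0.0)
    np.fill_diagonal(adjacency, 0.0)
    return GroundTruthNetwork(adjacency=adjacency)


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def simulate_nonlinear_var(net: GroundTruthNetwork, cfg: SimulationConfig,
                           initial: Optional[np.ndarray] = None) -> RoiTimeSeries:
    """Simulate a multivariate time series driven by ``net``.

    The first ``cfg.lag`` rows are the initial state: standard-normal draws
    by default, or the ``initial`` array (``lag x v``) when provided.  Under
    the identity nonlinearity, couplings whose spectral radius exceeds
    :data:`SPECTRAL_RADIUS_CAP` are rescaled to the cap (logged, not silent)
    so the series cannot diverge.
    """
    if net.v != cfg.n_regions:
        raise ValueError(
            f"network has {net.v} regions but config says {cfg.n_regions}"
        )
    adjacency = net.adjacency.copy()
    if cfg.nonlinearity == "identity":
        radius = _spectral_radius(adjacency)
        if radius > SPECTRAL_RADIUS_CAP:
            adjacency *= SPECTRAL_RADIUS_CAP / radius
            logger.warning(
                "coupling spectral radius %.3f exceeds %.2f; rescaled to "
                "keep the linear dynamics stationary", radius,
                SPECTRAL_RADIUS_CAP,
            )

    rng = np.random.default_rng(cfg.seed)
    t, v, lag = cfg.n_timepoints, cfg.n_regions, cfg.lag
    x = np.empty((t, v))
    if initial is None:
        x[:lag] = rng.standard_normal((lag, v))
    else:
        initial = np.asarray(initial, dtype=float)
        if initial.shape != (lag, v):
            raise ValueError(
                f"initial must have shape ({lag}, {v}), got {initial.shape}"
            )
        x[:lag] = initial
    noise = rng.normal(0.0, cfg.noise_sd, size=(t, v)) if cfg.noise_sd > 0 \
        else np.zeros((t, v))
    for tau in range(lag, t):
        drive = x[tau - lag] @ adjacency
        if cfg.nonlinearity == "tanh":
            drive = np.tanh(drive)
        x[tau] = drive + noise[tau]
    return RoiTimeSeries(values=x, region_names=list(net.region_names))


def connectome_node_features(adjacency: np.ndarray) -> np.ndarray:
    """Node features used throughout the package: rows of the symmetrized
    absolute connectome, so node ``i``'s feature vector is its undirected
    weight profile (``d = v``)."""
    a = np.abs(np.asarray(adjacency, dtype=float))
    return (a + a.T) / 2.0


def make_group_dataset(n_per_class: int, v: int, n_perturbed_edges: int,
                       effect_size: float, noise_sd: float,
                       seed: int = 0,
                       template_density: float = 0.2,
                       coupling_scale: float = 1.0) -> list[BrainGraph]:
    """Build a two-class population of connectomes with a localized group
    difference.

    One template directed graph is drawn; every subject's connectome is the
    template plus i.i.d. Normal(0, noise_sd^2) edge noise on all off-diagonal
    slots.  Class-1 subjects additionally have ``n_perturbed_edges`` fixed,
    randomly chosen off-diagonal positions shifted by ``+/- effect_size``
    (sign fixed per edge) — emulating a disease group whose pathology alters a
    small set of directed connections.  Returns ``2 * n_per_class`` graphs,
    class 0 first.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    max_slots = v * (v - 1)
    if n_perturbed_edges > max_slots:
        raise ValueError(
            f"n_perturbed_edges={n_perturbed_edges} exceeds the "
            f"{max_slots} off-diagonal slots of a {v}-region graph"
        )
    rng = np.random.default_rng(seed)
    template = sample_directed_graph(
        v, template_density, coupling_scale,
        seed=int(rng.integers(2 ** 31)),
    ).adjacency

    off_diag = [(m, i) for m in range(v) for i in range(v) if m != i]
    chosen = rng.choice(len(off_diag), size=n_perturbed_edges, replace=False)
    shift = np.zeros((v, v))
    for flat in chosen:
        m, i = off_diag[flat]
        shift[m, i] = rng.choice([-1.0, 1.0]) * effect_size

    graphs: list[BrainGraph] = []
    for label in (0, 1):
        for _ in range(n_per_class):
            noise = rng.normal(0.0, noise_sd, size=(v, v))
            np.fill_diagonal(noise, 0.0)
            adjacency = template + noise
            if label == 1:
                adjacency = adjacency + shift
            np.fill_diagonal(adjacency, 0.0)
            graphs.append(BrainGraph(
                adjacency=adjacency,
                node_features=connectome_node_features(adjacency),
                label=label,
            ))
    return graphs
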