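"""Hierarchical graph classification of brain networks.

Three stacked blocks, each a spectral graph convolution followed by TopK
pooling, turn a weighted connectome into progressively coarser subgraphs.
The convolution is

    N_{k+1} = relu( D^{-1/2} A_k D^{-1/2} N_k W_k )

on the symmetrized absolute adjacency with self-loops; pooling scores nodes
with a learnable projection (``score = N w / ||w||``), keeps the top ``p``
and gates retained features by ``tanh(score)`` so the projection receives
gradient.  After each pooling stage a per-feature L1 readout produces a
fixed-length vector; the three readouts are concatenated and classified by a
64-32 MLP with softmax under cross-entropy.

Directed, signed connectomes (as produced by the gate estimator) are
accepted: the normalization symmetrizes absolute weights, since the
``D^{-1/2} A D^{-1/2}`` form presumes symmetric nonnegative structure.

A batched NumPy forward/backward (all graphs share the atlas, hence the same
node count) keeps full-dataset training fast; the public per-graph
operations below are the reference path and the two are tested against each
other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from ._optim import Adam
from .types import BrainGraph

__all__ = [
    "HrgnnConfig",
    "LayerState",
    "normalize_adjacency",
    "gcn_layer",
    "node_scores",
    "topk_pool",
    "readout",
    "hrgnn_forward",
    "train_hrgnn",
    "predict",
    "HrgnnClassifier",
    "sweep_pool_keep",
    "resolve_keep",
]

logger = logging.getLogger(__name__)


@dataclass
class HrgnnConfig:
    """Architecture and training settings.

    ``pool_keep`` follows both dialects in use for TopK pooling: an integer
    is an absolute node budget per stage (default 40, the value found optimal
    on the dementia tasks), a float in (0, 1) a retention ratio of the
    current node count.  Counts exceeding the current node count are clamped
    with a logged warning.
    """

    n_layers: int = 3
    conv_widths: tuple[int, ...] = (64, 64, 64)
    pool_keep: Union[int, float] = 40
    mlp_widths: tuple[int, int] = (64, 32)
    learning_rate: float = 0.001
    epochs: int = 1000
    seed: int = 0
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_widths) != self.n_layers:
            raise ValueError(
                f"conv_widths has {len(self.conv_widths)} entries "
                f"for {self.n_layers} layers"
            )
        if isinstance(self.pool_keep, float):
            if not 0.0 < self.pool_keep < 1.0:
                raise ValueError(
                    f"pool_keep as a ratio must lie in (0, 1), "
                    f"got {self.pool_keep}"
                )
        elif self.pool_keep < 1:
            raise ValueError("pool_keep as a count must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class LayerState:
    """Running state of the conv/pool stack for a single graph."""

    adjacency: np.ndarray            # current (possibly pooled) raw adjacency
    features: np.ndarray             # current node features
    retained_indices: np.ndarray     # indices relative to the original graph
    layer_index: int = 0

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        self.retained_indices = np.asarray(self.retained_indices, dtype=int)


_clamp_warned: set[tuple[int, int]] = set()


def resolve_keep(keep: Union[int, float], v_current: int) -> int:
    """Resolve a ratio or absolute count against the current node count."""
    if isinstance(keep, float) and not float(keep).is_integer():
        k = max(1, int(np.ceil(keep * v_current)))
    else:
        k = int(keep)
        if k > v_current:
            if (k, v_current) not in _clamp_warned:   # warn once per shape
                _clamp_warned.add((k, v_current))
                logger.warning(
                    "pool keep %d exceeds current node count %d; clamped",
                    k, v_current,
                )
            k = v_current
    if k < 1:
        raise ValueError(f"resolved keep must be >= 1, got {k}")
    return min(k, v_current)


# ---------------------------------------------------------------------------
# public per-graph operations
# ---------------------------------------------------------------------------

def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization of a (possibly directed, signed)
    adjacency: ``D^{-1/2} (( |A| + |A|^T )/2 + I) D^{-1/2}``.

    Self-loops guarantee every degree is at least 1, so isolated nodes never
    divide by zero.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("adjacency contains non-finite entries")
    a = np.abs(A)
    a_tilde = (a + a.T) / 2.0 + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gcn_layer(state: LayerState, W_k: np.ndarray,
              activation: Callable[[np.ndarray], np.ndarray] = _relu
              ) -> np.ndarray:
    """One graph convolution: ``activation(S N W)`` with ``S`` the
    normalized current adjacency."""
    W_k = np.asarray(W_k, dtype=float)
    if state.features.shape[1] != W_k.shape[0]:
        raise ValueError(
            f"features have width {state.features.shape[1]}, "
            f"weights expect {W_k.shape[0]}"
        )
    s = normalize_adjacency(state.adjacency)
    return activation(s @ state.features @ W_k)


def node_scores(N_k: np.ndarray, projection: np.ndarray) -> np.ndarray:
    """TopK node-importance scores: projection of each node's feature row
    onto the unit direction ``w / ||w||``."""
    N_k = np.asarray(N_k, dtype=float)
    projection = np.asarray(projection, dtype=float)
    norm = np.linalg.norm(projection)
    if norm == 0:
        raise ValueError("projection vector must be non-zero")
    return N_k @ (projection / norm)


def topk_pool(state: LayerState, scores: np.ndarray,
              keep: Union[int, float]) -> LayerState:
    """Keep the highest-scoring nodes (ties broken by lower original index),
    restrict the adjacency to them, and gate retained features by
    ``tanh(score)``."""
    scores = np.asarray(scores, dtype=float)
    v_current = state.features.shape[0]
    if scores.shape != (v_current,):
        raise ValueError(
            f"scores have shape {scores.shape}, expected ({v_current},)"
        )
    k = resolve_keep(keep, v_current)
    order = np.argsort(-scores, kind="stable")   # stable => lowest index wins ties
    idx = np.sort(order[:k])
    gated = state.features[idx] * np.tanh(scores[idx])[:, None]
    return LayerState(
        adjacency=state.adjacency[np.ix_(idx, idx)],
        features=gated,
        retained_indices=state.retained_indices[idx],
        layer_index=state.layer_index + 1,
    )


def readout(N_k: np.ndarray) -> np.ndarray:
    """Permutation-invariant graph-level vector: per-feature (column-wise)
    sums of absolute values, a fixed-length L1 aggregation regardless of how
    many nodes survived pooling."""
    N_k = np.asarray(N_k, dtype=float)
    if N_k.ndim != 2 or N_k.shape[0] < 1:
        raise ValueError("readout needs at least one node")
    return np.abs(N_k).sum(axis=0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def hrgnn_forward(g: BrainGraph, params: dict,
                  cfg: HrgnnConfig) -> np.ndarray:
    """Class-probability vector for one graph via the reference per-graph
    path: conv -> pool three times, concatenated readouts, 64-32 MLP,
    softmax."""
    if g.v < 1:
        raise ValueError("graph must have at least 1 node")
    state = LayerState(adjacency=g.adjacency, features=g.node_features,
                       retained_indices=np.arange(g.v))
    readouts = []
    for k in range(cfg.n_layers):
        conv = gcn_layer(state, params[f"Wc{k}"])
        scores = node_scores(conv, params[f"p{k}"])
        state = topk_pool(
            LayerState(adjacency=state.adjacency, features=conv,
                       retained_indices=state.retained_indices,
                       layer_index=state.layer_index),
            scores, cfg.pool_keep,
        )
        readouts.append(readout(state.features))
    gr = np.concatenate(readouts)
    h0 = _relu(gr @ params["Wm0"] + params["bm0"])
    h1 = _relu(h0 @ params["Wm1"] + params["bm1"])
    logits = h1 @ params["Wout"] + params["bout"]
    return _softmax(logits)


# ---------------------------------------------------------------------------
# batched training path
# ---------------------------------------------------------------------------

def _init_params(d_in: int, cfg: HrgnnConfig,
                 rng: np.random.Generator) -> dict:
    params: dict = {}
    widths = (d_in,) + tuple(cfg.conv_widths)
    for k in range(cfg.n_layers):
        lim = 1.0 / np.sqrt(widths[k])
        params[f"Wc{k}"] = rng.uniform(-lim, lim,
                                       size=(widths[k], widths[k + 1]))
        params[f"p{k}"] = rng.uniform(-1.0, 1.0, size=widths[k + 1])
    gr_dim = sum(cfg.conv_widths)
    m0, m1 = cfg.mlp_widths
    for name, (fan_in, fan_out) in {
        "Wm0": (gr_dim, m0), "Wm1": (m0, m1), "Wout": (m1, cfg.n_classes),
    }.items():
        lim = 1.0 / np.sqrt(fan_in)
        params[name] = rng.uniform(-lim, lim, size=(fan_in, fan_out))
        params["b" + name[1:].lower() if name != "Wout" else "bout"] = \
            np.zeros(fan_out)
    return params


def _normalize_batch(A: np.ndarray) -> np.ndarray:
    a = np.abs(A)
    a_tilde = (a + np.swapaxes(a, -1, -2)) / 2.0 \
        + np.eye(A.shape[-1])[None, :, :]
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=-1))
    return a_tilde * d_inv_sqrt[:, :, None] * d_inv_sqrt[:, None, :]


def _forward_batch(A: np.ndarray, H: np.ndarray, params: dict,
                   cfg: HrgnnConfig):
    """Batched forward pass.  A: (n, v, v) raw adjacency, H: (n, v, d)."""
    n = A.shape[0]
    caches = []
    readouts = []
    for k in range(cfg.n_layers):
        s = _normalize_batch(A)
        sh = s @ H
        m = sh @ params[f"Wc{k}"]
        hc = _relu(m)
        p = params[f"p{k}"]
        p_norm = np.linalg.norm(p)
        p_hat = p / p_norm
        scores = hc @ p_hat                                  # (n, v_k)
        keep = resolve_keep(cfg.pool_keep, hc.shape[1])
        order = np.argsort(-scores, axis=1, kind="stable")
        idx = np.sort(order[:, :keep], axis=1)               # (n, keep)
        h_sel = np.take_along_axis(hc, idx[:, :, None], axis=1)
        s_sel = np.take_along_axis(scores, idx, axis=1)
        gate = np.tanh(s_sel)
        h_pool = h_sel * gate[:, :, None]
        ar = np.arange(n)[:, None, None]
        A = A[ar, idx[:, :, None], idx[:, None, :]]
        r = np.abs(h_pool).sum(axis=1)
        readouts.append(r)
        caches.append({
            "s": s, "sh": sh, "m": m, "hc": hc, "scores": scores,
            "idx": idx, "h_sel": h_sel, "gate": gate, "h_pool": h_pool,
            "p_hat": p_hat, "p_norm": p_norm,
        })
        H = h_pool
    gr = np.concatenate(readouts, axis=1)
    z0 = gr @ params["Wm0"] + params["bm0"]
    h0 = _relu(z0)
    z1 = h0 @ params["Wm1"] + params["bm1"]
    h1 = _relu(z1)
    logits = h1 @ params["Wout"] + params["bout"]
    probs = _softmax(logits)
    mlp_cache = {"gr": gr, "z0": z0, "h0": h0, "z1": z1, "h1": h1}
    return probs, caches, mlp_cache


def _backward_batch(labels: np.ndarray, probs: np.ndarray, caches: list,
                    mlp_cache: dict, params: dict, cfg: HrgnnConfig) -> dict:
    n = probs.shape[0]
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n

    h1, h0, gr = mlp_cache["h1"], mlp_cache["h0"], mlp_cache["gr"]
    grads["Wout"] = h1.T @ dlogits
    grads["bout"] = dlogits.sum(0)
    dh1 = dlogits @ params["Wout"].T
    dz1 = dh1 * (mlp_cache["z1"] > 0)
    grads["Wm1"] = h0.T @ dz1
    grads["bm1"] = dz1.sum(0)
    dh0 = dz1 @ params["Wm1"].T
    dz0 = dh0 * (mlp_cache["z0"] > 0)
    grads["Wm0"] = gr.T @ dz0
    grads["bm0"] = dz0.sum(0)
    dgr = dz0 @ params["Wm0"].T

    # split the concatenated readout gradient per stage
    splits = np.cumsum(cfg.conv_widths)[:-1]
    dr = np.split(dgr, splits, axis=1)

    carry = None   # gradient w.r.t. the current layer's pooled output
    for k in reversed(range(cfg.n_layers)):
        c = caches[k]
        dh_pool = np.sign(c["h_pool"]) * dr[k][:, None, :]
        if carry is not None:
            dh_pool = dh_pool + carry
        dh_sel = dh_pool * c["gate"][:, :, None]
        ds_sel = (dh_pool * c["h_sel"]).sum(axis=2) * (1.0 - c["gate"] ** 2)
        dhc = np.zeros_like(c["hc"])
        np.put_along_axis(dhc, c["idx"][:, :, None], dh_sel, axis=1)
        dscores = np.zeros_like(c["scores"])
        np.put_along_axis(dscores, c["idx"], ds_sel, axis=1)
        dhc += dscores[:, :, None] * c["p_hat"]
        dp_hat = np.einsum("nj,njh->h", dscores, c["hc"])
        p_hat = c["p_hat"]
        grads[f"p{k}"] = (dp_hat - (dp_hat @ p_hat) * p_hat) / c["p_norm"]
        dm = dhc * (c["m"] > 0)
        grads[f"Wc{k}"] = np.einsum("nvd,nvh->dh", c["sh"], dm)
        dh_in = c["s"] @ (dm @ params[f"Wc{k}"].T)
        carry = dh_in
    return grads


def _stack_dataset(dataset: Sequence[BrainGraph]
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    vs = {g.v for g in dataset}
    ds = {g.d for g in dataset}
    if len(vs) != 1 or len(ds) != 1:
        raise ValueError(
            "all graphs must share node count and feature width for "
            f"batched training (got v={sorted(vs)}, d={sorted(ds)})"
        )
    A = np.stack([g.adjacency for g in dataset])
    H = np.stack([g.node_features for g in dataset])
    labels = np.array([-1 if g.label is None else g.label for g in dataset])
    return A, H, labels


def train_hrgnn(dataset: Sequence[BrainGraph], cfg: HrgnnConfig
                ) -> tuple[dict, list[float]]:
    """Full-batch Adam training under cross-entropy; returns the parameter
    dictionary and the per-epoch loss trace (one record per epoch)."""
    if len(dataset) < 2:
        raise ValueError("dataset must contain at least 2 graphs")
    A, H, labels = _stack_dataset(dataset)
    classes = np.unique(labels[labels >= 0])
    if classes.size < 2:
        raise ValueError("training requires at least 2 classes present")
    if labels.min() < 0:
        raise ValueError("all training graphs must carry a label")
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(H.shape[2], cfg, rng)
    opt = Adam(params, lr=cfg.learning_rate)
    losses: list[float] = []
    for epoch in range(cfg.epochs):
        probs, caches, mlp_cache = _forward_batch(A, H, params, cfg)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(len(labels)), labels]
                                     + eps)))
        grads = _backward_batch(labels, probs, caches, mlp_cache, params, cfg)
        opt.step(params, grads)
        losses.append(loss)
        if (epoch + 1) % 100 == 0:
            logger.info("epoch %d: cross-entropy %.4f", epoch + 1, loss)
    return params, losses


def predict(dataset: Sequence[BrainGraph], params: dict,
            cfg: HrgnnConfig) -> np.ndarray:
    """Predicted class labels for a list of graphs."""
    A, H, _ = _stack_dataset(dataset)
    probs, _, _ = _forward_batch(A, H, params, cfg)
    return probs.argmax(axis=1)


class HrgnnClassifier:
    """scikit-learn-style wrapper: ``fit`` on labelled graphs, ``predict``
    labels for new ones."""

    def __init__(self, cfg: Optional[HrgnnConfig] = None) -> None:
        self.cfg = cfg if cfg is not None else HrgnnConfig()
        self.params_: Optional[dict] = None
        self.losses_: Optional[list[float]] = None

    def fit(self, graphs: Sequence[BrainGraph]) -> "HrgnnClassifier":
        self.params_, self.losses_ = train_hrgnn(graphs, self.cfg)
        return self

    def predict(self, graphs: Sequence[BrainGraph]) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        return predict(graphs, self.params_, self.cfg)

    def predict_proba(self, graphs: Sequence[BrainGraph]) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("classifier is not fitted")
        A, H, _ = _stack_dataset(graphs)
        probs, _, _ = _forward_batch(A, H, self.params_, self.cfg)
        return probs


def sweep_pool_keep(dataset: Sequence[BrainGraph], cfg: HrgnnConfig,
                    keep_values: Sequence[Union[int, float]]):
    """Ablation over the pooling budget: one 10-fold cross-validation per
    keep value with a shared fold split; returns a tidy table
    (keep, acc, sen, spe, f1)."""
    import pandas as pd

    from .evaluation import kfold_cross_validate

    if len(keep_values) == 0:
        raise ValueError("keep_values must be non-empty")
    rows = []
    for keep in keep_values:
        cfg_k = HrgnnConfig(
            n_layers=cfg.n_layers, conv_widths=cfg.conv_widths,
            pool_keep=keep, mlp_widths=cfg.mlp_widths,
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            seed=cfg.seed, n_classes=cfg.n_classes,
        )
        result = kfold_cross_validate(
            dataset, lambda: HrgnnClassifier(cfg_k), k=10, seed=cfg.seed,
        )
        pooled = result.pooled
        rows.append({"keep": keep, "acc": pooled.acc, "sen": pooled.sen,
                     "spe": pooled.spe, "f1": pooled.f1})
    return pd.DataFrame(rows)
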