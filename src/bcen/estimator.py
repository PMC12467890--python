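"""Gated generative-adversarial estimation of directed connectivity.

The estimator learns, for every region ``i``, a small generative module that
predicts region ``i``'s signal from the (lagged) signals of all other
regions.  The input of module ``i`` is the full region vector multiplied
elementwise by a learnable *causal gate* column ``g[:, i]`` whose own-region
entry is pinned at zero; the gated vector passes through one tanh hidden
layer to a scalar prediction.  After training, the magnitude of gate entry
``(m, i)`` is read out as the strength of the directed influence ``m -> i``.

Replacing the observed column ``i`` by its prediction yields a synthetic
sample ``X~_i``; a shared discriminator trained to tell real rows from
synthetic rows supplies (a) a density-ratio estimate of the KL divergence
between the real and synthetic row distributions, reported in the loss
trace, and (b) an adversarial gradient that pushes the predictions toward
the real signal distribution.

The generator objective combines squared reconstruction error, an L1 penalty
on the gates (sparse influences), and the adversarial term weighted by
``beta``; ``beta = 0`` recovers a purely regression-based estimator.

All networks are plain NumPy with hand-coded reverse-mode gradients and an
Adam optimizer; finite-difference tests in the suite verify the gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._optim import Adam
from .types import CausalGates, DirectedConnectome, RoiTimeSeries

__all__ = [
    "BcenConfig",
    "GeneratorModule",
    "Discriminator",
    "TrainingTrace",
    "TrainingDivergedError",
    "init_bcen",
    "predict_region",
    "assemble_swap_sample",
    "estimate_kl",
    "fit_discriminator",
    "generator_loss",
    "discriminator_step",
    "train_bcen",
    "extract_connectome",
]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when a non-finite loss appears during training."""

    def __init__(self, epoch: int, what: str = "generator loss") -> None:
        self.epoch = epoch
        super().__init__(f"non-finite {what} at epoch {epoch}")


@dataclass
class BcenConfig:
    """Hyperparameters of the connectivity estimator.

    Defaults follow the published training recipe: one hidden layer of 100
    tanh units per generative module, a two-hidden-layer 100-unit ReLU
    discriminator, Adam at learning rate 0.001, 3000 generator epochs
    interleaved with 1000 discriminator epochs.  ``sparsity_weight`` (lambda)
    scales the L1 gate penalty and ``adversarial_weight`` (beta) the
    discriminator-driven term; ``lag = 0`` predicts from the same time point
    (the instantaneous form), ``lag >= 1`` from the past.
    """

    hidden_width: int = 100
    learning_rate: float = 0.001
    generator_epochs: int = 3000
    discriminator_epochs: int = 1000
    sparsity_weight: float = 0.1
    adversarial_weight: float = 1.0
    lag: int = 1
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.discriminator_epochs < 1:
            raise ValueError("discriminator_epochs must be >= 1")
        if self.generator_epochs < self.discriminator_epochs:
            raise ValueError(
                "generator_epochs must be >= discriminator_epochs "
                f"({self.generator_epochs} < {self.discriminator_epochs})"
            )
        if self.sparsity_weight < 0 or self.adversarial_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.lag < 0:
            raise ValueError("lag must be >= 0")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")


@dataclass
class GeneratorModule:
    """Generative module of one region: gated input, tanh hidden layer,
    scalar linear output.  ``gate_column[index]`` is structurally zero."""

    index: int
    gate_column: np.ndarray      # (v,)
    hidden_weights: np.ndarray   # (v, h)
    hidden_bias: np.ndarray      # (h,)
    output_weights: np.ndarray   # (h,)
    output_bias: float


@dataclass
class Discriminator:
    """Shared real-vs-synthetic classifier over single time-point rows:
    two ReLU hidden layers of width 100 and a scalar logit output."""

    w1: np.ndarray   # (v, h)
    b1: np.ndarray   # (h,)
    w2: np.ndarray   # (h, h)
    b2: np.ndarray   # (h,)
    w3: np.ndarray   # (h,)
    b3: float

    def logits(self, rows: np.ndarray) -> np.ndarray:
        """Logit per row; positive means 'looks real' under the logistic
        training convention."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != self.w1.shape[0]:
            raise ValueError(
                f"rows have width {rows.shape[1]}, "
                f"discriminator expects {self.w1.shape[0]}"
            )
        h1 = np.maximum(rows @ self.w1 + self.b1, 0.0)
        h2 = np.maximum(h1 @ self.w2 + self.b2, 0.0)
        return h2 @ self.w3 + self.b3

    # -- internals used by training ------------------------------------
    def _forward_cache(self, rows: np.ndarray):
        a1 = rows @ self.w1 + self.b1
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ self.w2 + self.b2
        h2 = np.maximum(a2, 0.0)
        s = h2 @ self.w3 + self.b3
        return s, (rows, a1, h1, a2, h2)

    def _input_grad(self, ds: np.ndarray, cache) -> np.ndarray:
        _, a1, _, a2, _ = cache
        dh2 = ds[:, None] * self.w3
        da2 = dh2 * (a2 > 0)
        dh1 = da2 @ self.w2.T
        da1 = dh1 * (a1 > 0)
        return da1 @ self.w1.T

    def _param_grads(self, ds: np.ndarray, cache) -> dict:
        rows, a1, h1, a2, h2 = cache
        dh2 = ds[:, None] * self.w3
        da2 = dh2 * (a2 > 0)
        dh1 = da2 @ self.w2.T
        da1 = dh1 * (a1 > 0)
        return {
            "w3": h2.T @ ds, "b3": np.asarray(ds.sum()),
            "w2": h1.T @ da2, "b2": da2.sum(0),
            "w1": rows.T @ da1, "b1": da1.sum(0),
        }

    def _params(self) -> dict:
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2,
                "b2": self.b2, "w3": self.w3, "b3": np.asarray(self.b3)}

    def _set_params(self, params: dict) -> None:
        self.w1, self.b1 = params["w1"], params["b1"]
        self.w2, self.b2 = params["w2"], params["b2"]
        self.w3, self.b3 = params["w3"], float(params["b3"])


@dataclass
class TrainingTrace:
    """Per-epoch loss components (one record per generator epoch) plus one
    record per discriminator update."""

    epoch: list[int] = field(default_factory=list)
    generator_loss: list[float] = field(default_factory=list)
    reconstruction: list[float] = field(default_factory=list)
    sparsity: list[float] = field(default_factory=list)
    kl_estimate: list[float] = field(default_factory=list)
    gate_diag_max: list[float] = field(default_factory=list)
    discriminator_epoch: list[int] = field(default_factory=list)
    discriminator_loss: list[float] = field(default_factory=list)

    @property
    def n_generator_records(self) -> int:
        return len(self.epoch)

    @property
    def n_discriminator_records(self) -> int:
        return len(self.discriminator_epoch)

    def to_frame(self):
        """Tidy per-generator-epoch table (discriminator loss forward-filled
        as NaN where no update happened)."""
        import pandas as pd

        d_loss = np.full(len(self.epoch), np.nan)
        for e, val in zip(self.discriminator_epoch, self.discriminator_loss):
            d_loss[e] = val
        return pd.DataFrame({
            "epoch": self.epoch,
            "g_loss": self.generator_loss,
            "d_loss": d_loss,
            "recon": self.reconstruction,
            "sparsity": self.sparsity,
            "kl": self.kl_estimate,
        })


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _init_gen_params(v: int, cfg: BcenConfig, rng: np.random.Generator) -> dict:
    h = cfg.hidden_width
    gates = rng.uniform(-0.5, 0.5, size=(v, v))
    np.fill_diagonal(gates, 0.0)
    lim_in = 1.0 / np.sqrt(v)
    lim_hid = 1.0 / np.sqrt(h)
    w1 = rng.uniform(-lim_in, lim_in, size=(v, v, h))
    # gauge constraint from the start: unit-norm hidden input rows, so the
    # Uniform(-0.5, 0.5) gates are the composite path strengths at init
    norms = np.linalg.norm(w1, axis=2)
    w1 /= np.where(norms > 0, norms, 1.0)[:, :, None]
    return {
        "gates": gates,
        "w1": w1,
        "b1": rng.uniform(-lim_in, lim_in, size=(v, h)),
        "w2": rng.uniform(-lim_hid, lim_hid, size=(v, h)),
        "b2": rng.uniform(-lim_hid, lim_hid, size=(v,)),
    }


def _init_disc_params(v: int, cfg: BcenConfig, rng: np.random.Generator) -> dict:
    h = cfg.hidden_width
    lim_in = 1.0 / np.sqrt(v)
    lim_hid = 1.0 / np.sqrt(h)
    return {
        "w1": rng.uniform(-lim_in, lim_in, size=(v, h)),
        "b1": rng.uniform(-lim_in, lim_in, size=(h,)),
        "w2": rng.uniform(-lim_hid, lim_hid, size=(h, h)),
        "b2": rng.uniform(-lim_hid, lim_hid, size=(h,)),
        "w3": rng.uniform(-lim_hid, lim_hid, size=(h,)),
        "b3": np.asarray(0.0),
    }


def _modules_from_params(params: dict) -> list[GeneratorModule]:
    v = params["gates"].shape[0]
    return [
        GeneratorModule(
            index=i,
            gate_column=params["gates"][:, i],
            hidden_weights=params["w1"][i],
            hidden_bias=params["b1"][i],
            output_weights=params["w2"][i],
            output_bias=float(params["b2"][i]),
        )
        for i in range(v)
    ]


def init_bcen(v: int, cfg: BcenConfig
              ) -> tuple[list[GeneratorModule], Discriminator, CausalGates]:
    """Build the ``v`` generative modules, the shared discriminator and the
    gate matrix, fully reproducibly from ``cfg.seed``.

    Gates are i.i.d. Uniform(-0.5, 0.5) with the diagonal zeroed; network
    weights use fan-in-scaled uniform initialization.
    """
    if v < 2:
        raise ValueError(f"v must be >= 2, got {v}")
    rng = np.random.default_rng(cfg.seed)
    gen = _init_gen_params(v, cfg, rng)
    disc_p = _init_disc_params(v, cfg, rng)
    disc = Discriminator(w1=disc_p["w1"], b1=disc_p["b1"], w2=disc_p["w2"],
                         b2=disc_p["b2"], w3=disc_p["w3"],
                         b3=float(disc_p["b3"]))
    return (_modules_from_params(gen), disc,
            CausalGates(gates=gen["gates"]))


# ---------------------------------------------------------------------------
# forward pieces (public per-module API)
# ---------------------------------------------------------------------------

def predict_region(module_i: GeneratorModule, X: RoiTimeSeries,
                   lag: int = 1) -> np.ndarray:
    """Predicted signal of the module's region across all ``t`` time points.

    For ``tau >= lag`` the row ``X[tau - lag, :]`` is gated, passed through
    the tanh hidden layer and the linear output; the first ``lag`` entries
    copy the observed values (the unpredictable prefix).  ``lag = 0`` is the
    instantaneous form.
    """
    if module_i.gate_column.shape[0] != X.v:
        raise ValueError(
            f"module expects {module_i.gate_column.shape[0]} regions, "
            f"time series has {X.v}"
        )
    if lag < 0:
        raise ValueError("lag must be >= 0")
    rows = X.values if lag == 0 else X.values[:-lag]
    z = rows * module_i.gate_column
    h = np.tanh(z @ module_i.hidden_weights + module_i.hidden_bias)
    yhat = h @ module_i.output_weights + module_i.output_bias
    out = np.empty(X.t)
    out[:lag] = X.values[:lag, module_i.index]
    out[lag:] = yhat
    return out


def assemble_swap_sample(X: RoiTimeSeries, xhat_i: np.ndarray,
                         i: int) -> RoiTimeSeries:
    """Synthetic sample: a copy of ``X`` with column ``i`` replaced by the
    predicted signal; every other column is bit-identical."""
    xhat_i = np.asarray(xhat_i, dtype=float)
    if not 0 <= i < X.v:
        raise ValueError(f"region index {i} out of range for v={X.v}")
    if xhat_i.shape != (X.t,):
        raise ValueError(
            f"predicted signal has shape {xhat_i.shape}, expected ({X.t},)"
        )
    values = X.values.copy()
    values[:, i] = xhat_i
    return RoiTimeSeries(values=values, region_names=list(X.region_names))


def estimate_kl(disc: Discriminator, real_rows: np.ndarray,
                synth_rows: np.ndarray) -> float:
    """Density-ratio estimate of KL(P_real || P_synth).

    With the discriminator trained on the logistic real-vs-synthetic
    objective its logit approximates ``log(p_real / p_synth)``, so the mean
    logit over real rows estimates the KL divergence.  May be negative for an
    undertrained discriminator; no clamping.
    """
    real_rows = np.atleast_2d(np.asarray(real_rows, dtype=float))
    synth_rows = np.atleast_2d(np.asarray(synth_rows, dtype=float))
    if real_rows.size == 0 or synth_rows.size == 0:
        raise ValueError("both row sets must be non-empty")
    if real_rows.shape[1] != synth_rows.shape[1]:
        raise ValueError(
            f"row widths differ: {real_rows.shape[1]} vs {synth_rows.shape[1]}"
        )
    return float(np.mean(disc.logits(real_rows)))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generator_loss(X: RoiTimeSeries, modules: Sequence[GeneratorModule],
                   gates: CausalGates, disc: Discriminator,
                   cfg: BcenConfig) -> tuple[float, dict]:
    """Full generator objective and its components.

    total = ||X_hat - X||_2^2
          + lambda * (1/v) * sum |gates|
          + beta * sum_i KL_hat(X || X~_i)
    """
    v = X.v
    if len(modules) != v:
        raise ValueError(f"{len(modules)} modules for {v} regions")
    lag = cfg.lag
    recon = 0.0
    kl_sum = 0.0
    real_rows = X.values[lag:]
    for module in modules:
        xhat = predict_region(module, X, lag=lag)
        recon += float(np.sum((xhat - X.values[:, module.index]) ** 2))
        synth = assemble_swap_sample(X, xhat, module.index)
        kl_sum += estimate_kl(disc, real_rows, synth.values[lag:])
    sparsity = cfg.sparsity_weight * float(np.sum(np.abs(gates.gates))) / v
    total = recon + sparsity + cfg.adversarial_weight * kl_sum
    return total, {"reconstruction": recon, "sparsity": sparsity,
                   "kl": kl_sum, "total": total}


# ---------------------------------------------------------------------------
# discriminator training
# ---------------------------------------------------------------------------

def _disc_loss_and_grads(disc: Discriminator, real_rows: np.ndarray,
                         synth_rows: np.ndarray):
    """Class-balanced logistic loss: real rows labelled 1, synthetic 0."""
    s_r, cache_r = disc._forward_cache(real_rows)
    s_s, cache_s = disc._forward_cache(synth_rows)
    loss = 0.5 * float(np.mean(_softplus(-s_r))) \
        + 0.5 * float(np.mean(_softplus(s_s)))
    # d loss / d logit
    ds_r = -0.5 * _sigmoid(-s_r) / len(s_r)
    ds_s = 0.5 * _sigmoid(s_s) / len(s_s)
    grads_r = disc._param_grads(ds_r, cache_r)
    grads_s = disc._param_grads(ds_s, cache_s)
    grads = {k: grads_r[k] + grads_s[k] for k in grads_r}
    return loss, grads


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def discriminator_step(disc: Discriminator, X: RoiTimeSeries,
                       synth_samples: Sequence[RoiTimeSeries],
                       optimizer: Optional[Adam] = None,
                       lag: int = 1) -> float:
    """One optimizer step on the real-vs-synthetic logistic objective, over
    time-point rows pooled across all synthetic samples.  Returns the
    post-step loss."""
    if len(synth_samples) == 0:
        raise ValueError("at least one synthetic sample is required")
    real_rows = X.values[lag:]
    synth_rows = np.concatenate([s.values[lag:] for s in synth_samples])
    params = disc._params()
    if optimizer is None:
        optimizer = Adam(params, lr=0.001)
    _, grads = _disc_loss_and_grads(disc, real_rows, synth_rows)
    optimizer.step(params, grads)
    disc._set_params(params)
    loss_after, _ = _disc_loss_and_grads(disc, real_rows, synth_rows)
    return loss_after


def fit_discriminator(real_rows: np.ndarray, synth_rows: np.ndarray,
                      max_steps: int = 2000, lr: float = 0.001,
                      val_fraction: float = 0.2, patience: int = 20,
                      hidden_width: int = 100,
                      seed: int = 0) -> tuple[Discriminator, list[float]]:
    """Train a fresh discriminator to convergence on fixed row sets.

    Full-batch Adam with early stopping on a validation split: training
    stops once the validation logistic loss has not improved for
    ``patience`` consecutive steps, and the best-validation parameters are
    returned.  For identical real/synthetic distributions the population
    optimum is the zero logit, so early stopping prevents the overfitting
    that would otherwise bias the KL estimate away from zero.

    Returns the trained discriminator and the validation-loss history.
    """
    real_rows = np.atleast_2d(np.asarray(real_rows, dtype=float))
    synth_rows = np.atleast_2d(np.asarray(synth_rows, dtype=float))
    if real_rows.shape[1] != synth_rows.shape[1]:
        raise ValueError("row widths differ")
    rng = np.random.default_rng(seed)
    v = real_rows.shape[1]

    def split(rows):
        idx = rng.permutation(len(rows))
        n_val = max(1, int(val_fraction * len(rows)))
        return rows[idx[n_val:]], rows[idx[:n_val]]

    real_tr, real_val = split(real_rows)
    synth_tr, synth_val = split(synth_rows)

    cfg = BcenConfig(hidden_width=hidden_width, seed=seed)
    p = _init_disc_params(v, cfg, rng)
    disc = Discriminator(w1=p["w1"], b1=p["b1"], w2=p["w2"], b2=p["b2"],
                         w3=p["w3"], b3=float(p["b3"]))
    params = disc._params()
    opt = Adam(params, lr=lr)
    best = {k: np.copy(val) for k, val in params.items()}
    best_val = np.inf
    stale = 0
    history: list[float] = []
    for _ in range(max_steps):
        _, grads = _disc_loss_and_grads(disc, real_tr, synth_tr)
        opt.step(params, grads)
        disc._set_params(params)
        val_loss, _ = _disc_loss_and_grads(disc, real_val, synth_val)
        history.append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best = {k: np.copy(val) for k, val in params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    disc._set_params(best)
    return disc, history


# ---------------------------------------------------------------------------
# training loop (batched over modules)
# ---------------------------------------------------------------------------

def _gen_forward(params: dict, x_in: np.ndarray):
    """Batched forward over all v modules.  x_in: (n, v) input rows."""
    z = x_in[None, :, :] * params["gates"].T[:, None, :]      # (v, n, v)
    a = np.einsum("inv,ivh->inh", z, params["w1"]) + params["b1"][:, None, :]
    h = np.tanh(a)
    yhat = np.einsum("inh,ih->in", h, params["w2"]) + params["b2"][:, None]
    return yhat, (z, h)


def _gen_backward(params: dict, x_in: np.ndarray, dyhat: np.ndarray,
                  cache) -> dict:
    z, h = cache
    dw2 = np.einsum("inh,in->ih", h, dyhat)
    db2 = dyhat.sum(axis=1)
    dh = dyhat[:, :, None] * params["w2"][:, None, :]
    da = dh * (1.0 - h * h)
    dw1 = np.einsum("inv,inh->ivh", z, da)
    db1 = da.sum(axis=1)
    dz = np.einsum("inh,ivh->inv", da, params["w1"])
    dgates = np.einsum("inm,nm->mi", dz, x_in)
    return {"gates": dgates, "w1": dw1, "b1": db1, "w2": dw2, "b2": db2}


def _fold_gate_norms(gen: dict) -> None:
    """Gauge-fixing step that makes gate magnitudes identifiable.

    The map ``x -> (x * g) @ W1`` is invariant under rescaling input row
    ``W1[m, :]`` by ``c`` and gate ``g[m]`` by ``1/c``, so the gate alone
    carries no scale information.  After every optimizer step each hidden
    input row is renormalized to unit norm and its norm folded into the
    corresponding gate — a function-preserving reparameterization under
    which the L1 penalty acts on the true composite strength of each
    input path."""
    norms = np.linalg.norm(gen["w1"], axis=2)        # (module i, source m)
    safe = np.where(norms > 0, norms, 1.0)
    gen["w1"] /= safe[:, :, None]
    gen["gates"] *= safe.T                           # gates[m, i] <-> w1[i, m]


def train_bcen(X: RoiTimeSeries, cfg: BcenConfig
               ) -> tuple[CausalGates, TrainingTrace]:
    """Train the full estimator on one subject's time series.

    Runs ``cfg.generator_epochs`` full-batch generator updates; discriminator
    updates are spread evenly through the loop so they total exactly
    ``cfg.discriminator_epochs`` (the default 3000/1000 schedule updates the
    discriminator after every third generator epoch).  The gate diagonal is
    re-zeroed after every step.  Fully reproducible from ``cfg.seed``.
    """
    if not np.all(np.isfinite(X.values)):
        raise ValueError("time series contains non-finite values")
    if X.t <= cfg.lag:
        raise ValueError(f"need t > lag, got t={X.t}, lag={cfg.lag}")
    v, lag = X.v, cfg.lag
    values = X.values
    if cfg.standardize:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        values = (values - mu) / sd

    x_in = values if lag == 0 else values[:-lag]
    y = values[lag:] if lag > 0 else values
    n = y.shape[0]

    rng = np.random.default_rng(cfg.seed)
    gen = _init_gen_params(v, cfg, rng)
    disc_p = _init_disc_params(v, cfg, rng)
    disc = Discriminator(w1=disc_p["w1"], b1=disc_p["b1"], w2=disc_p["w2"],
                         b2=disc_p["b2"], w3=disc_p["w3"],
                         b3=float(disc_p["b3"]))
    gen_opt = Adam(gen, lr=cfg.learning_rate)
    disc_params = disc._params()
    disc_opt = Adam(disc_params, lr=cfg.learning_rate)

    trace = TrainingTrace()
    g_total, d_total = cfg.generator_epochs, cfg.discriminator_epochs
    lam, beta = cfg.sparsity_weight, cfg.adversarial_weight
    diag = np.arange(v)

    for epoch in range(g_total):
        yhat, cache = _gen_forward(gen, x_in)           # (v, n)
        resid = yhat - y.T
        recon = float(np.sum(resid ** 2))
        sparsity = lam * float(np.sum(np.abs(gen["gates"]))) / v

        # synthetic rows: module i's rows are y with column i predicted
        synth = np.broadcast_to(y, (v, n, v)).copy()
        synth[diag, :, diag] = yhat
        synth_flat = synth.reshape(v * n, v)

        s_synth, cache_synth = disc._forward_cache(synth_flat)
        kl_hat = float(np.mean(disc.logits(y))) * v     # sum over v modules
        g_loss = recon + sparsity + beta * kl_hat
        if not np.isfinite(g_loss):
            raise TrainingDivergedError(epoch)

        # optimize the per-entry mean reconstruction so the stated lambda /
        # beta defaults weigh the three terms on comparable scales; the
        # trace reports the summed form of the printed objective
        dyhat = 2.0 * resid / resid.size
        if beta > 0:
            # non-saturating adversarial surrogate: the reported KL term is
            # constant in the generator, so the gradient uses
            # beta * sum_i mean softplus(-logit(X~_i)) instead
            ds = (-beta * _sigmoid(-s_synth) / n)
            dx_synth = disc._input_grad(ds, cache_synth).reshape(v, n, v)
            dyhat = dyhat + dx_synth[diag, :, diag]

        grads = _gen_backward(gen, x_in, dyhat, cache)
        grads["gates"] += lam * np.sign(gen["gates"]) / v
        grads["gates"][diag, diag] = 0.0                # structural zero
        gen_opt.step(gen, grads)
        gen["gates"][diag, diag] = 0.0
        _fold_gate_norms(gen)

        # evenly spread discriminator updates totalling d_total
        if (epoch + 1) * d_total // g_total > epoch * d_total // g_total:
            d_loss, d_grads = _disc_loss_and_grads(disc, y, synth_flat)
            if not np.isfinite(d_loss):
                raise TrainingDivergedError(epoch, "discriminator loss")
            disc_opt.step(disc_params, d_grads)
            disc._set_params(disc_params)
            trace.discriminator_epoch.append(epoch)
            trace.discriminator_loss.append(d_loss)

        trace.epoch.append(epoch)
        trace.generator_loss.append(g_loss)
        trace.reconstruction.append(recon)
        trace.sparsity.append(sparsity)
        trace.kl_estimate.append(kl_hat)
        trace.gate_diag_max.append(float(np.max(np.abs(np.diag(gen["gates"])))))

        if (epoch + 1) % 100 == 0:
            logger.info(
                "epoch %d: g_loss=%.4f recon=%.4f sparsity=%.4f kl=%.4f",
                epoch + 1, g_loss, recon, sparsity, kl_hat,
            )

    gates = gen["gates"].copy()
    gates[diag, diag] = 0.0
    return CausalGates(gates=gates, region_names=list(X.region_names)), trace


def extract_connectome(gates: CausalGates,
                       mode: str = "absolute") -> DirectedConnectome:
    """Read the trained gates out as a weighted directed connectome.

    ``absolute`` (default) takes gate magnitudes; ``signed`` is the identity
    map.  No thresholding is applied — the continuous graph is returned.
    """
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    w = gates.gates.copy() if mode == "signed" else np.abs(gates.gates)
    np.fill_diagonal(w, 0.0)
    return DirectedConnectome(weights=w, region_names=list(gates.region_names),
                              directed=True, method_tag=f"bcen-{mode}")
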