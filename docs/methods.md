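# Methods

This note records the models implemented in `bcen`, the assumptions behind
them, the defaults and why they were chosen, and the places where the
design was genuinely open and a decision had to be made.

## Connectivity estimator

### Model

Each region *i* of a `t×v` series `X` has a generative module
`X̂[τ,i] = w₂ᵀ tanh(W₁ (g[:,i] ⊙ X[τ−lag,:]) + b₁) + b₂` with a 100-unit
hidden layer. The gate vector `g[:,i]` carries the directed influences of
all regions on region *i*; its own-region entry is a structural zero,
enforced by masking the gradient and re-zeroing after every optimizer step,
so no training dynamics can ever reintroduce a self-loop. The first `lag`
time points of each prediction copy the observed values (they have no
lagged predecessors); `lag = 0` gives the instantaneous form, and the
default `lag = 1` encodes the premise that causes precede their effects.

The `v` modules are trained jointly by full-batch Adam (lr 0.001) for 3000
generator epochs by default. A shared discriminator — two hidden ReLU
layers of width 100, scalar logit — is updated on an evenly spread schedule
totalling 1000 epochs (one update after every third generator epoch at the
defaults; the schedule generalizes to any epoch pair). It is trained with a
class-balanced logistic loss on single time-point rows: real rows of `X`
against the pooled rows of all `v` one-column-substituted samples `X̃_i`.
Rows (not whole matrices) are the sample unit because one subject provides
`t − lag` of them — enough to estimate a density ratio — whereas whole
matrices would provide exactly one.

### Loss and reported components

The generator objective is reconstruction + L1 gates + adversarial term:
`‖X̂−X‖₂² + λ(1/v)Σ|g| + βΣᵢKL̂(X‖X̃ᵢ)`. Two numerical points:

* **Scale balance.** The optimizer minimizes the *per-entry mean* of the
  reconstruction term. With the literal summed form, the reconstruction
  gradient outweighs the L1 term by the ~`t·v` entry count, the
  overparameterized modules interpolate the observation noise, and gate
  magnitudes become meaningless. The trace and the `generator_loss`
  function still report the summed form; only the gradient scaling
  differs, which leaves the minimizer family unchanged but makes the
  default λ = 0.1, β = 1 weights meaningful.
* **Adversarial gradient.** `KL̂(X‖X̃ᵢ)` is estimated as the mean
  discriminator logit over *real* rows (the standard density-ratio
  identity, since the converged logit approximates
  `log p_real/p_synth`). That expectation is constant in the generator
  parameters, so the generator's adversarial *gradient* uses the
  non-saturating surrogate `β·Σᵢ mean softplus(−logit(X̃ᵢ))`, the usual GAN
  generator objective; the reported KL component is the density-ratio
  estimate itself.

### Gate identifiability (gauge fixing)

The map `x ↦ (x ⊙ g) W₁` is invariant under rescaling input row `W₁[m,:]`
by `c` and `g[m]` by `1/c`: the gate alone carries no scale information,
and in early experiments the raw gate magnitudes ranked true edges *below*
false ones (the network used free capacity on non-edges to fit noise).
The implementation therefore fixes the gauge: hidden-layer input rows are
unit-norm at initialization and re-normalized after every step, with the
norm folded into the corresponding gate. This is function-preserving and
makes each |g[m,i]| the composite strength of the path m→i — exactly the
quantity the L1 penalty should act on and the connectome extraction reads
out. Initialization: gates i.i.d. Uniform(−0.5, 0.5) with zero diagonal;
network weights fan-in-scaled uniform (then row-normalized for `W₁`).

Inputs are z-scored per region before training (toggleable) so gate
magnitudes are comparable across regions with different signal scales.

### Discriminator convergence and KL calibration

For *identical* real and synthetic distributions the population-optimal
discriminator is the zero logit, and further training only overfits the
finite sample, biasing the KL estimate. `fit_discriminator` therefore uses
validation-based early stopping (best-validation parameters returned), and
calibration is assessed on held-out draws — the standard practice in
density-ratio estimation. At 10,000 rows per side this yields a held-out
logistic loss within ~1% of log 2 and |KL̂| below 0.01–0.05.

## Graph classifier

Three conv→pool stages. The convolution normalizes the *current* (pooled)
adjacency at every stage as `D̃^{-1/2}((|A|+|Aᵀ|)/2 + I)D̃^{-1/2}`:
symmetrized absolute weights because the spectral form presumes symmetric
non-negative structure, self-loops so isolated nodes never divide by zero.
Signed, directed connectomes (as produced by the estimator in `signed`
mode) are thereby accepted unchanged.

TopK pooling scores nodes by a learnable projection, `score = N w/‖w‖`,
keeps the `p` best (ties broken by lower original index — a fixed,
documented rule), restricts the adjacency to the kept rows/columns, and
multiplies kept features by `tanh(score)` so the projection receives
gradient. `p` may be an absolute budget (default 40 nodes, the value the
ablation identifies as optimal) or a ratio of the current node count; a
budget exceeding the node count is clamped with a logged warning.

The readout after each pooling stage is the per-feature (column-wise) sum
of absolute values. A row-wise L1 would produce a vector whose length
tracks the surviving node count and could not feed a fixed-size MLP, so
the fixed-length per-feature aggregation is used — a deliberate design
decision. The three readouts are concatenated (width 64+64+64 = 192 at the
defaults) and classified by a 64–32 ReLU MLP with softmax, trained
full-batch with Adam (lr 0.001, 1000 epochs default) under cross-entropy.

Node features default to the rows of the symmetrized absolute connectome
(`d = v`), the common self-contained choice for connectome GNNs.

Training and prediction run through a batched NumPy forward/backward over
the whole dataset (all graphs share the atlas, hence the node count); the
per-graph operations (`normalize_adjacency`, `gcn_layer`, `node_scores`,
`topk_pool`, `readout`) are the reference path and the test suite checks
the two agree to machine precision, alongside finite-difference gradient
checks and dense brute-force oracles for every layer.

## Synthetic data

`sample_directed_graph` draws each ordered off-diagonal pair independently
with the requested density; weights are uniform on ±[0.5, 1.0]·scale —
bounded away from zero so ground-truth edges are identifiable from short
series. `simulate_nonlinear_var` iterates
`X[τ] = φ(X[τ−lag] A) + ε`, φ ∈ {identity, tanh}, ε ~ N(0, sd²), with
standard-normal initial rows (overridable). Under the identity
nonlinearity, couplings with spectral radius above 0.95 are rescaled to
0.95 and a warning logged, guaranteeing stationarity.

`make_group_dataset` draws one template graph (density 0.2, scale 1.0),
adds N(0, noise_sd²) edge noise per subject, and shifts a fixed random set
of `n_perturbed_edges` positions by ±effect_size in class 1 — a stand-in
for a patient group whose pathology alters a small set of directed
connections. What this emulates — and what it does not: subjects are
exchangeable draws around one template, with no site effects, no global
scaling differences, no hemodynamic forward model and no atlas geometry.
Passing tests therefore demonstrate correctness of the algorithms under a
known generative model, not clinical performance on real fMRI.

## Evaluation

ACC/SEN/SPE/F1 come from the binary confusion table and are reported as
percentages; an undefined ratio (zero denominator) is NaN with a logged
warning, never silently 0. Cross-validation is stratified, seeded and
pooled: the headline metrics aggregate the confusion counts over all folds
(micro aggregation), with per-fold metrics also returned. Recovery of a
known graph is scored by AUROC/AUPRC of absolute off-diagonal weights
against the true edge pattern, ties handled by rank averaging. Method
comparisons use Welch's unequal-variance t-test — the safer default when
the variance assumption is unstated. The bivariate Granger baseline fits
nested OLS models per ordered pair and uses the exact F reference
distribution; its p-values are verified against statsmodels and its type-I
error against the nominal 5% level over 500 white-noise replicates.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
full pipeline executes in minutes on one CPU while every property remains
measurable: recovery uses v = 8 regions, t = 600 time points and a
500/167-epoch schedule over five seeds; the regression-limit check uses
1000/334 epochs; the classification benchmark uses 60 subjects per class
at v = 30 with 150 training epochs per fold, and the pooling ablation 60
epochs per fold across eight budgets. The full 3000/1000 and 1000-epoch
defaults remain in the configs.

## Known limitations

* Gate magnitudes are comparable thanks to gauge fixing, but carry no
  statistical significance; no edge-level inference is provided.
* The estimator assumes a single dominant lag; mixed-lag dynamics must be
  approximated through the configurable `lag`.
* The classifier's batched trainer requires all graphs to share a node
  count (one atlas), as is standard in connectome classification.
* Multivariate Granger variants, frequency-domain estimators (PDC/DTF),
  transfer entropy and DCM are out of scope; the baselines are Pearson
  correlation and pairwise Granger causality only.
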