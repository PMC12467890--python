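# bcen

Directed brain-network estimation and hierarchical graph classification.

Resting-state fMRI gives one signal per brain region (e.g. the 116 AAL
parcels), and the standard way to connect regions — Pearson correlation —
is undirected: it cannot say whether region *m* drives region *i* or the
reverse. This package implements a **Brain Connectivity Estimation Network
(BCEN)**, a gated generative-adversarial estimator of *directed* (effective)
connectivity from multivariate ROI time series, together with a
**hierarchical representation graph neural network (HRGNN)** that classifies
the resulting weighted directed connectomes, e.g. patients versus controls.
A synthetic-data module supplies ground-truth directed graphs, nonlinear
vector-autoregressive (VAR) time series, and labelled two-class graph
populations, so every stage is testable without any external dataset.

It is aimed at researchers in network neuroscience and systems biology who
want a self-contained, NumPy-only reference implementation of
gate-based causal discovery plus TopK-pooling graph classification, with
the statistics (recovery AUROC, cross-validated ACC/SEN/SPE/F1, Granger
baselines, Welch tests) built in.

## The models

**Connectivity estimator.** For time series `X ∈ R^{t×v}`, region *i* gets a
generative module that predicts its signal from all regions one lag back:

    X̂[τ, i] = f_i( g[:, i] ⊙ X[τ−1, :] ),

where `f_i` is a one-hidden-layer network (100 tanh units) and `g[:, i]` is a
learnable *causal gate* vector with `g[i, i] ≡ 0` (structural zero: no
self-loop). Replacing column *i* of `X` by its prediction yields a synthetic
sample `X̃_i`; a shared discriminator `D` (two 100-unit ReLU layers) is
trained to tell real rows from synthetic rows, and its logit provides a
density-ratio estimate of `KL(X ‖ X̃_i)`. The generator objective is

    L = ‖X̂ − X‖₂² + λ·(1/v)·Σ|g| + β·Σ_i KL̂(X ‖ X̃_i),

with λ = 0.1, β = 1 by default; β = 0 recovers a purely regression-based
estimator. After training, |g[m, i]| is read out as the weight of the
directed edge *m → i*.

**Graph classifier.** Three blocks of spectral graph convolution
`N ← relu(D̃^{-1/2} Ã D̃^{-1/2} N W)` followed by TopK pooling (learnable
projection scores, keep the best `p` nodes, gate kept features by
`tanh(score)`). After each pooling stage a per-feature L1 readout produces a
fixed-length vector; the three readouts are concatenated (`G_r = r₁‖r₂‖r₃`)
and classified by a 64–32 MLP with softmax under cross-entropy. Default
pooling budget `p = 40` nodes per stage.

Both networks are pure NumPy with hand-coded reverse-mode gradients and an
Adam optimizer; finite-difference tests verify every gradient path.

## Worked example

`examples/01_estimate_directed_connectivity.py` simulates an 8-region
linear VAR from a known sparse directed graph, trains the estimator, and
compares edge recovery against the baselines:

```
simulated 600 time points x 8 regions, 14 true directed edges
reconstruction error: 4651 -> 1443 over 500 epochs
 gated estimator: edge-recovery AUROC=1.000 AUPRC=1.000
         pearson: edge-recovery AUROC=0.412 AUPRC=0.217
         granger: edge-recovery AUROC=0.889 AUPRC=0.841
```

AUROC is the probability that a true directed edge outranks a non-edge
(0.5 = chance). The undirected correlation network cannot orient edges and
scores near chance, pairwise Granger causality does well on linear data,
and the gate magnitudes rank every true edge above every non-edge here.

`examples/02_classify_connectomes.py` cross-validates the graph classifier
on a synthetic two-class population (ten directed edges shifted in class 1):

```
10-fold CV (pooled): ACC=100.0% SEN=100.0% SPE=100.0% F1=100.0%
```

and `examples/03_pooling_ablation.py` sweeps the pooling budget with a
shared fold split, mirroring the ablation used to pick the default.

## Command line

A thin CLI wraps the library:

```bash
bcen simulate --regions 10 --timepoints 135 --density 0.2 --seed 1 --out-prefix toy
bcen estimate --input toy.ts.tsv --lambda 0.1 --beta 1.0 --seed 1 \
     --out net.tsv --trace trace.tsv
bcen baseline --method granger --input toy.ts.tsv --out gc.tsv
bcen recover  --estimate net.tsv --truth toy.truth.tsv
bcen classify train|predict|sweep ...
bcen evaluate --predictions preds.tsv --labels labels.tsv --out metrics.tsv
```

All artifacts are tab-separated text (time series, square connectome
matrices, edge lists, training traces); writes and reads round-trip
bit-exactly.

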