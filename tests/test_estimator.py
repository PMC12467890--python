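"""Tests of the gated adversarial connectivity estimator."""

import numpy as np
import pytest

from bcen._optim import Adam
from bcen.estimator import (
    BcenConfig,
    Discriminator,
    GeneratorModule,
    _disc_loss_and_grads,
    _gen_backward,
    _gen_forward,
    _init_disc_params,
    assemble_swap_sample,
    estimate_kl,
    extract_connectome,
    fit_discriminator,
    generator_loss,
    init_bcen,
    predict_region,
    train_bcen,
)
from bcen.types import CausalGates, RoiTimeSeries


def _make_disc(v, seed=0, zero_output=False):
    p = _init_disc_params(v, BcenConfig(seed=seed),
                          np.random.default_rng(seed))
    if zero_output:
        p["w3"] = np.zeros_like(p["w3"])
        p["b3"] = np.asarray(0.0)
    return Discriminator(w1=p["w1"], b1=p["b1"], w2=p["w2"], b2=p["b2"],
                         w3=p["w3"], b3=float(p["b3"]))


class TestInit:
    def test_gate_diagonal_is_structurally_zero(self):
        for v, seed in [(3, 0), (8, 5), (20, 42)]:
            _, _, gates = init_bcen(v, BcenConfig(seed=seed))
            assert np.all(np.diag(gates.gates) == 0)

    def test_bitwise_reproducible(self):
        cfg = BcenConfig(seed=17)
        mods_a, disc_a, gates_a = init_bcen(6, cfg)
        mods_b, disc_b, gates_b = init_bcen(6, cfg)
        np.testing.assert_array_equal(gates_a.gates, gates_b.gates)
        np.testing.assert_array_equal(disc_a.w1, disc_b.w1)
        for ma, mb in zip(mods_a, mods_b):
            np.testing.assert_array_equal(ma.hidden_weights,
                                          mb.hidden_weights)

    def test_full_atlas_free_entry_count(self):
        _, _, gates = init_bcen(116, BcenConfig(seed=0))
        off_diag = gates.gates[~np.eye(116, dtype=bool)]
        assert off_diag.size == 116 * 115 == 13_340
        assert np.all(off_diag != 0)   # uniform init almost surely nonzero

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            init_bcen(1, BcenConfig())


class TestPredictRegion:
    def test_zero_gate_column_gives_constant_prediction(self):
        modules, _, _ = init_bcen(4, BcenConfig(seed=1))
        mod = modules[2]
        mod.gate_column[:] = 0.0
        ts = RoiTimeSeries(values=np.random.default_rng(0)
                           .standard_normal((30, 4)))
        xhat = predict_region(mod, ts, lag=1)
        # constant up to float rounding: biases only after the prefix
        assert np.ptp(xhat[1:]) < 1e-12

    def test_matches_hand_computed_composition(self):
        # 2 regions, 3 time points, instantaneous form, hand-set weights
        mod = GeneratorModule(
            index=1,
            gate_column=np.array([2.0, 0.0]),
            hidden_weights=np.array([[1.0, -1.0], [0.5, 0.5]]),
            hidden_bias=np.array([0.1, -0.1]),
            output_weights=np.array([3.0, 1.0]),
            output_bias=0.25,
        )
        x = np.array([[0.2, 9.0], [-0.4, 9.0], [1.0, 9.0]])
        ts = RoiTimeSeries(values=x)
        got = predict_region(mod, ts, lag=0)
        for tau in range(3):
            z0 = x[tau, 0] * 2.0          # region 1's own input is gated out
            h = [np.tanh(z0 * 1.0 + 0.1), np.tanh(z0 * (-1.0) - 0.1)]
            expected = 3.0 * h[0] + 1.0 * h[1] + 0.25
            assert got[tau] == pytest.approx(expected, abs=1e-12)

    def test_prediction_monotone_in_gated_signal(self):
        # positive weights + tanh: larger gate on a positive signal raises X̂
        mod = GeneratorModule(
            index=1, gate_column=np.array([0.5, 0.0]),
            hidden_weights=np.abs(np.random.default_rng(3)
                                  .standard_normal((2, 4))),
            hidden_bias=np.zeros(4),
            output_weights=np.ones(4), output_bias=0.0,
        )
        ts = RoiTimeSeries(values=np.full((5, 2), 1.0))
        low = predict_region(mod, ts, lag=0)
        mod.gate_column[0] = 1.0
        high = predict_region(mod, ts, lag=0)
        assert np.all(high > low)

    def test_dimension_mismatch_rejected(self):
        modules, _, _ = init_bcen(4, BcenConfig(seed=1))
        ts = RoiTimeSeries(values=np.zeros((10, 3)) + np.arange(3))
        with pytest.raises(ValueError):
            predict_region(modules[0], ts, lag=1)


class TestSwapSample:
    def test_identity_substitution_is_noop(self):
        ts = RoiTimeSeries(values=np.random.default_rng(1)
                           .standard_normal((12, 5)))
        out = assemble_swap_sample(ts, ts.values[:, 3].copy(), 3)
        np.testing.assert_array_equal(out.values, ts.values)

    def test_substitution_is_local_to_one_column(self):
        ts = RoiTimeSeries(values=np.random.default_rng(2)
                           .standard_normal((12, 5)))
        out = assemble_swap_sample(ts, np.zeros(12), 2)
        for j in range(5):
            if j != 2:
                np.testing.assert_array_equal(out.values[:, j],
                                              ts.values[:, j])
        assert np.all(out.values[:, 2] == 0)

    def test_one_subject_yields_v_distinct_samples(self):
        ts = RoiTimeSeries(values=np.random.default_rng(3)
                           .standard_normal((10, 4)))
        samples = [assemble_swap_sample(ts, np.full(10, 99.0), i)
                   for i in range(4)]
        assert len(samples) == 4
        for i, s in enumerate(samples):
            for j, other in enumerate(samples):
                if i != j:
                    assert not np.array_equal(s.values, other.values)

    def test_out_of_range_index_rejected(self):
        ts = RoiTimeSeries(values=np.zeros((5, 3)) + np.arange(3))
        with pytest.raises(ValueError):
            assemble_swap_sample(ts, np.zeros(5), 3)


class TestKlEstimator:
    def test_zero_output_discriminator_gives_zero_kl(self):
        disc = _make_disc(4, zero_output=True)
        rows = np.random.default_rng(0).standard_normal((50, 4))
        assert estimate_kl(disc, rows, rows) == 0.0

    def test_width_mismatch_rejected(self):
        disc = _make_disc(4)
        with pytest.raises(ValueError):
            estimate_kl(disc, np.zeros((5, 4)), np.zeros((5, 3)))

    def test_kl_grows_with_distribution_shift(self):
        rng = np.random.default_rng(1)
        real = rng.standard_normal((3000, 4))
        estimates = []
        for shift in (0.5, 1.0):
            synth = rng.standard_normal((3000, 4)) + shift
            disc, _ = fit_discriminator(real, synth, max_steps=250,
                                        patience=25, seed=0)
            estimates.append(estimate_kl(disc, real, synth))
        # closed-form Gaussian KL: 4*shift^2/2 = 0.5 then 2.0
        assert 0 < estimates[0] < estimates[1]


class TestDiscriminator:
    def test_logistic_loss_is_nonnegative(self):
        disc = _make_disc(3, seed=2)
        rng = np.random.default_rng(2)
        loss, _ = _disc_loss_and_grads(disc, rng.standard_normal((40, 3)),
                                       rng.standard_normal((40, 3)))
        assert loss >= 0

    def test_separable_classes_drive_loss_to_zero(self):
        rng = np.random.default_rng(3)
        real = rng.standard_normal((500, 3)) + 6.0
        synth = rng.standard_normal((500, 3)) - 6.0
        disc, _ = fit_discriminator(real, synth, max_steps=2000,
                                    patience=100, seed=1)
        loss, _ = _disc_loss_and_grads(disc, real, synth)
        assert loss < 0.05

    def test_step_reduces_loss_and_rejects_empty_synthetic_set(self):
        from bcen.estimator import assemble_swap_sample, discriminator_step

        rng = np.random.default_rng(5)
        ts = RoiTimeSeries(values=rng.standard_normal((50, 3)))
        disc = _make_disc(3, seed=5)
        synth = [assemble_swap_sample(ts, rng.standard_normal(50) + 4.0, i)
                 for i in range(3)]
        losses = [discriminator_step(disc, ts, synth) for _ in range(40)]
        assert all(loss >= 0 for loss in losses)
        assert losses[-1] < losses[0]    # separable shift is learnable
        with pytest.raises(ValueError):
            discriminator_step(disc, ts, [])

    def test_input_gradient_matches_finite_differences(self):
        disc = _make_disc(3, seed=4)
        rows = np.random.default_rng(4).standard_normal((6, 3))
        s, cache = disc._forward_cache(rows)
        ds = np.ones_like(s)
        analytic = disc._input_grad(ds, cache)
        eps = 1e-6
        for n in range(rows.shape[0]):
            for j in range(rows.shape[1]):
                r = rows.copy()
                r[n, j] += eps
                up = disc.logits(r).sum()
                r[n, j] -= 2 * eps
                down = disc.logits(r).sum()
                fd = (up - down) / (2 * eps)
                assert analytic[n, j] == pytest.approx(fd, abs=1e-5)


class TestGeneratorLoss:
    def test_perfect_reconstruction_zero_gates_gives_zero_loss(self):
        v, t = 3, 6
        const = 1.7
        ts = RoiTimeSeries(values=np.full((t, v), const)
                           + np.array([0.0, 1e-9, 2e-9]))  # unique-ish cols
        modules, disc, gates = init_bcen(v, BcenConfig(seed=0))
        gates.gates[:] = 0.0
        for i, mod in enumerate(modules):
            mod.gate_column[:] = 0.0
            mod.hidden_bias[:] = 0.0
            mod.output_weights[:] = 0.0
            mod.output_bias = float(ts.values[0, i])   # constant column value
        cfg = BcenConfig(adversarial_weight=0.0, sparsity_weight=0.5, seed=0)
        total, parts = generator_loss(ts, modules, gates, disc, cfg)
        assert total == pytest.approx(0.0, abs=1e-15)
        assert parts["reconstruction"] == pytest.approx(0.0, abs=1e-15)

    def test_reduces_to_regression_loss_without_penalties(self):
        rng = np.random.default_rng(5)
        ts = RoiTimeSeries(values=rng.standard_normal((20, 4)))
        modules, disc, gates = init_bcen(4, BcenConfig(seed=5))
        cfg = BcenConfig(sparsity_weight=0.0, adversarial_weight=0.0, seed=5)
        total, parts = generator_loss(ts, modules, gates, disc, cfg)
        recon = sum(
            np.sum((predict_region(m, ts, lag=1)
                    - ts.values[:, m.index]) ** 2)
            for m in modules
        )
        assert total == pytest.approx(recon)
        assert parts["sparsity"] == 0
        # the KL estimate is still reported, but carries zero weight
        assert total == parts["reconstruction"]

    def test_matches_hand_computed_three_term_sum(self):
        rng = np.random.default_rng(6)
        ts = RoiTimeSeries(values=rng.standard_normal((8, 3)))
        modules, disc, gates = init_bcen(3, BcenConfig(seed=6))
        cfg = BcenConfig(sparsity_weight=0.3, adversarial_weight=2.0,
                         lag=1, seed=6)
        total, parts = generator_loss(ts, modules, gates, disc, cfg)
        # independent arithmetic: plain loops over the same definitions
        recon = 0.0
        kl = 0.0
        for m in modules:
            xhat = predict_region(m, ts, lag=1)
            recon += float(np.sum((xhat - ts.values[:, m.index]) ** 2))
            kl += float(np.mean(disc.logits(ts.values[1:])))
        sparsity = 0.3 * float(np.abs(gates.gates).sum()) / 3
        assert total == pytest.approx(recon + sparsity + 2.0 * kl, rel=1e-12)
        assert parts["sparsity"] == pytest.approx(sparsity)


class TestGeneratorGradients:
    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        v, h, n = 3, 5, 7
        x_in = rng.standard_normal((n, v))
        y = rng.standard_normal((n, v))
        params = {
            "gates": rng.uniform(-0.5, 0.5, (v, v)),
            "w1": rng.standard_normal((v, v, h)) * 0.3,
            "b1": rng.standard_normal((v, h)) * 0.1,
            "w2": rng.standard_normal((v, h)) * 0.3,
            "b2": rng.standard_normal(v) * 0.1,
        }

        def loss_of(p):
            yhat, _ = _gen_forward(p, x_in)
            return float(np.sum((yhat - y.T) ** 2))

        yhat, cache = _gen_forward(params, x_in)
        grads = _gen_backward(params, x_in, 2.0 * (yhat - y.T), cache)
        eps = 1e-6
        for name in params:
            flat = params[name].reshape(-1)
            for idx in rng.choice(flat.size, size=min(5, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_of(params)
                flat[idx] = orig - eps
                down = loss_of(params)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grads[name].reshape(-1)[idx] == pytest.approx(
                    fd, rel=1e-4, abs=1e-6)


class TestTraining:
    def test_trace_record_counts_match_epoch_budget(self, trained_bcen):
        cfg, _, trace = trained_bcen
        assert trace.n_generator_records == cfg.generator_epochs == 90
        assert trace.n_discriminator_records == cfg.discriminator_epochs == 30

    def test_gate_diagonal_zero_at_every_logged_epoch(self, trained_bcen):
        _, gates, trace = trained_bcen
        assert np.all(np.asarray(trace.gate_diag_max) == 0)
        assert np.all(np.diag(gates.gates) == 0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_reconstruction_decreases_during_training(self, seed):
        from bcen.synthetic import SimulationConfig, sample_directed_graph, \
            simulate_nonlinear_var
        net = sample_directed_graph(5, 0.3, 1.0, seed=seed)
        sim = SimulationConfig(n_regions=5, n_timepoints=150, noise_sd=0.1,
                               seed=seed)
        ts = simulate_nonlinear_var(net, sim)
        cfg = BcenConfig(generator_epochs=150, discriminator_epochs=50,
                         seed=seed)
        _, trace = train_bcen(ts, cfg)
        assert trace.reconstruction[-1] < trace.reconstruction[0]

    def test_training_is_deterministic(self, small_var):
        _, ts = small_var
        cfg = BcenConfig(generator_epochs=40, discriminator_epochs=14, seed=9)
        gates_a, _ = train_bcen(ts, cfg)
        gates_b, _ = train_bcen(ts, cfg)
        np.testing.assert_array_equal(gates_a.gates, gates_b.gates)

    def test_short_series_rejected(self):
        ts = RoiTimeSeries(values=np.random.default_rng(0)
                           .standard_normal((2, 3)))
        with pytest.raises(ValueError):
            train_bcen(ts, BcenConfig(lag=2, generator_epochs=3,
                                      discriminator_epochs=1))


class TestExtractConnectome:
    def test_absolute_mode_is_nonnegative_with_zero_diagonal(self):
        gates = CausalGates(gates=np.random.default_rng(1)
                            .uniform(-1, 1, (5, 5)))
        np.fill_diagonal(gates.gates, 0.0)
        conn = extract_connectome(gates, mode="absolute")
        assert np.all(conn.weights >= 0)
        assert np.all(np.diag(conn.weights) == 0)

    def test_signed_mode_is_identity(self):
        g = np.random.default_rng(2).uniform(-1, 1, (4, 4))
        np.fill_diagonal(g, 0.0)
        conn = extract_connectome(CausalGates(gates=g), mode="signed")
        np.testing.assert_array_equal(conn.weights, g)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            extract_connectome(CausalGates(gates=np.zeros((3, 3))),
                               mode="threshold")


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"generator_epochs": 10, "discriminator_epochs": 20},
        {"discriminator_epochs": 0},
        {"sparsity_weight": -0.1},
        {"lag": -1},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BcenConfig(**kwargs)
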