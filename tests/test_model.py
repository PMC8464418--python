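"""Network construction, forward variants, loss, gradients, training."""

import numpy as np
import pytest

from dcrecon.dc import DCParams, dc_image_update
from dcrecon.encoding import forward_fourier, sos_combine
from dcrecon.model import (
    NetworkConfig,
    TrainConfig,
    build_network,
    forward_reconstruct,
    forward_reconstruct_multicoil,
    loss_and_gradients,
    mse_loss,
    parameter_count,
    train,
)
from dcrecon.phantoms import (
    generate_coil_sensitivities,
    make_dataset,
)
from dcrecon.encoding import (
    AcquisitionSpec,
    make_cartesian_mask,
    simulate_acquisition,
    simulate_multicoil_acquisition,
    zero_fill_recon,
)


def _toy_instance(rng, shape=(16, 16), R=2):
    truth = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    mask = make_cartesian_mask(shape, R=R, center_fraction=0.0, seed=3)
    y = simulate_acquisition(truth, AcquisitionSpec(mask=mask))
    return truth, mask, y, zero_fill_recon(y, mask)


class TestBuildNetwork:
    def test_seeded_init_is_deterministic(self):
        cfg = NetworkConfig(seed=11)
        a, b = build_network(cfg), build_network(cfg)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_parameter_count_matches_arithmetic(self):
        # sum over layers of k^2 * c_in * c_out + c_out
        cfg = NetworkConfig(n_conv_layers=3, channels_per_layer=32,
                            kernel_size=3, in_channels=2, out_channels=2)
        expected = (9 * 2 * 32 + 32) + (9 * 32 * 32 + 32) + (9 * 32 * 2 + 2)
        assert expected == 10434
        assert parameter_count(cfg) == expected
        params = build_network(cfg)
        assert sum(w.size for w in params.weights) + sum(
            b.size for b in params.biases
        ) == expected

    def test_residual_zero_output_layer_gives_identity(self, rng):
        cfg = NetworkConfig(residual=True, use_dc=False, seed=5)
        params = build_network(cfg)  # output layer starts at zero
        _, _, _, x_u = _toy_instance(rng)
        out = forward_reconstruct(x_u, params, cfg)
        assert np.max(np.abs(out - x_u)) < 1e-12
        # and stays the identity if the hidden layers are re-randomized
        params.weights[0] = rng.standard_normal(params.weights[0].shape)
        out = forward_reconstruct(x_u, params, cfg)
        assert np.max(np.abs(out - x_u)) < 1e-12

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_conv_layers=0)
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=4)
        with pytest.raises(ValueError):
            NetworkConfig(lam=-1.0)
        with pytest.raises(ValueError):
            NetworkConfig(residual=True, in_channels=2, out_channels=4)


class TestForwardReconstruct:
    def test_hard_dc_output_matches_observation_on_sampled_set(self, rng):
        cfg = NetworkConfig(use_dc=True, lam=np.inf, seed=2)
        params = build_network(cfg)
        params.weights[-1] = rng.standard_normal(params.weights[-1].shape) * 0.1
        _, mask, y, x_u = _toy_instance(rng)
        out = forward_reconstruct(x_u, params, cfg, y=y, mask=mask)
        K = forward_fourier(out)
        assert np.max(np.abs(K[mask.mask] - y[mask.mask])) < 1e-12

    def test_no_dc_variant_is_bare_cnn(self, rng):
        cfg_ndc = NetworkConfig(use_dc=False, seed=2)
        cfg_dc = NetworkConfig(use_dc=True, lam=np.inf, seed=2)
        params = build_network(cfg_ndc)
        params.weights[-1] = rng.standard_normal(params.weights[-1].shape) * 0.1
        truth, mask, y, x_u = _toy_instance(rng)
        bare = forward_reconstruct(x_u, params, cfg_ndc)
        dc = forward_reconstruct(x_u, params, cfg_dc, y=y, mask=mask)
        assert not np.allclose(bare, dc)

    def test_zero_init_residual_with_dc_equals_dc_of_input(self, rng):
        cfg = NetworkConfig(use_dc=True, lam=1.0, seed=4)
        params = build_network(cfg)  # identity CNN
        _, mask, y, x_u = _toy_instance(rng)
        out = forward_reconstruct(x_u, params, cfg, y=y, mask=mask)
        expected = dc_image_update(x_u, y, DCParams(lam=1.0, mask=mask))
        assert np.max(np.abs(out - expected)) < 1e-12

    def test_missing_kspace_rejected(self, rng):
        cfg = NetworkConfig(use_dc=True)
        params = build_network(cfg)
        _, _, _, x_u = _toy_instance(rng)
        with pytest.raises(ValueError, match="requires"):
            forward_reconstruct(x_u, params, cfg)


class TestMultiCoil:
    def test_sos_label_path_and_hard_consistency(self, rng):
        from dcrecon.phantoms import generate_phantom

        n_coils = 2
        ph = generate_phantom((32, 32), seed=1)
        sens = generate_coil_sensitivities((32, 32), n_coils, seed=2)
        mask = make_cartesian_mask((32, 32), R=2, seed=3)
        spec = AcquisitionSpec(mask=mask, noise_sigma=0.0, seed=4)
        ys = simulate_multicoil_acquisition(ph.image, sens, spec)
        x_us = [zero_fill_recon(y, mask) for y in ys]

        cfg = NetworkConfig(in_channels=2 * n_coils, out_channels=2 * n_coils,
                            use_dc=True, lam=np.inf, seed=0)
        params = build_network(cfg)  # identity CNN at init
        out = forward_reconstruct_multicoil(x_us, params, cfg, y_coils=ys, mask=mask)
        assert np.isrealobj(out)
        # identity CNN + hard DC on noiseless data = zero-filled coils with
        # measured lines restored = the coil images themselves on C
        expected = sos_combine(
            [dc_image_update(xu, y, DCParams(lam=np.inf, mask=mask))
             for xu, y in zip(x_us, ys)]
        )
        assert np.max(np.abs(out - expected)) < 1e-12

    def test_coil_count_mismatch_rejected(self, rng):
        cfg = NetworkConfig(in_channels=4, out_channels=4, use_dc=False)
        params = build_network(cfg)
        with pytest.raises(ValueError, match="coils"):
            forward_reconstruct_multicoil([np.zeros((16, 16))], params, cfg)


class TestMSELoss:
    def test_identical_images_zero(self, random_complex_image):
        x = random_complex_image((8, 8))
        assert mse_loss(x, x) == 0.0

    def test_constant_offset_mean_convention(self):
        x_gnd = np.zeros((8, 8), dtype=complex)
        x_cnn = np.full((8, 8), 0.3 + 0j)
        assert np.isclose(mse_loss(x_gnd, x_cnn), 0.09)

    def test_matches_elementwise_brute_force(self, random_complex_image):
        a, b = random_complex_image((8, 8)), random_complex_image((8, 8))
        total = 0.0
        for i in range(8):
            for j in range(8):
                d = a[i, j] - b[i, j]
                total += d.real**2 + d.imag**2
        assert np.isclose(mse_loss(a, b), total / 64)

    def test_shape_mismatch_rejected(self, random_complex_image):
        with pytest.raises(ValueError):
            mse_loss(random_complex_image((8, 8)), random_complex_image((4, 4)))


class TestGradients:
    @pytest.mark.parametrize("use_dc,lam", [(False, 0.0), (True, 1.0), (True, np.inf)])
    def test_analytic_gradient_matches_finite_differences(self, rng, use_dc, lam):
        cfg = NetworkConfig(n_conv_layers=2, channels_per_layer=3,
                            kernel_size=3, residual=True, use_dc=use_dc,
                            lam=lam, seed=8)
        params = build_network(cfg)
        params.weights[-1] = 0.05 * rng.standard_normal(params.weights[-1].shape)
        truth, mask, y, x_u = _toy_instance(rng, shape=(4, 4) if not use_dc else (16, 16))
        args = (x_u[None], truth[None],
                y[None] if use_dc else None,
                mask.mask[None] if use_dc else None)
        _, grads = loss_and_gradients(params, cfg, *args)
        eps = 1e-6
        rng_idx = np.random.default_rng(0)
        for layer in range(2):
            W = params.weights[layer]
            flat_ids = rng_idx.choice(W.size, size=4, replace=False)
            for fid in flat_ids:
                idx = np.unravel_index(fid, W.shape)
                orig = W[idx]
                W[idx] = orig + eps
                lp, _ = loss_and_gradients(params, cfg, *args)
                W[idx] = orig - eps
                lm, _ = loss_and_gradients(params, cfg, *args)
                W[idx] = orig
                fd = (lp - lm) / (2 * eps)
                an = grads.weights[layer][idx]
                assert abs(fd - an) <= 1e-4 * max(1e-8, abs(fd)) + 1e-9


class TestTrain:
    def test_identity_task_starts_and_stays_at_zero_loss(self):
        data = make_dataset(4, (16, 16), R=1, noise_sigma=0.0, seed=1)
        cfg = NetworkConfig(n_conv_layers=2, channels_per_layer=4,
                            residual=True, use_dc=False, seed=0)
        # plain SGD and float64: updates are proportional to the (round-off
        # level) gradients, so an already-solved task stays solved.  Adam
        # would rescale even round-off gradients to learning-rate-sized
        # steps — a property of the optimizer, not of the model.
        res = train(data, cfg, TrainConfig(epochs=3, batch_size=2, seed=0,
                                           optimizer="sgd", dtype="float64"))
        assert res.loss_trace[0] < 1e-10
        assert res.loss_trace[-1] < 1e-10

    def test_training_descends_and_is_reproducible(self):
        data = make_dataset(12, (32, 32), R=4, noise_sigma=0.0, seed=2)
        cfg = NetworkConfig(n_conv_layers=2, channels_per_layer=8,
                            use_dc=False, seed=1)
        tc = TrainConfig(epochs=6, batch_size=4, learning_rate=1e-3, seed=3)
        res1 = train(data, cfg, tc)
        res2 = train(data, cfg, tc)
        assert res1.loss_trace == res2.loss_trace
        assert len(res1.loss_trace) == 6
        assert res1.loss_trace[-1] < res1.loss_trace[0]

    def test_empty_dataset_rejected(self):
        data = make_dataset(1, (16, 16), R=2, seed=0)
        empty = type(data)(samples=(), acceleration=2.0, noise_sigma=0.0, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(empty, NetworkConfig(use_dc=False), TrainConfig())

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="lbfgs")
        with pytest.raises(ValueError):
            TrainConfig(dtype="float16")
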