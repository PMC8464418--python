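"""Fourier operator contracts, Cartesian masks, the acquisition model."""

import numpy as np
import pytest

from dcrecon.encoding import (
    AcquisitionSpec,
    SamplingMask,
    forward_fourier,
    inverse_fourier,
    make_cartesian_mask,
    simulate_acquisition,
    sos_combine,
    zero_fill_recon,
)


def dense_centered_dft(shape):
    """Independent dense DFT oracle: explicit exponential sums with centered
    frequency and spatial indices (f = p - n/2, s = i - n/2)."""
    n_x, n_y = shape
    fx = np.arange(n_x) - n_x // 2
    fy = np.arange(n_y) - n_y // 2
    sx = np.arange(n_x) - n_x // 2
    sy = np.arange(n_y) - n_y // 2
    G = np.zeros((n_x * n_y, n_x * n_y), dtype=complex)
    for p in range(n_x):
        for q in range(n_y):
            for i in range(n_x):
                for j in range(n_y):
                    G[p * n_y + q, i * n_y + j] = np.exp(
                        -2j * np.pi * (fx[p] * sx[i] / n_x + fy[q] * sy[j] / n_y)
                    ) / np.sqrt(n_x * n_y)
    return G


class TestFourier:
    def test_round_trip_and_parseval(self, random_complex_image):
        x = random_complex_image((32, 32))
        k = forward_fourier(x)
        assert np.max(np.abs(inverse_fourier(k) - x)) < 1e-12
        assert abs(np.linalg.norm(k) - np.linalg.norm(x)) < 1e-10

    def test_constant_image_concentrates_at_dc(self):
        c = 2.5
        k = forward_fourier(np.full((64, 64), c, dtype=complex))
        assert np.isclose(k[32, 32], 64 * c)
        off = k.copy()
        off[32, 32] = 0
        assert np.max(np.abs(off)) < 1e-10

    def test_matches_dense_dft_oracle(self, random_complex_image):
        x = random_complex_image((8, 8))
        G = dense_centered_dft((8, 8))
        assert np.max(np.abs(forward_fourier(x).ravel() - G @ x.ravel())) < 1e-12
        k = random_complex_image((8, 8))
        assert np.max(
            np.abs(inverse_fourier(k).ravel() - G.conj().T @ k.ravel())
        ) < 1e-12

    def test_inverse_basics(self):
        assert np.all(inverse_fourier(np.zeros((16, 16))) == 0)
        impulse = np.zeros((16, 16), dtype=complex)
        impulse[8, 8] = 1.0
        img = inverse_fourier(impulse)
        assert np.allclose(img, img[0, 0])  # constant image

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            forward_fourier(np.ones(16))
        bad = np.ones((16, 16))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            forward_fourier(bad)


class TestCartesianMask:
    def test_full_sampling(self):
        m = make_cartesian_mask((32, 32), R=1)
        assert m.mask.all()
        assert len(m.sampled_set) == 32 * 32

    def test_line_counts_with_center_band(self):
        m = make_cartesian_mask((64, 64), R=2, center_fraction=0.08, seed=3)
        assert abs(m.n_sampled_lines - 32) <= 1
        # 5-line fully sampled center band
        assert m.mask[:, 30:35].all()
        # full readout direction: each kept column is fully sampled
        cols = m.mask[0]
        assert np.array_equal(m.mask, np.tile(cols, (64, 1)))

    def test_sampled_set_is_the_mask_support(self):
        m = make_cartesian_mask((32, 32), R=4, seed=9)
        flat = np.zeros(32 * 32, dtype=bool)
        flat[m.sampled_set] = True
        assert np.array_equal(flat.reshape(32, 32), m.mask)

    @pytest.mark.parametrize("shape,R", [((64, 64), 2), ((64, 48), 4),
                                         ((32, 64), 6), ((128, 96), 8)])
    def test_sampled_fraction_near_target(self, shape, R):
        m = make_cartesian_mask(shape, R=R, center_fraction=0.08, seed=1)
        n_pe = shape[1]
        assert abs(m.sampled_fraction - 1 / R) <= 1.0 / n_pe + 1e-12

    def test_rejects_impossible_acceleration(self):
        with pytest.raises(ValueError, match="central band"):
            make_cartesian_mask((64, 64), R=40, center_fraction=0.08)
        with pytest.raises(ValueError):
            make_cartesian_mask((64, 64), R=0.5)


class TestAcquisition:
    def test_noiseless_full_sampling_is_identity(self, random_complex_image):
        x = random_complex_image((32, 32))
        spec = AcquisitionSpec(mask=make_cartesian_mask((32, 32), R=1),
                               noise_sigma=0.0, seed=0)
        y = simulate_acquisition(x, spec)
        assert np.max(np.abs(inverse_fourier(y) - x)) < 1e-12

    def test_zero_outside_sampled_set(self, random_complex_image):
        mask = make_cartesian_mask((32, 32), R=4, seed=2)
        spec = AcquisitionSpec(mask=mask, noise_sigma=0.5, seed=7)
        y = simulate_acquisition(random_complex_image((32, 32)), spec)
        assert np.all(y[~mask.mask] == 0)

    def test_noise_variance_matches_model(self):
        # complex noise variance at a sampled index is 2 sigma^2
        sigma = 0.1
        x = np.ones((16, 16), dtype=complex)
        mask = make_cartesian_mask((16, 16), R=2, center_fraction=0.0, seed=0)
        gx = forward_fourier(x)
        idx = tuple(np.argwhere(mask.mask)[0])
        draws = np.empty(4000, dtype=complex)
        for s in range(draws.size):
            y = simulate_acquisition(
                x, AcquisitionSpec(mask=mask, noise_sigma=sigma, seed=s)
            )
            draws[s] = y[idx] - gx[idx]
        var = np.mean(np.abs(draws) ** 2)
        assert abs(var - 2 * sigma**2) / (2 * sigma**2) < 0.08

    def test_shape_mismatch_rejected(self, random_complex_image):
        mask = make_cartesian_mask((16, 16), R=2)
        with pytest.raises(ValueError):
            simulate_acquisition(random_complex_image((32, 32)),
                                 AcquisitionSpec(mask=mask))

    def test_negative_sigma_rejected(self):
        mask = make_cartesian_mask((16, 16), R=2)
        with pytest.raises(ValueError):
            AcquisitionSpec(mask=mask, noise_sigma=-0.1)


class TestZeroFill:
    def test_recovers_fully_sampled(self, random_complex_image):
        x = random_complex_image((32, 32))
        spec = AcquisitionSpec(mask=make_cartesian_mask((32, 32), R=1))
        assert np.max(np.abs(zero_fill_recon(simulate_acquisition(x, spec)) - x)) < 1e-12

    def test_zero_kspace_gives_zero_image(self):
        assert np.all(zero_fill_recon(np.zeros((16, 16))) == 0)

    def test_impulse_every_other_line_aliases_to_two_ghosts(self):
        # keep every other phase-encode column: the impulse splits into two
        # half-amplitude copies separated by half the field of view
        n = 16
        x = np.zeros((n, n), dtype=complex)
        x[5, 3] = 1.0
        grid = np.zeros((n, n), dtype=bool)
        grid[:, ::2] = True
        mask = SamplingMask(mask=grid, acceleration=2.0, center_fraction=0.0)
        y = simulate_acquisition(x, AcquisitionSpec(mask=mask))
        x_u = zero_fill_recon(y, mask)

        # dense-DFT oracle for the same computation
        G = dense_centered_dft((n, n))
        y_oracle = (G @ x.ravel()) * grid.ravel()
        x_oracle = (G.conj().T @ y_oracle).reshape(n, n)
        assert np.max(np.abs(x_u - x_oracle)) < 1e-12

        mags = np.abs(x_u)
        ghosts = np.argwhere(mags > 1e-10)
        assert len(ghosts) == 2
        assert np.allclose(mags[mags > 1e-10], 0.5)
        assert {tuple(g) for g in ghosts} == {(5, 3), (5, (3 + n // 2) % n)}

    def test_rejects_nonzero_outside_sampled_set(self, random_complex_image):
        mask = make_cartesian_mask((16, 16), R=2, center_fraction=0.0, seed=0)
        y = random_complex_image((16, 16))  # nonzero everywhere
        with pytest.raises(ValueError, match="outside the sampled set"):
            zero_fill_recon(y, mask)


class TestSOSCombine:
    def test_single_coil_is_magnitude(self, random_complex_image):
        x = random_complex_image((8, 8))
        assert np.allclose(sos_combine([x]), np.abs(x))

    def test_two_identical_coils(self, random_complex_image):
        x = random_complex_image((8, 8))
        assert np.allclose(sos_combine([x, x]), np.sqrt(2) * np.abs(x))

    def test_matches_per_pixel_brute_force(self, random_complex_image):
        coils = [random_complex_image((8, 8)) for _ in range(4)]
        expected = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                expected[i, j] = np.sqrt(
                    sum(abs(c[i, j]) ** 2 for c in coils)
                )
        assert np.allclose(sos_combine(coils), expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sos_combine([])
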