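"""Fourier encoding, Cartesian undersampling and the MR acquisition model.

MR data are acquired in k-space (the 2D spatial-frequency domain).  An
accelerated scan measures only a subset ``C`` of k-space locations, selected
by a binary sampling mask ``m``.  The forward model is

    y = m ⊙ (G x + i)

where ``G`` is the 2D Fourier transform of the image ``x`` and ``i`` is
complex Gaussian noise added at the sampled locations.  The classical
baseline reconstruction ("IFFT" / zero-filled) applies the adjoint of the
undersampled operator: unmeasured frequencies are left at zero and the
inverse transform is taken, which produces the aliased image ``x_u``.

The Fourier convention throughout is the *centered, unitary* DFT (DC
component at the grid center, orthonormal scaling), so the transform is
exactly norm-preserving and its adjoint equals its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingMask",
    "AcquisitionSpec",
    "forward_fourier",
    "inverse_fourier",
    "make_cartesian_mask",
    "simulate_acquisition",
    "simulate_multicoil_acquisition",
    "zero_fill_recon",
    "sos_combine",
]


def _check_image(x: np.ndarray, name: str = "image") -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2D, got shape {x.shape}")
    if not np.all(np.isfinite(x.view(float) if np.iscomplexobj(x) else x)):
        raise ValueError(f"{name} contains non-finite entries")
    return x.astype(np.complex128, copy=False)


def forward_fourier(x: np.ndarray) -> np.ndarray:
    """Centered, unitary 2D DFT of an image (image domain -> k-space).

    Unitarity means Parseval's equality ``||F x|| = ||x||`` holds exactly
    (up to floating point) and the inverse transform is the adjoint.
    """
    x = _check_image(x)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def inverse_fourier(k: np.ndarray) -> np.ndarray:
    """Inverse (= adjoint) of :func:`forward_fourier` (k-space -> image)."""
    k = _check_image(k, "k-space")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k), norm="ortho"))


@dataclass(frozen=True)
class SamplingMask:
    """Binary Cartesian undersampling template.

    ``mask`` is 1 where k-space is measured.  Rows are the frequency-encode
    direction (always fully sampled); columns are phase-encode lines, and
    undersampling removes whole columns.  ``sampled_set`` (the set ``C``) is
    the flat-index array of measured locations.
    """

    mask: np.ndarray
    acceleration: float
    center_fraction: float
    seed: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.acceleration < 1:
            raise ValueError("acceleration must be >= 1")

    @property
    def sampled_set(self) -> np.ndarray:
        """Flat indices of the sampled set C (row-major order)."""
        return np.flatnonzero(self.mask.ravel())

    @property
    def sampled_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def n_sampled_lines(self) -> int:
        return int(self.mask[0].sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class AcquisitionSpec:
    """Mask plus noise model for one simulated acquisition.

    ``noise_sigma`` is the standard deviation of the Gaussian noise added
    independently to the real and imaginary parts of each *sampled* k-space
    entry (so the complex noise variance is ``2 sigma^2``).
    """

    mask: SamplingMask
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def make_cartesian_mask(
    shape: tuple[int, int],
    R: float,
    center_fraction: float = 0.08,
    seed: int = 0,
) -> SamplingMask:
    """Random 1D-Cartesian line mask with a fully sampled central band.

    Keeps ``round(n_pe / R)`` of the ``n_pe`` phase-encode columns: the
    ``round(center_fraction * n_pe)`` central (low-frequency) columns are
    always kept, the remainder drawn uniformly without replacement.  The
    sampled fraction is therefore within one line of ``1/R``.
    """
    n_fe, n_pe = shape
    if R < 1:
        raise ValueError("acceleration R must be >= 1")
    if not 0 <= center_fraction < 1:
        raise ValueError("center_fraction must be in [0, 1)")

    if R == 1:
        mask = np.ones(shape, dtype=bool)
        return SamplingMask(mask, acceleration=1.0,
                            center_fraction=center_fraction, seed=seed)

    n_keep = int(round(n_pe / R))
    n_center = int(round(center_fraction * n_pe))
    if n_keep <= n_center or n_keep < 1:
        raise ValueError(
            f"acceleration R={R} leaves no lines beyond the "
            f"{n_center}-line central band ({n_keep} lines total); "
            "reduce R or center_fraction"
        )

    center_lo = n_pe // 2 - n_center // 2
    center_cols = np.arange(center_lo, center_lo + n_center)
    outside = np.setdiff1d(np.arange(n_pe), center_cols)
    rng = np.random.default_rng(seed)
    random_cols = rng.choice(outside, size=n_keep - n_center, replace=False)

    cols = np.concatenate([center_cols, random_cols])
    mask = np.zeros(shape, dtype=bool)
    mask[:, cols] = True
    return SamplingMask(mask, acceleration=float(R),
                        center_fraction=center_fraction, seed=seed)


def simulate_acquisition(x: np.ndarray, spec: AcquisitionSpec) -> np.ndarray:
    """Simulate ``y = m ⊙ (G x + i)``.

    Noise is drawn i.i.d. complex Gaussian at the sampled indices only;
    entries outside the sampled set C are exactly zero.
    """
    x = _check_image(x)
    m = spec.mask.mask
    if x.shape != m.shape:
        raise ValueError(f"image shape {x.shape} != mask shape {m.shape}")
    y = forward_fourier(x)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        n_sampled = int(m.sum())
        noise = spec.noise_sigma * (
            rng.standard_normal(n_sampled) + 1j * rng.standard_normal(n_sampled)
        )
        y[m] += noise
    y[~m] = 0.0
    return y


def simulate_multicoil_acquisition(
    x: np.ndarray,
    sensitivities,
    spec: AcquisitionSpec,
) -> list[np.ndarray]:
    """Per-coil acquisitions of a sensitivity-weighted image.

    Each coil sees ``S_c ⊙ x`` through the same mask; noise streams are
    independent across coils (sub-seeded from ``spec.seed``).
    """
    x = _check_image(x)
    maps = sensitivities.maps if hasattr(sensitivities, "maps") else sensitivities
    children = np.random.SeedSequence(spec.seed).spawn(len(maps))
    out = []
    for smap, child in zip(maps, children):
        coil_spec = AcquisitionSpec(
            mask=spec.mask,
            noise_sigma=spec.noise_sigma,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        out.append(simulate_acquisition(smap * x, coil_spec))
    return out


def zero_fill_recon(y: np.ndarray, mask: SamplingMask | None = None) -> np.ndarray:
    """Zero-filled ("IFFT") reconstruction ``x_u = G^H y``.

    The unmeasured spectrum stays at zero, so undersampling shows up as
    coherent aliasing in the image.  If ``mask`` is given, ``y`` is checked
    to vanish outside the sampled set.
    """
    y = _check_image(y, "k-space")
    if mask is not None:
        if y.shape != mask.shape:
            raise ValueError("k-space / mask shape mismatch")
        if np.any(y[~mask.mask] != 0):
            raise ValueError("k-space has nonzero entries outside the sampled set")
    return inverse_fourier(y)


def sos_combine(coil_images) -> np.ndarray:
    """Root sum-of-squares combination of multi-coil images.

    Returns the real-valued magnitude image sqrt(sum_c |x_c|^2), the
    standard way a single magnitude image is formed from coil images.
    """
    if len(coil_images) == 0:
        raise ValueError("sos_combine requires at least one coil image")
    imgs = [_check_image(c, "coil image") for c in coil_images]
    if any(c.shape != imgs[0].shape for c in imgs):
        raise ValueError("coil images must share a shape")
    stack = np.stack(imgs)
    return np.sqrt(np.sum(np.abs(stack) ** 2, axis=0))
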