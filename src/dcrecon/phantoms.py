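"""Seeded synthetic test objects for undersampled-MRI experiments.

The clinical images behind an MR reconstruction study are rarely available,
so this module generates piecewise-constant ellipse phantoms — the standard
analytically checkable MR test object — together with smooth coil
sensitivity maps and complete training/evaluation datasets (ground truth,
simulated undersampled acquisition, zero-filled input).

Two phantom styles are provided:

* ``"random"`` — a superposition of randomly placed ellipses with random
  intensities, clipped to [0, 1]; an endless family of training images.
* ``"shepp-logan"`` — the canonical Shepp-Logan head phantom with the
  modified (Toft) contrast values, whose ellipse parameter table is public
  and can be rasterized independently for verification.

All generators are deterministic under a fixed seed; datasets spawn one
independent substream per sample so sample ``i`` does not depend on how
many samples precede it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import (
    AcquisitionSpec,
    SamplingMask,
    make_cartesian_mask,
    simulate_acquisition,
    zero_fill_recon,
)

__all__ = [
    "Phantom",
    "CoilSensitivitySet",
    "TrainingSample",
    "TrainingSet",
    "SHEPP_LOGAN_ELLIPSES",
    "generate_phantom",
    "generate_coil_sensitivities",
    "make_dataset",
    "high_frequency_energy_fraction",
]

# Modified Shepp-Logan ellipse table (Toft contrast values, so intensities
# stay within [0, 1]): (additive intensity, semi-axis a (x), semi-axis b (y),
# center x0, center y0, rotation angle in degrees, counter-clockwise).
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


@dataclass(frozen=True)
class Phantom:
    """A ground-truth image: complex-valued array with magnitudes in [0, 1]."""

    image: np.ndarray
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass(frozen=True)
class CoilSensitivitySet:
    """Smooth complex coil sensitivity maps, SOS-normalized to 1 per pixel."""

    maps: tuple[np.ndarray, ...]
    seed: int

    @property
    def n_coils(self) -> int:
        return len(self.maps)

    def sos(self) -> np.ndarray:
        return np.sqrt(sum(np.abs(m) ** 2 for m in self.maps))


@dataclass(frozen=True)
class TrainingSample:
    """One (input, label) pair plus the acquisition that produced it."""

    x_gnd: np.ndarray
    x_u: np.ndarray
    kspace: np.ndarray
    mask: SamplingMask
    seed: int


@dataclass(frozen=True)
class TrainingSet:
    """A seeded collection of (zero-filled input, ground truth) pairs."""

    samples: tuple[TrainingSample, ...]
    acceleration: float
    noise_sigma: float
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(x_u, x_gnd) pairs, the training corpus proper."""
        return [(s.x_u, s.x_gnd) for s in self.samples]


def _pixel_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates on [-1, 1] x [-1, 1]; x varies along rows."""
    n_x, n_y = shape
    x = (np.arange(n_x) - (n_x - 1) / 2) / (n_x / 2)
    y = (np.arange(n_y) - (n_y - 1) / 2) / (n_y / 2)
    return np.meshgrid(x, y, indexing="ij")

def _rasterize_ellipses(shape, ellipses) -> np.ndarray:
    X, Y = _pixel_grid(shape)
    img = np.zeros(shape, dtype=float)
    for amp, a, b, x0, y0, phi_deg in ellipses:
        phi = np.deg2rad(phi_deg)
        xr = (X - x0) * np.cos(phi) + (Y - y0) * np.sin(phi)
        yr = -(X - x0) * np.sin(phi) + (Y - y0) * np.cos(phi)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += amp
    return img


def _smooth_phase_map(shape, rng, max_phase: float) -> np.ndarray:
    # low-order polynomial phase: smooth by construction
    X, Y = _pixel_grid(shape)
    c = rng.uniform(-1.0, 1.0, size=4)
    p = c[0] * X + c[1] * Y + c[2] * X * Y + c[3] * (X**2 - Y**2)
    scale = np.abs(p).max()
    return max_phase * p / scale if scale > 0 else p


def generate_phantom(
    shape: tuple[int, int],
    n_ellipses: int = 8,
    seed: int = 0,
    mode: str = "random",
    smooth_phase: bool = False,
    max_phase: float = np.pi / 4,
) -> Phantom:
    """Generate a piecewise-constant ellipse phantom.

    Parameters
    ----------
    shape
        Image dimensions; each side must be at least 16 pixels.
    n_ellipses
        Number of random ellipses (ignored in ``"shepp-logan"`` mode).
    seed
        Seeds ellipse placement and the optional phase map.
    mode
        ``"random"`` or ``"shepp-logan"`` (canonical table above).
    smooth_phase
        If true, multiply by ``exp(i * phase)`` with a smooth low-order
        polynomial phase map, so the phantom exercises complex-valued code
        paths the way real acquisitions do.  Magnitudes are unchanged.
    """
    n_x, n_y = shape
    if n_x < 16 or n_y < 16:
        raise ValueError(f"phantom shape must be >= 16 px per side, got {shape}")
    rng = np.random.default_rng(seed)

    if mode == "shepp-logan":
        img = _rasterize_ellipses(shape, SHEPP_LOGAN_ELLIPSES)
    elif mode == "random":
        if n_ellipses < 1:
            raise ValueError("n_ellipses must be >= 1")
        ellipses = []
        for _ in range(n_ellipses):
            amp = rng.uniform(-0.5, 1.0)
            a = rng.uniform(0.08, 0.45)
            b = rng.uniform(0.08, 0.45)
            x0, y0 = rng.uniform(-0.65, 0.65, size=2)
            phi = rng.uniform(0.0, 180.0)
            ellipses.append((amp, a, b, x0, y0, phi))
        img = _rasterize_ellipses(shape, ellipses)
    else:
        raise ValueError(f"unknown phantom mode {mode!r}")

    img = np.clip(img, 0.0, 1.0)
    out = img.astype(np.complex128)
    if smooth_phase:
        out = out * np.exp(1j * _smooth_phase_map(shape, rng, max_phase))
    return Phantom(image=out, seed=seed)


def generate_coil_sensitivities(
    shape: tuple[int, int],
    n_coils: int,
    seed: int = 0,
    max_mode: int = 2,
) -> CoilSensitivitySet:
    """Smooth complex sensitivity maps, SOS-normalized to 1 per pixel.

    Each coil is synthesized from Fourier modes with at most ``max_mode``
    cycles across the field of view (random complex coefficients, decaying
    with spatial frequency, plus a dominant uniform term that keeps the
    sum-of-squares bounded away from zero).  Building the maps in a
    strictly low-frequency basis makes them bandlimited by construction —
    the smoothness contract (< 1% spectral energy above a quarter of the
    Nyquist radius) holds with orders of magnitude to spare, division by
    the SOS included.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    rng = np.random.default_rng(seed)
    n_x, n_y = shape
    X, Y = np.meshgrid(np.arange(n_x) / n_x, np.arange(n_y) / n_y, indexing="ij")

    maps = []
    for _ in range(n_coils):
        g = np.full(shape, 3.0 + 0j)
        for fx in range(-max_mode, max_mode + 1):
            for fy in range(-max_mode, max_mode + 1):
                if fx == 0 and fy == 0:
                    continue
                weight = np.exp(-(fx**2 + fy**2) / 2.0)
                coef = weight * (rng.standard_normal() + 1j * rng.standard_normal())
                g = g + coef * np.exp(2j * np.pi * (fx * X + fy * Y))
        maps.append(g)

    sos = np.sqrt(sum(np.abs(m) ** 2 for m in maps))
    maps = tuple(m / sos for m in maps)
    return CoilSensitivitySet(maps=maps, seed=seed)


def high_frequency_energy_fraction(arr: np.ndarray, cutoff: float = 0.25) -> float:
    """Fraction of spectral energy above ``cutoff`` × Nyquist radius.

    The smoothness oracle for sensitivity maps: a map is accepted as smooth
    when this fraction is below 1%.
    """
    from .encoding import forward_fourier

    k = forward_fourier(np.asarray(arr, dtype=np.complex128))
    n_x, n_y = arr.shape
    fx = (np.arange(n_x) - n_x // 2) / (n_x / 2)
    fy = (np.arange(n_y) - n_y // 2) / (n_y / 2)
    FX, FY = np.meshgrid(fx, fy, indexing="ij")
    radius = np.sqrt(FX**2 + FY**2)
    energy = np.abs(k) ** 2
    return float(energy[radius > cutoff].sum() / energy.sum())


def make_dataset(
    n: int,
    shape: tuple[int, int] = (64, 64),
    R: float = 4.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_ellipses: int = 8,
    center_fraction: float = 0.08,
    mode: str = "random",
    smooth_phase: bool = False,
) -> TrainingSet:
    """Build ``n`` (zero-filled input, ground truth) training pairs.

    Every sample draws its own phantom, mask and noise stream from an
    independent substream of the master seed, then simulates the
    acquisition and zero-fills it:

        x_u = G^H [ m ⊙ (G x_gnd + noise) ]

    At ``R=1`` with ``noise_sigma=0`` this is the identity (x_u == x_gnd).
    """
    if n < 1:
        raise ValueError("dataset size n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    samples = []
    for child in children:
        s_phantom, s_mask, s_noise = (int(v) for v in child.generate_state(3) % (2**31))
        ph = generate_phantom(shape, n_ellipses=n_ellipses, seed=s_phantom,
                              mode=mode, smooth_phase=smooth_phase)
        mask = make_cartesian_mask(shape, R=R, center_fraction=center_fraction,
                                   seed=s_mask)
        spec = AcquisitionSpec(mask=mask, noise_sigma=noise_sigma, seed=s_noise)
        y = simulate_acquisition(ph.image, spec)
        x_u = zero_fill_recon(y, mask)
        samples.append(TrainingSample(x_gnd=ph.image, x_u=x_u, kspace=y,
                                      mask=mask, seed=s_phantom))
    return TrainingSet(samples=tuple(samples), acceleration=float(R),
                       noise_sigma=float(noise_sigma), seed=seed)
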