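"""Reconstruction-quality metrics and the method × acceleration grid.

Three standard measures compare a reconstruction against its ground truth,
all computed on magnitude images:

* **NMSE** — normalized mean square error ``||ref − est||² / ||ref||²``
  (lower is better; 0 for a perfect reconstruction, 1 for an all-zero one).
* **PSNR** — peak signal-to-noise ratio ``10 log10(peak² / MSE)`` in dB
  with ``peak = max |ref|`` (higher is better; infinite when MSE = 0,
  reported as ``inf``).
* **SSIM** — mean structural similarity over a Gaussian-weighted sliding
  window (σ = 1.5, K1 = 0.01, K2 = 0.03, the conventional settings),
  in [−1, 1], higher is better.

:func:`evaluate_grid` runs a set of reconstruction methods (the IFFT
zero-filled baseline and the trained CNN variants with and without the
data-consistency layer) over a test set at several acceleration factors
and reports the mean metrics per (method, R) row — the shape of a standard
undersampled-reconstruction results table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .encoding import AcquisitionSpec, make_cartesian_mask, simulate_acquisition, zero_fill_recon
from .model import NetworkConfig, NetworkParams, forward_reconstruct

__all__ = [
    "MetricsRecord",
    "nmse",
    "psnr",
    "ssim",
    "evaluate_grid",
]

METHODS = ("IFFT", "CNN_DC", "CNN_NDC")


@dataclass(frozen=True)
class MetricsRecord:
    """One row of the results grid: a method at one acceleration factor."""

    method: str
    acceleration: float
    psnr_db: float
    nmse: float
    ssim: float
    n_images: int

    def __post_init__(self) -> None:
        if self.nmse < 0:
            raise ValueError("nmse must be >= 0")
        if not -1.0 - 1e-12 <= self.ssim <= 1.0 + 1e-12:
            raise ValueError("ssim must lie in [-1, 1]")


def _magnitudes(ref, est):
    ref = np.asarray(ref)
    est = np.asarray(est)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {est.shape}")
    return np.abs(ref).astype(float), np.abs(est).astype(float)


def nmse(ref: np.ndarray, est: np.ndarray) -> float:
    """Normalized mean square error ``||ref − est||² / ||ref||²``.

    Computed on the complex difference, so it is invariant to a common
    rescaling of both images but sensitive to phase errors.
    """
    ref = np.asarray(ref, dtype=np.complex128)
    est = np.asarray(est, dtype=np.complex128)
    if ref.shape != est.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {est.shape}")
    denom = np.sum(np.abs(ref) ** 2)
    if denom == 0:
        raise ValueError("nmse undefined for an all-zero reference")
    return float(np.sum(np.abs(ref - est) ** 2) / denom)


def psnr(ref: np.ndarray, est: np.ndarray) -> float:
    """Peak SNR in dB, peak taken from the reference magnitude.

    Returns ``inf`` for an exact reconstruction (zero MSE); computed on
    magnitude images, hence invariant to a global phase factor.
    """
    ref_m, est_m = _magnitudes(ref, est)
    mse = float(np.mean((ref_m - est_m) ** 2))
    peak = float(ref_m.max())
    if mse == 0.0:
        return float("inf")
    if peak == 0.0:
        raise ValueError("psnr undefined for an all-zero reference")
    return float(10.0 * np.log10(peak**2 / mse))


def ssim(
    ref: np.ndarray,
    est: np.ndarray,
    window_sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Mean structural similarity on magnitude images.

    Gaussian sliding window (std ``window_sigma``, truncated at 3.5 σ, the
    conventional 11×11 support for σ = 1.5), population moments, and the
    usual stabilizers ``C1 = (k1 L)²``, ``C2 = (k2 L)²`` with ``L`` the
    reference's dynamic range (max − min of the magnitude, unless given).
    The local map is averaged after cropping the half-window border, where
    the windowed moments are edge-contaminated.
    """
    ref_m, est_m = _magnitudes(ref, est)
    truncate = 3.5
    radius = int(truncate * window_sigma + 0.5)
    win_size = 2 * radius + 1
    if min(ref_m.shape) < win_size:
        raise ValueError(
            f"image {ref_m.shape} smaller than the {win_size}px SSIM window"
        )
    if data_range is None:
        data_range = float(ref_m.max() - ref_m.min())
        if data_range == 0:
            raise ValueError("reference has zero dynamic range; pass data_range")

    filt = lambda a: gaussian_filter(a, sigma=window_sigma, truncate=truncate)
    ux, uy = filt(ref_m), filt(est_m)
    uxx, uyy, uxy = filt(ref_m * ref_m), filt(est_m * est_m), filt(ref_m * est_m)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    pad = radius
    return float(s[pad:-pad, pad:-pad].mean())


def evaluate_grid(
    methods,
    accelerations,
    test_phantoms,
    trained_params: dict | None = None,
    noise_sigma: float = 0.0,
    center_fraction: float = 0.08,
    seed: int = 0,
    out_csv=None,
) -> pd.DataFrame:
    """Mean PSNR/NMSE/SSIM per (method, acceleration) over a test set.

    Parameters
    ----------
    methods
        Subset of ``("IFFT", "CNN_DC", "CNN_NDC")``.
    accelerations
        Acceleration factors R to test, e.g. ``(2, 4, 6)``.
    test_phantoms
        Ground-truth complex images (or ``Phantom`` objects).
    trained_params
        ``{(method, R): (NetworkParams, NetworkConfig)}`` for the CNN
        methods; the IFFT baseline needs none.
    seed
        Seeds the per-image mask and noise substreams; masks are redrawn
        per image so the grid measures the method, not one mask.

    Returns a DataFrame with columns method, acceleration, psnr_db, nmse,
    ssim, n_images (one row per method × R), optionally written to CSV.
    """
    trained_params = trained_params or {}
    for mth in methods:
        if mth not in METHODS:
            raise ValueError(f"unknown method {mth!r}; expected one of {METHODS}")
        if mth != "IFFT":
            for R in accelerations:
                if (mth, R) not in trained_params:
                    raise ValueError(f"no trained parameters for ({mth}, R={R})")

    images = [
        np.asarray(getattr(p, "image", p), dtype=np.complex128)
        for p in test_phantoms
    ]
    rows = []
    for R in accelerations:
        # one acquisition per image, shared by all methods at this R
        children = np.random.SeedSequence((seed, int(R * 1000))).spawn(len(images))
        acqs = []
        for img, child in zip(images, children):
            s_mask, s_noise = (int(v) for v in child.generate_state(2) % (2**31))
            mask = make_cartesian_mask(img.shape, R=R,
                                       center_fraction=center_fraction, seed=s_mask)
            y = simulate_acquisition(
                img, AcquisitionSpec(mask=mask, noise_sigma=noise_sigma, seed=s_noise)
            )
            acqs.append((img, mask, y, zero_fill_recon(y, mask)))

        for mth in methods:
            vals = {"psnr_db": [], "nmse": [], "ssim": []}
            for img, mask, y, x_u in acqs:
                if mth == "IFFT":
                    rec = x_u
                else:
                    params, cfg = trained_params[(mth, R)]
                    rec = forward_reconstruct(x_u, params, cfg, y=y, mask=mask)
                vals["psnr_db"].append(psnr(img, rec))
                vals["nmse"].append(nmse(img, rec))
                vals["ssim"].append(ssim(img, rec))
            rows.append(
                MetricsRecord(
                    method=mth,
                    acceleration=float(R),
                    psnr_db=float(np.mean(vals["psnr_db"])),
                    nmse=float(np.mean(vals["nmse"])),
                    ssim=float(np.mean(vals["ssim"])),
                    n_images=len(images),
                )
            )

    df = pd.DataFrame([r.__dict__ for r in rows])
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
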