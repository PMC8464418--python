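"""The k-space data-consistency operator and its dense verification oracle.

A CNN de-aliasing step is free to alter every frequency of its input,
including the ones that were actually measured.  The data-consistency (DC)
step pulls the predicted spectrum back toward the measurements by solving
the regularized least-squares condition

    (I + λ G_u^H G_u) x = x_cnn + λ G_u^H y

where ``G_u = m G`` is the undersampled Fourier operator and λ weighs the
measurements against the CNN prediction (large λ for low-noise data).
Because ``G`` is unitary and ``m`` is diagonal, the normal operator is
diagonal in the frequency domain and the solution is a per-index blend:

    Y_i = (T_cnn(i) + λ T_0(i)) / (1 + λ)   for i in C (sampled),
    Y_i = T_cnn(i)                          for i not in C,

with ``T_cnn = G x_cnn`` the predicted spectrum and ``T_0 = y`` the
observed zero-filled spectrum.  The λ → ∞ limit (``lam=np.inf``) replaces
the sampled entries outright — the right choice for noiseless data.

:func:`dc_least_squares_oracle` solves the same system by explicit dense
linear algebra and exists solely so the closed form can be verified against
an independent computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import SamplingMask, forward_fourier, inverse_fourier

__all__ = [
    "DCParams",
    "apply_data_consistency",
    "dc_image_update",
    "dc_least_squares_oracle",
]


@dataclass(frozen=True)
class DCParams:
    """λ and the sampled set for one data-consistency application.

    ``lam`` is non-negative; ``np.inf`` selects hard replacement of the
    sampled entries (exact consistency, appropriate when noise_sigma = 0).
    """

    lam: float
    mask: SamplingMask

    def __post_init__(self) -> None:
        if not (self.lam >= 0):  # also rejects nan
            raise ValueError(f"lambda must be >= 0 or inf, got {self.lam}")


def apply_data_consistency(
    T_cnn: np.ndarray, T_0: np.ndarray, params: DCParams
) -> np.ndarray:
    """Per-frequency blend of predicted and observed spectra.

    On the sampled set C the output is the convex combination
    ``(T_cnn + λ T_0) / (1 + λ)``; elsewhere the prediction passes through
    untouched.
    """
    T_cnn = np.asarray(T_cnn, dtype=np.complex128)
    T_0 = np.asarray(T_0, dtype=np.complex128)
    m = params.mask.mask
    if T_cnn.shape != T_0.shape or T_cnn.shape != m.shape:
        raise ValueError(
            f"shape mismatch: T_cnn {T_cnn.shape}, T_0 {T_0.shape}, mask {m.shape}"
        )
    out = T_cnn.copy()
    if np.isinf(params.lam):
        out[m] = T_0[m]
    elif params.lam > 0:
        out[m] = (T_cnn[m] + params.lam * T_0[m]) / (1.0 + params.lam)
    return out


def dc_image_update(
    x_cnn: np.ndarray, y: np.ndarray, params: DCParams
) -> np.ndarray:
    """Image-domain data-consistency update ``G^H blend(G x_cnn, y)``."""
    T_cnn = forward_fourier(x_cnn)
    Y = apply_data_consistency(T_cnn, y, params)
    return inverse_fourier(Y)


def _dense_fourier_matrix(shape: tuple[int, int]) -> np.ndarray:
    """Dense matrix of the centered unitary 2D DFT acting on vec(x)."""
    n_x, n_y = shape
    n = n_x * n_y
    G = np.empty((n, n), dtype=np.complex128)
    basis = np.zeros(n, dtype=np.complex128)
    for j in range(n):
        basis[j] = 1.0
        G[:, j] = forward_fourier(basis.reshape(shape)).ravel()
        basis[j] = 0.0
    return G


def dc_least_squares_oracle(
    x_cnn: np.ndarray, y: np.ndarray, params: DCParams
) -> np.ndarray:
    """Solve the data-consistency normal equations by dense linear algebra.

    Builds ``G_u = M G`` explicitly (n × n with n = n_x · n_y; keep images
    small) and solves ``(I + λ G_u^H G_u) x = x_cnn + λ G_u^H y``.  The
    λ = ∞ limit is handled as the constrained problem: sampled frequencies
    equal the observations, unsampled ones equal the prediction's.
    """
    x_cnn = np.asarray(x_cnn, dtype=np.complex128)
    y = np.asarray(y, dtype=np.complex128)
    shape = x_cnn.shape
    n = shape[0] * shape[1]
    if n > 256:
        raise ValueError("dense oracle is meant for tiny images (n <= 256)")
    G = _dense_fourier_matrix(shape)
    M = np.diag(params.mask.mask.ravel().astype(float))
    Gu = M @ G

    if np.isinf(params.lam):
        # constrained limit, expressed in the frequency domain
        K = G @ x_cnn.ravel()
        K[params.mask.mask.ravel()] = y.ravel()[params.mask.mask.ravel()]
        return (G.conj().T @ K).reshape(shape)

    A = np.eye(n) + params.lam * (Gu.conj().T @ Gu)
    b = x_cnn.ravel() + params.lam * (Gu.conj().T @ y.ravel())
    return np.linalg.solve(A, b).reshape(shape)
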