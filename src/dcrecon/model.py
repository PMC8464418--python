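"""The de-aliasing reconstruction network and its training loop.

The network ``g_cnn`` maps a zero-filled (aliased) reconstruction ``x_u``
to a de-aliased image.  Architecture: an input layer, three convolutional
layers with ReLU activations between them, and a linear output layer.  Two
variants are distinguished throughout the package:

* **CNN_DC** — the CNN followed by the k-space data-consistency layer of
  :mod:`dcrecon.dc`, so the output's spectrum is blended with (λ < ∞) or
  replaced by (λ = ∞) the measured samples.
* **CNN_NDC** — the bare CNN, no k-space correction.

Complex images are handled as two real channels (real, imaginary).  In
multi-coil mode the input is the 2·n_coils-channel zero-filled block, the
DC layer acts per coil, and the coil outputs are combined by root
sum-of-squares into the single-channel magnitude image that serves as the
training label.

Training minimizes the mean squared error between the reconstruction and
the ground truth over the training pairs ``(x_u, x_gnd)`` by Adam.  The
whole stack — convolutions, ReLU, the DC layer (linear, hence
self-adjoint up to the frequency-domain diagonal) and the SOS combination
— carries hand-derived analytic gradients.  Training runs in float32 by
default (the usual choice for conv nets); switching ``TrainConfig.dtype``
to float64 lets the gradients be validated against central finite
differences to ~1e-7 relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .dc import DCParams, dc_image_update
from .encoding import SamplingMask

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "TrainConfig",
    "TrainResult",
    "TrainingDivergedError",
    "build_network",
    "parameter_count",
    "forward_reconstruct",
    "forward_reconstruct_multicoil",
    "mse_loss",
    "loss_and_gradients",
    "train",
]

_ACTIVATIONS = ("relu", "tanh", "identity")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and DC-layer settings of the reconstruction network.

    ``lam`` is the data-consistency weight λ; ``np.inf`` enforces exact
    agreement with the measured k-space samples (noiseless regime) and a
    finite value blends prediction and measurement (noisy regime).
    """

    n_conv_layers: int = 3
    channels_per_layer: int = 32
    kernel_size: int = 3
    activation: str = "relu"
    residual: bool = True
    use_dc: bool = True
    lam: float = np.inf
    in_channels: int = 2
    out_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_layers < 1:
            raise ValueError("n_conv_layers must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.channels_per_layer < 1:
            raise ValueError("channels_per_layer must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        if not (self.lam >= 0):
            raise ValueError("lam must be >= 0 or inf")
        if self.residual and self.in_channels != self.out_channels:
            raise ValueError("residual mode needs in_channels == out_channels")

    @property
    def layer_channels(self) -> list[tuple[int, int]]:
        """(c_in, c_out) per convolutional layer."""
        sizes = (
            [self.in_channels]
            + [self.channels_per_layer] * (self.n_conv_layers - 1)
            + [self.out_channels]
        )
        return list(zip(sizes[:-1], sizes[1:]))


@dataclass
class NetworkParams:
    """Convolution weights and biases, ordered input -> output layer."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights],
                             [b.copy() for b in self.biases])

    def flat(self) -> np.ndarray:
        return np.concatenate(
            [a.ravel() for pair in zip(self.weights, self.biases) for a in pair]
        )


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")


@dataclass
class TrainResult:
    params: NetworkParams
    loss_trace: list[float]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite; carries the epoch."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


def build_network(config: NetworkConfig) -> NetworkParams:
    """He-initialized parameters, deterministic under ``config.seed``.

    In residual mode the output layer starts at zero, so the freshly built
    network is exactly the identity map: training starts from the
    zero-filled input rather than from a random perturbation of it, and an
    already-perfect input (full sampling) yields zero initial loss.
    """
    rng = np.random.default_rng(config.seed)
    k = config.kernel_size
    weights, biases = [], []
    n_layers = len(config.layer_channels)
    for i, (c_in, c_out) in enumerate(config.layer_channels):
        std = np.sqrt(2.0 / (k * k * c_in))
        w = rng.normal(0.0, std, size=(c_out, c_in, k, k))
        if config.residual and i == n_layers - 1:
            w = np.zeros_like(w)
        weights.append(w)
        biases.append(np.zeros(c_out))
    return NetworkParams(weights, biases)


def parameter_count(config: NetworkConfig) -> int:
    k = config.kernel_size
    return sum(k * k * ci * co + co for ci, co in config.layer_channels)


# ---------------------------------------------------------------- conv core

def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """'Same'-padded 2D cross-correlation, accumulated over kernel offsets.

    x: (N, C, H, W);  W: (O, C, k, k).  One channel-mixing tensordot per
    kernel offset keeps the working set small (no im2col blow-up), which
    is what makes single-core training on 64×64 images cheap.  Returns
    (out, xp) with the padded input kept for the backward pass.
    """
    n, c, h, w = x.shape
    k = W.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    acc = None
    for di in range(k):
        for dj in range(k):
            contrib = np.tensordot(
                W[:, :, di, dj], xp[:, :, di:di + h, dj:dj + w], axes=([1], [1])
            )  # (O, N, H, W)
            acc = contrib if acc is None else acc + contrib
    out = acc.transpose(1, 0, 2, 3) + b[None, :, None, None].astype(x.dtype)
    return out, xp


def _conv2d_backward(dout: np.ndarray, xp: np.ndarray, W: np.ndarray):
    """Gradients of _conv2d w.r.t. (x, W, b) given upstream dout (N,O,H,W)."""
    n, o, h, w = dout.shape
    c, k = W.shape[1], W.shape[-1]
    dW = np.empty_like(W)
    for di in range(k):
        for dj in range(k):
            dW[:, :, di, dj] = np.tensordot(
                dout, xp[:, :, di:di + h, dj:dj + w], axes=([0, 2, 3], [0, 2, 3])
            )
    db = dout.sum(axis=(0, 2, 3))
    # gradient w.r.t. the input: correlate dout with the flipped, transposed kernel
    Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
    dx, _ = _conv2d(dout, Wt, np.zeros(c, dtype=W.dtype))
    return dx, dW, db


def _activate(z: np.ndarray, kind: str):
    if kind == "relu":
        a = np.maximum(z, 0.0)
        return a, (z > 0)
    if kind == "tanh":
        a = np.tanh(z)
        return a, 1.0 - a * a
    return z, None  # identity


def _activate_backward(da: np.ndarray, grad_factor, kind: str) -> np.ndarray:
    if kind == "identity":
        return da
    return da * grad_factor


def _cnn_forward(x: np.ndarray, params: NetworkParams, config: NetworkConfig):
    """Forward pass on (N, C, H, W); returns output and the backward cache."""
    cache = []
    a = x
    last = len(params.weights) - 1
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        z, xp = _conv2d(a, W, b)
        if i < last:
            a_next, gf = _activate(z, config.activation)
        else:
            a_next, gf = z, None  # linear output layer
        cache.append((xp, gf))
        a = a_next
    out = x + a if config.residual else a
    return out, cache


def _cnn_backward(dout: np.ndarray, cache, params: NetworkParams,
                  config: NetworkConfig):
    """Backprop through the conv stack; returns (dx, grads)."""
    grads_W = [None] * len(params.weights)
    grads_b = [None] * len(params.biases)
    da = dout
    last = len(params.weights) - 1
    for i in range(last, -1, -1):
        xp, gf = cache[i]
        if i < last:
            da = _activate_backward(da, gf, config.activation)
        da, grads_W[i], grads_b[i] = _conv2d_backward(da, xp, params.weights[i])
    dx = da + dout if config.residual else da
    return dx, NetworkParams(grads_W, grads_b)


# ------------------------------------------------- complex <-> channel glue

def _to_channels(x: np.ndarray) -> np.ndarray:
    """(N, H, W) complex -> (N, 2, H, W) real."""
    return np.stack([x.real, x.imag], axis=1)


def _to_complex(x2: np.ndarray) -> np.ndarray:
    """(N, 2, H, W) real -> (N, H, W) complex."""
    return x2[:, 0] + 1j * x2[:, 1]


def _fft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def _ifft2c(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def _dc_batch(x: np.ndarray, ys: np.ndarray, masks: np.ndarray,
              lam: float) -> np.ndarray:
    """Batched data-consistency blend on (N, H, W) complex images."""
    K = _fft2c(x)
    if np.isinf(lam):
        K = np.where(masks, ys, K)
    elif lam > 0:
        K = np.where(masks, (K + lam * ys) / (1.0 + lam), K)
    return _ifft2c(K)


def _dc_batch_backward(dx: np.ndarray, masks: np.ndarray, lam: float) -> np.ndarray:
    """Adjoint of the (real-linear) DC map: same diagonal, zero data term."""
    zeros = np.zeros_like(dx)
    return _dc_batch(dx, zeros, masks, lam)


# ----------------------------------------------------------- public forward

def forward_reconstruct(
    x_u: np.ndarray,
    params: NetworkParams,
    config: NetworkConfig,
    y: np.ndarray | None = None,
    mask: SamplingMask | None = None,
) -> np.ndarray:
    """Reconstruct a single complex image from its zero-filled input.

    With ``config.use_dc`` the measured spectrum ``y`` and its mask are
    required and the CNN output passes through the data-consistency layer;
    without it (CNN_NDC) the bare CNN output is returned.
    """
    if config.use_dc and (y is None or mask is None):
        raise ValueError("use_dc=True requires the measured k-space y and its mask")
    x2 = _to_channels(np.asarray(x_u, dtype=np.complex128)[None])
    out2, _ = _cnn_forward(x2, params, config)
    x_cnn = _to_complex(out2)[0]
    if config.use_dc:
        return dc_image_update(x_cnn, y, DCParams(lam=config.lam, mask=mask))
    return x_cnn


def forward_reconstruct_multicoil(
    x_u_coils,
    params: NetworkParams,
    config: NetworkConfig,
    y_coils=None,
    mask: SamplingMask | None = None,
) -> np.ndarray:
    """Multi-coil reconstruction: coil block in, SOS magnitude image out.

    The zero-filled coil images enter as a 2·n_coils-channel block, the
    network predicts per-coil corrections, data consistency applies per
    coil, and the result is the root-sum-of-squares magnitude image.
    """
    x_u_coils = [np.asarray(c, dtype=np.complex128) for c in x_u_coils]
    n_coils = len(x_u_coils)
    if config.in_channels != 2 * n_coils:
        raise ValueError(
            f"config.in_channels={config.in_channels} but {n_coils} coils given"
        )
    if config.use_dc and (y_coils is None or mask is None):
        raise ValueError("use_dc=True requires per-coil k-space and the mask")
    block = np.concatenate([_to_channels(c[None]) for c in x_u_coils], axis=1)
    out2, _ = _cnn_forward(block, params, config)
    coil_out = [out2[:, 2 * i] + 1j * out2[:, 2 * i + 1] for i in range(n_coils)]
    if config.use_dc:
        dcp = DCParams(lam=config.lam, mask=mask)
        coil_out = [
            dc_image_update(c[0], y, dcp)[None]
            for c, y in zip(coil_out, y_coils)
        ]
    return np.sqrt(sum(np.abs(c[0]) ** 2 for c in coil_out))


def mse_loss(x_gnd: np.ndarray, x_cnn: np.ndarray) -> float:
    """Mean squared error ``||x_gnd - x_cnn||² / n_pixels``.

    For complex images the squared magnitude of the difference is summed
    (real and imaginary parts both contribute), then divided by the pixel
    count.  With the sum convention of the raw squared norm in mind, this
    differs only by the constant factor ``1/n``; the mean makes learning
    rates transferable across image sizes.
    """
    x_gnd = np.asarray(x_gnd)
    x_cnn = np.asarray(x_cnn)
    if x_gnd.shape != x_cnn.shape:
        raise ValueError(f"shape mismatch {x_gnd.shape} vs {x_cnn.shape}")
    diff = x_gnd - x_cnn
    return float(np.sum(np.abs(diff) ** 2) / x_gnd.size)


# ------------------------------------------------------------------ training

def loss_and_gradients(
    params: NetworkParams,
    config: NetworkConfig,
    x_u: np.ndarray,
    x_gnd: np.ndarray,
    ys: np.ndarray | None = None,
    masks: np.ndarray | None = None,
):
    """Batch loss and analytic parameter gradients.

    ``x_u``/``x_gnd``: (N, H, W) complex; ``ys``/``masks``: (N, H, W)
    (required when ``config.use_dc``).  The loss is the mean over the batch
    of the per-image :func:`mse_loss`.
    """
    n, h, w = x_u.shape
    x2 = _to_channels(x_u)
    out2, cache = _cnn_forward(x2, params, config)
    x_cnn = _to_complex(out2)
    if config.use_dc:
        if ys is None or masks is None:
            raise ValueError("use_dc=True requires ys and masks")
        x_rec = _dc_batch(x_cnn, ys, masks, config.lam)
    else:
        x_rec = x_cnn

    diff = x_rec - x_gnd
    loss = float(np.sum(np.abs(diff) ** 2) / (n * h * w))

    dl = 2.0 * diff / (n * h * w)  # d loss / d x_rec (complex, Wirtinger-free:
    # the map is treated as real-linear on (re, im) channels)
    if config.use_dc:
        dl = _dc_batch_backward(dl, masks, config.lam)
    dout2 = _to_channels(dl)
    _, grads = _cnn_backward(dout2, cache, params, config)
    return loss, grads


def _stack_training_set(data):
    x_u = np.stack([s.x_u for s in data.samples])
    x_gnd = np.stack([s.x_gnd for s in data.samples])
    ys = np.stack([s.kspace for s in data.samples])
    masks = np.stack([s.mask.mask for s in data.samples])
    return x_u, x_gnd, ys, masks


def train(
    data,
    net_config: NetworkConfig,
    train_config: TrainConfig,
) -> TrainResult:
    """Fit the network to a :class:`~dcrecon.phantoms.TrainingSet`.

    Minimizes the summed (mean-normalized) MSE over the training pairs by
    minibatch Adam (or plain SGD).  Fully deterministic under the two
    seeds: ``net_config.seed`` fixes the initialization, and
    ``train_config.seed`` fixes the minibatch shuffling.  Returns the final
    parameters with the per-epoch mean loss trace.
    """
    if len(data.samples) == 0:
        raise ValueError("training set is empty")
    dtype = np.dtype(train_config.dtype)
    cdtype = np.complex64 if dtype == np.float32 else np.complex128
    params = build_network(net_config)
    params = NetworkParams([w.astype(dtype) for w in params.weights],
                           [b.astype(dtype) for b in params.biases])
    x_u, x_gnd, ys, masks = _stack_training_set(data)
    x_u, x_gnd, ys = (a.astype(cdtype) for a in (x_u, x_gnd, ys))
    n = x_u.shape[0]
    rng = np.random.default_rng(train_config.seed)

    lr = train_config.learning_rate
    adam = train_config.optimizer == "adam"
    if adam:
        m = NetworkParams([np.zeros_like(w) for w in params.weights],
                          [np.zeros_like(b) for b in params.biases])
        v = NetworkParams([np.zeros_like(w) for w in params.weights],
                          [np.zeros_like(b) for b in params.biases])
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

    trace: list[float] = []
    for epoch in range(train_config.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = perm[start:start + train_config.batch_size]
            loss, grads = loss_and_gradients(
                params, net_config, x_u[idx], x_gnd[idx],
                ys[idx] if net_config.use_dc else None,
                masks[idx] if net_config.use_dc else None,
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            epoch_losses.append(loss)
            if adam:
                t += 1
                for gs, ps, ms, vs in (
                    (grads.weights, params.weights, m.weights, v.weights),
                    (grads.biases, params.biases, m.biases, v.biases),
                ):
                    for i, g in enumerate(gs):
                        ms[i] = beta1 * ms[i] + (1 - beta1) * g
                        vs[i] = beta2 * vs[i] + (1 - beta2) * g * g
                        mhat = ms[i] / (1 - beta1**t)
                        vhat = vs[i] / (1 - beta2**t)
                        ps[i] -= lr * mhat / (np.sqrt(vhat) + eps)
            else:
                for gs, ps in ((grads.weights, params.weights),
                               (grads.biases, params.biases)):
                    for i, g in enumerate(gs):
                        ps[i] -= lr * g
        trace.append(float(np.mean(epoch_losses)))
    return TrainResult(params=params, loss_trace=trace)
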