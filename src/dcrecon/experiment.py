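"""End-to-end reconstruction experiments: simulate → train → evaluate.

Ties the package together into the standard study template: for each
acceleration factor R, train the de-aliasing network in its two variants
(with and without the data-consistency layer) on a seeded phantom corpus,
then score IFFT / CNN_DC / CNN_NDC on held-out phantoms with PSNR, NMSE
and SSIM.  The result is the familiar method × acceleration grid.

Every run is fully described by an :class:`ExperimentConfig`, which
round-trips through JSON so a results table can always be regenerated from
the config stored next to it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import evaluate_grid
from .model import NetworkConfig, TrainConfig, TrainResult, train
from .phantoms import generate_phantom, make_dataset

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one reconstruction experiment.

    The defaults are the package's study conditions: 50 random-ellipse
    64×64 training phantoms and 20 held-out ones, noiseless acquisitions
    at R = 2, 4, 6 with an 8%-of-lines fully sampled center band, the
    3-layer/32-channel residual network, and ~210 Adam steps per variant
    (30 epochs of 50 samples in batches of 8).
    """

    shape: tuple[int, int] = (64, 64)
    n_train: int = 50
    n_test: int = 20
    n_ellipses: int = 8
    accelerations: tuple[float, ...] = (2.0, 4.0, 6.0)
    center_fraction: float = 0.08
    noise_sigma: float = 0.0
    methods: tuple[str, ...] = ("IFFT", "CNN_DC", "CNN_NDC")
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        if np.isinf(d["network"]["lam"]):
            d["network"]["lam"] = "inf"
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, blob: str) -> "ExperimentConfig":
        d = json.loads(blob)
        net = d.pop("network", {})
        if net.get("lam") == "inf":
            net["lam"] = np.inf
        tr = d.pop("training", {})
        d["shape"] = tuple(d.get("shape", (64, 64)))
        d["accelerations"] = tuple(d.get("accelerations", (2.0, 4.0, 6.0)))
        d["methods"] = tuple(d.get("methods", ("IFFT", "CNN_DC", "CNN_NDC")))
        return cls(network=NetworkConfig(**net), training=TrainConfig(**tr), **d)

    def with_seed(self, seed: int) -> "ExperimentConfig":
        """Re-seed every stream (data, init, shuffling) from one master seed."""
        ss = np.random.SeedSequence(seed)
        s_data, s_net, s_train = (int(v) for v in ss.generate_state(3) % (2**31))
        return replace(
            self,
            seed=s_data,
            network=replace(self.network, seed=s_net),
            training=replace(self.training, seed=s_train),
        )


@dataclass
class ExperimentResult:
    grid: pd.DataFrame
    params_by: dict
    traces: dict
    config: ExperimentConfig


def _variant_config(network: NetworkConfig, variant: str) -> NetworkConfig:
    if variant == "CNN_DC":
        return replace(network, use_dc=True)
    if variant == "CNN_NDC":
        return replace(network, use_dc=False)
    raise ValueError(f"unknown CNN variant {variant!r}")


def run_experiment(config: ExperimentConfig, verbose: bool = False) -> ExperimentResult:
    """Run the full study grid described by ``config``.

    Per acceleration factor, a fresh training set is simulated and each
    requested CNN variant is trained on it (the zero-filled baseline needs
    no training).  All methods are then evaluated on the same held-out
    phantoms and acquisitions.  Deterministic: the config's seeds fix the
    phantoms, masks, noise, initialization and minibatch order.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(2 + len(config.accelerations)) % (2**31)
    test_seed = int(seeds[0])

    cnn_variants = [m for m in config.methods if m != "IFFT"]
    params_by, traces = {}, {}
    for i, R in enumerate(config.accelerations):
        data_seed = int(seeds[2 + i])
        data = make_dataset(
            config.n_train, config.shape, R=R,
            noise_sigma=config.noise_sigma, seed=data_seed,
            n_ellipses=config.n_ellipses,
            center_fraction=config.center_fraction,
        )
        for variant in cnn_variants:
            net_cfg = _variant_config(config.network, variant)
            result: TrainResult = train(data, net_cfg, config.training)
            params_by[(variant, R)] = (result.params, net_cfg)
            traces[(variant, R)] = result.loss_trace
            if verbose:
                print(
                    f"[train] {variant} R={R}: loss "
                    f"{result.loss_trace[0]:.5f} -> {result.loss_trace[-1]:.5f}"
                )

    test_children = np.random.SeedSequence(test_seed).spawn(config.n_test)
    test_phantoms = [
        generate_phantom(
            config.shape, n_ellipses=config.n_ellipses,
            seed=int(c.generate_state(1)[0] % (2**31)),
        )
        for c in test_children
    ]
    grid = evaluate_grid(
        config.methods, config.accelerations, test_phantoms,
        trained_params=params_by, noise_sigma=config.noise_sigma,
        center_fraction=config.center_fraction, seed=test_seed,
    )
    return ExperimentResult(grid=grid, params_by=params_by, traces=traces,
                            config=config)
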