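"""On-disk formats: NIfTI images, CSV masks/grids, HDF5 datasets/checkpoints.

Conventions
-----------
* Phantoms / magnitude images: NIfTI-1, one volume for the magnitude and
  one for the phase (complex data round-trips losslessly as the pair).
* Masks and small image fixtures: plain CSV grids.
* Acquisitions and training sets: HDF5 groups holding {kspace, mask,
  sigma, seed} per sample.
* Network checkpoints: HDF5 with one dataset per weight/bias plus the
  network configuration serialized as a JSON attribute, so a checkpoint is
  self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import nibabel as nib

from .encoding import SamplingMask
from .model import NetworkConfig, NetworkParams
from .phantoms import Phantom, TrainingSample, TrainingSet

__all__ = [
    "save_phantom_nifti",
    "load_phantom_nifti",
    "mask_to_csv",
    "mask_from_csv",
    "image_to_csv",
    "image_from_csv",
    "save_training_set",
    "load_training_set",
    "save_checkpoint",
    "load_checkpoint",
]


def save_phantom_nifti(phantom, path_magnitude, path_phase=None) -> None:
    """Write a complex image as magnitude (+ optional phase) NIfTI volumes."""
    img = np.asarray(getattr(phantom, "image", phantom), dtype=np.complex128)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.abs(img).astype(np.float64), affine),
             str(path_magnitude))
    if path_phase is not None:
        nib.save(nib.Nifti1Image(np.angle(img).astype(np.float64), affine),
                 str(path_phase))


def load_phantom_nifti(path_magnitude, path_phase=None, seed: int = -1) -> Phantom:
    mag = np.asarray(nib.load(str(path_magnitude)).dataobj, dtype=float)
    if path_phase is not None:
        phase = np.asarray(nib.load(str(path_phase)).dataobj, dtype=float)
        img = mag * np.exp(1j * phase)
    else:
        img = mag.astype(np.complex128)
    return Phantom(image=img, seed=seed)


def mask_to_csv(mask: SamplingMask, path) -> None:
    np.savetxt(path, mask.mask.astype(int), fmt="%d", delimiter=",")


def mask_from_csv(path, acceleration: float, center_fraction: float = 0.0,
                  seed: int | None = None) -> SamplingMask:
    grid = np.loadtxt(path, delimiter=",").astype(bool)
    return SamplingMask(mask=grid, acceleration=acceleration,
                        center_fraction=center_fraction, seed=seed)


def image_to_csv(image: np.ndarray, path) -> None:
    """Real-valued grid to CSV (small fixtures only)."""
    np.savetxt(path, np.asarray(image, dtype=float), delimiter=",")


def image_from_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def save_training_set(data: TrainingSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["acceleration"] = data.acceleration
        f.attrs["noise_sigma"] = data.noise_sigma
        f.attrs["seed"] = data.seed
        f.attrs["n_samples"] = len(data.samples)
        for i, s in enumerate(data.samples):
            g = f.create_group(f"sample_{i:05d}")
            g.create_dataset("x_gnd", data=s.x_gnd)
            g.create_dataset("x_u", data=s.x_u)
            g.create_dataset("kspace", data=s.kspace)
            g.create_dataset("mask", data=s.mask.mask.astype(np.uint8))
            g.attrs["mask_seed"] = -1 if s.mask.seed is None else s.mask.seed
            g.attrs["center_fraction"] = s.mask.center_fraction
            g.attrs["sigma"] = data.noise_sigma
            g.attrs["seed"] = s.seed


def load_training_set(path) -> TrainingSet:
    with h5py.File(path, "r") as f:
        R = float(f.attrs["acceleration"])
        sigma = float(f.attrs["noise_sigma"])
        seed = int(f.attrs["seed"])
        samples = []
        for i in range(int(f.attrs["n_samples"])):
            g = f[f"sample_{i:05d}"]
            mask = SamplingMask(
                mask=np.asarray(g["mask"], dtype=bool),
                acceleration=R,
                center_fraction=float(g.attrs["center_fraction"]),
                seed=int(g.attrs["mask_seed"]),
            )
            samples.append(
                TrainingSample(
                    x_gnd=np.asarray(g["x_gnd"]),
                    x_u=np.asarray(g["x_u"]),
                    kspace=np.asarray(g["kspace"]),
                    mask=mask,
                    seed=int(g.attrs["seed"]),
                )
            )
    return TrainingSet(samples=tuple(samples), acceleration=R,
                       noise_sigma=sigma, seed=seed)


def _config_to_json(config: NetworkConfig) -> str:
    d = asdict(config)
    if np.isinf(d["lam"]):
        d["lam"] = "inf"
    return json.dumps(d)


def _config_from_json(blob: str) -> NetworkConfig:
    d = json.loads(blob)
    if d["lam"] == "inf":
        d["lam"] = np.inf
    return NetworkConfig(**d)


def save_checkpoint(path, params: NetworkParams, config: NetworkConfig,
                    loss_trace=None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["config"] = _config_to_json(config)
        for i, (w, b) in enumerate(zip(params.weights, params.biases)):
            f.create_dataset(f"weight_{i}", data=w)
            f.create_dataset(f"bias_{i}", data=b)
        if loss_trace is not None:
            f.create_dataset("loss_trace", data=np.asarray(loss_trace, float))


def load_checkpoint(path) -> tuple[NetworkParams, NetworkConfig, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        config = _config_from_json(f.attrs["config"])
        weights, biases = [], []
        i = 0
        while f"weight_{i}" in f:
            weights.append(np.asarray(f[f"weight_{i}"]))
            biases.append(np.asarray(f[f"bias_{i}"]))
            i += 1
        trace = np.asarray(f["loss_trace"]) if "loss_trace" in f else None
    return NetworkParams(weights, biases), config, trace
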