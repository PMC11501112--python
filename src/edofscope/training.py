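"""End-to-end optimization of the phase mask and the deblurring network.

Training follows a two-stage schedule: first the U-Net alone against fixed
optics, then joint optimization of mask parameters and network weights with
separate Adam learning rates (1e-7 for the optical layer, 1e-4 for the
D-CNN, as selected empirically for this problem class).  Each step draws a
random augmented patch, assigns it one of the M depth positions sampled
uniformly in diopters across the target range (cycling through them), forms
the noisy sensor image and minimizes the depth-averaged RMSE between the
reconstruction and the sharp ground truth.  No auxiliary PSF-similarity
term is used: depth-invariance of the optics emerges from the loss alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deblur_net import UNet
from .grad import Adam
from .image_formation import center_crop
from .optical_layer import DifferentiableOptics
from .optics_core import DepthSpec
from .synthetic_data import SyntheticDataset

__all__ = ["TrainConfig", "AugmentationSpec", "sample_depths", "rmse_loss",
           "train_stage1", "train_joint"]


@dataclass(frozen=True)
class AugmentationSpec:
    """Geometric/photometric augmentation applied to sampled patches."""

    rotations: tuple[int, ...] = (0, 90, 180, 270)
    flip_horizontal: bool = True
    flip_vertical: bool = True
    brightness_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self):
        if any(r % 90 for r in self.rotations):
            raise ValueError("rotations restricted to multiples of 90 degrees")


@dataclass(frozen=True)
class TrainConfig:
    depth_spec: DepthSpec
    lr_optics: float = 1e-7
    lr_network: float = 1e-4
    batch_size: int = 1
    stage1_steps: int = 200
    joint_steps: int = 300
    seed: int = 0
    sigma_s: float = 0.01
    patch_size: int = 32
    source_margin: int = 32  # extra border convolved away before the crop
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)

    def __post_init__(self):
        if self.lr_optics <= 0 or self.lr_network <= 0:
            raise ValueError("learning rates must be positive")
        if self.patch_size % 16:
            raise ValueError("patch_size must be a multiple of 16")


def sample_depths(spec: DepthSpec) -> np.ndarray:
    """M depths uniformly spaced in diopters (1/z), endpoints included.

    For M = 1 the single depth is the diopter midpoint of the range.
    """
    if spec.n_depths == 1:
        diopters = np.array([(1.0 / spec.z_min + 1.0 / spec.z_max) / 2.0])
    else:
        diopters = np.linspace(1.0 / spec.z_max, 1.0 / spec.z_min, spec.n_depths)
    return np.sort(1.0 / diopters)


def rmse_loss(ground_truth: np.ndarray, reconstructions: list[np.ndarray]) -> float:
    """Depth-averaged root-mean-square pixel error.

    Per depth: sqrt((1/N) sum (I - I_R)^2); the per-depth values are averaged
    arithmetically over the M reconstructions.
    """
    if len(reconstructions) == 0:
        raise ValueError("need at least one reconstruction")
    vals = []
    for rec in reconstructions:
        if rec.shape != ground_truth.shape:
            raise ValueError(f"shape mismatch {rec.shape} vs {ground_truth.shape}")
        vals.append(math.sqrt(float(np.mean((ground_truth - rec) ** 2))))
    return float(np.mean(vals))


def _rmse_and_grad(gt: np.ndarray, rec: np.ndarray) -> tuple[float, np.ndarray]:
    diff = rec - gt
    rmse = math.sqrt(float(np.mean(diff ** 2)))
    if rmse == 0.0:
        return 0.0, np.zeros_like(diff)
    return rmse, diff / (diff.size * rmse)


def _augment(patch: np.ndarray, rng: np.random.Generator,
             spec: AugmentationSpec) -> np.ndarray:
    k = int(rng.choice([r // 90 for r in spec.rotations]))
    patch = np.rot90(patch, k)
    if spec.flip_horizontal and rng.random() < 0.5:
        patch = patch[:, ::-1]
    if spec.flip_vertical and rng.random() < 0.5:
        patch = patch[::-1, :]
    b = rng.uniform(*spec.brightness_range)
    return np.clip(patch * b, 0.0, 1.0)


def _run(config: TrainConfig, optics: DifferentiableOptics, net: UNet,
         data: SyntheticDataset, n_steps: int, stage: str,
         train_optics: bool, rng: np.random.Generator) -> pd.DataFrame:
    depths = sample_depths(config.depth_spec)
    opt_net = Adam(net.params(), lr=config.lr_network)
    opt_mask = Adam(optics.params(), lr=config.lr_optics) if train_optics else None
    net.train()
    source_size = config.patch_size + config.source_margin
    log = []
    for step in range(n_steps):
        source = _augment(data.sample_patch(rng, source_size),
                          rng, config.augmentation)
        gt = center_crop(source, config.patch_size)
        depth = float(depths[step % len(depths)])
        noise = (rng.normal(0.0, config.sigma_s, (config.patch_size,) * 2)
                 if config.sigma_s > 0 else None)
        sensor = optics.forward(source, depth, config.patch_size, noise=noise)
        recon = net.forward(sensor[None, None].astype(net.dtype))
        loss, dgrad = _rmse_and_grad(gt, recon[0, 0])
        if not math.isfinite(loss):
            raise RuntimeError(f"divergence at {stage} step {step}: loss={loss}")
        opt_net.zero_grad()
        if opt_mask:
            opt_mask.zero_grad()
        dx = net.backward(dgrad[None, None].astype(net.dtype))
        if train_optics:
            optics.backward(dx[0, 0].astype(float))
            opt_mask.step()
        opt_net.step()
        log.append({"step": step, "stage": stage, "loss": loss,
                    "depth": depth,
                    "lr": config.lr_optics if train_optics else config.lr_network})
    return pd.DataFrame(log, columns=["step", "stage", "loss", "depth", "lr"])


def train_stage1(config: TrainConfig, optics: DifferentiableOptics, net: UNet,
                 data: SyntheticDataset) -> tuple[UNet, pd.DataFrame]:
    """Stage 1: train the D-CNN with the optics frozen."""
    rng = np.random.default_rng(config.seed)
    log = _run(config, optics, net, data, config.stage1_steps, "stage1",
               train_optics=False, rng=rng)
    net.training_stage = "stage1"
    return net, log


def train_joint(config: TrainConfig, optics: DifferentiableOptics, net: UNet,
                data: SyntheticDataset) -> tuple[DifferentiableOptics, UNet, pd.DataFrame]:
    """Stage 2: jointly update mask parameters and network weights."""
    rng = np.random.default_rng(config.seed + 1)
    log = _run(config, optics, net, data, config.joint_steps, "joint",
               train_optics=True, rng=rng)
    net.training_stage = "joint"
    return optics, net, log
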