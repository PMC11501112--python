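"""Shared fixtures: toy optical systems and a cached desk-scale training run."""

from __future__ import annotations

import numpy as np
import pytest

from edofscope.deblur_net import NetworkSpec, UNet
from edofscope.optical_layer import DifferentiableOptics
from edofscope.optics_core import DepthSpec, OpticalSystem, psf_stack
from edofscope.synthetic_data import generate_split
from edofscope.training import TrainConfig, sample_depths, train_joint, train_stage1

MITUTOYO_D = 1.07e-3
MITUTOYO_Z0 = 4e-3


def make_system(grid_size: int, pupil_diameter: float = MITUTOYO_D,
                z0: float = MITUTOYO_Z0) -> OpticalSystem:
    return OpticalSystem(wavelength=550e-9, tube_focal_length=0.2,
                         objective_focal_length=z0,
                         pupil_aperture=pupil_diameter, grid_size=grid_size,
                         sample_pitch=pupil_diameter / grid_size,
                         numerical_aperture=0.42)


@pytest.fixture(scope="session")
def system16() -> OpticalSystem:
    return make_system(16)


@pytest.fixture(scope="session")
def system64() -> OpticalSystem:
    return make_system(64)


@pytest.fixture(scope="session")
def depth_100um() -> DepthSpec:
    return DepthSpec.symmetric(MITUTOYO_Z0, 100e-6, 5)


@pytest.fixture(scope="session")
def small_dataset():
    data = generate_split(12, 2, 3, seed=7, image_size=256)
    return data


def run_toy_training(system, depth_spec, dataset, seed: int):
    """One desk-scale two-stage run (200 network-only + 300 joint steps)."""
    cfg = TrainConfig(depth_spec=depth_spec, stage1_steps=200, joint_steps=300,
                      seed=seed, patch_size=32, source_margin=32)
    optics = DifferentiableOptics(system, "height")
    net = UNet(NetworkSpec.desk_scale(8), seed=seed)
    initial_phase = optics.mask_phase().copy()
    net, log1 = train_stage1(cfg, optics, net, dataset)
    optics, net, log2 = train_joint(cfg, optics, net, dataset)
    return {"optics": optics, "net": net, "log1": log1, "log2": log2,
            "initial_phase": initial_phase, "config": cfg}


@pytest.fixture(scope="session")
def toy_replicates(system64, depth_100um, small_dataset):
    """Three fixed-seed desk-scale end-to-end runs (shared across tests)."""
    return [run_toy_training(system64, depth_100um, small_dataset, seed)
            for seed in (3, 4, 5)]


@pytest.fixture(scope="session")
def eval_depths(depth_100um):
    return sample_depths(depth_100um)
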