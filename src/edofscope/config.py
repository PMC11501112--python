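"""Run configuration: parsing, validation, and the stage pipeline.

A run is described by a small YAML file with ``optical``, ``mask``,
``train``, ``data``, ``eval`` and ``paths`` blocks.  Validation collects
*all* violations (not just the first) and reports them with their key
paths.  The pipeline executes requested stages in order
(synth -> design -> train -> eval -> robustness), writing each artifact
with a sidecar recording the configuration hash and seed that produced it;
stages whose artifacts already exist are skipped unless forced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .deblur_net import NetworkSpec, UNet, load_checkpoint, save_checkpoint
from .evaluation import RobustnessSpec, evaluate_system, fabrication_robustness
from .optical_layer import DifferentiableOptics
from .optics_core import (DepthSpec, OBJECTIVE_PRESETS, OpticalSystem,
                          design_report, mtf_from_psf, psf_stack)
from .phase_masks import CubicMask, DOEMask, cubic_phase
from .synthetic_data import generate_split
from .training import TrainConfig, train_joint, train_stage1

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline",
           "STAGES"]

STAGES = ("synth", "design", "train", "eval", "robustness", "psf", "mtf")
MASK_TYPES = ("doe", "phase", "cubic")


class ConfigError(ValueError):
    """Carries every violation found during validation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n  " + "\n  ".join(violations))


@dataclass
class RunConfig:
    raw: dict
    seed: int
    system: OpticalSystem
    depth_spec: DepthSpec
    mask_type: str
    mask_params: dict
    train: dict
    data: dict
    eval_params: dict
    out_dir: Path
    warnings: list[str] = field(default_factory=list)

    @property
    def hash(self) -> str:
        return eio.config_hash(self.raw)


_KNOWN_TOP = {"seed", "optical", "mask", "train", "data", "eval", "paths"}
_DEFAULT_TRAIN = {"n_depths": 5, "lr_optics": 1e-7, "lr_network": 1e-4,
                  "stage1_steps": 200, "joint_steps": 300, "patch_size": 32,
                  "sigma_s": 0.01, "channel_min": 8, "source_margin": 32}
_DEFAULT_DATA = {"n_train": 12, "n_val": 2, "n_test": 3, "image_size": 256}
_DEFAULT_EVAL = {"out_size": 64, "robustness_sigmas": [0.0, 30e-9, 50e-9],
                 "n_trials": 10, "pad_factor": 2}


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys produce warnings; invariant violations are collected and
    raised together as :class:`ConfigError`, each naming its key path.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    violations: list[str] = []
    warnings = [f"unknown key '{k}'" for k in raw if k not in _KNOWN_TOP]

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        violations.append("seed: must be a non-negative integer")
        seed = 0

    opt = raw.get("optical", {}) or {}
    wavelength = float(opt.get("wavelength", 550e-9))
    grid_size = int(opt.get("grid_size", 64))
    dof_half = float(opt.get("dof_half_range", 100e-6))
    if wavelength <= 0:
        violations.append("optical.wavelength: must be positive")
    if dof_half <= 0:
        violations.append("optical.dof_half_range: must be positive")
    if grid_size < 16:
        violations.append("optical.grid_size: must be >= 16")

    system = depth_spec = None
    if not violations:
        try:
            if "objective" in opt:
                name = str(opt["objective"]).lower()
                if name not in OBJECTIVE_PRESETS:
                    violations.append(f"optical.objective: unknown preset {name!r}")
                else:
                    system = OpticalSystem.from_objective(
                        name, wavelength=wavelength, grid_size=grid_size)
            else:
                system = OpticalSystem(
                    wavelength=wavelength,
                    tube_focal_length=float(opt.get("tube_focal_length", 0)),
                    objective_focal_length=float(opt.get("objective_focal_length", 0)),
                    pupil_aperture=float(opt.get("pupil_diameter", 0)),
                    grid_size=grid_size,
                    sample_pitch=float(opt.get("pupil_diameter", 0)) / grid_size,
                    numerical_aperture=float(opt.get("na", 0.0)))
        except (ValueError, ZeroDivisionError) as exc:
            violations.append(f"optical: {exc}")
        if system is not None:
            try:
                depth_spec = DepthSpec.symmetric(
                    system.z0, dof_half,
                    int(raw.get("train", {}).get("n_depths",
                                                 _DEFAULT_TRAIN["n_depths"]) or 5))
            except ValueError as exc:
                violations.append(f"optical.dof_half_range: {exc}")

    mask = raw.get("mask", {}) or {}
    mask_type = str(mask.get("type", "doe")).lower()
    if mask_type not in MASK_TYPES:
        violations.append(f"mask.type: must be one of {MASK_TYPES}")

    train = {**_DEFAULT_TRAIN, **(raw.get("train", {}) or {})}
    for key in ("lr_optics", "lr_network"):
        if train[key] <= 0:
            violations.append(f"train.{key}: must be positive")
    if train["patch_size"] % 16:
        violations.append("train.patch_size: must be a multiple of 16")

    data = {**_DEFAULT_DATA, **(raw.get("data", {}) or {})}
    for key in ("n_train", "n_val", "n_test"):
        if data[key] < 0:
            violations.append(f"data.{key}: must be >= 0")
    if data["image_size"] < 256:
        violations.append("data.image_size: must be >= 256")

    eval_params = {**_DEFAULT_EVAL, **(raw.get("eval", {}) or {})}
    if any(s < 0 for s in eval_params["robustness_sigmas"]):
        violations.append("eval.robustness_sigmas: must be >= 0")

    out_dir = Path((raw.get("paths", {}) or {}).get("out_dir", "edofscope_run"))

    if violations:
        raise ConfigError(violations)
    return RunConfig(raw=raw, seed=seed, system=system, depth_spec=depth_spec,
                     mask_type=mask_type, mask_params=mask, train=train,
                     data=data, eval_params=eval_params, out_dir=out_dir,
                     warnings=warnings)


def _module_seed(base: int, module: str) -> int:
    """Expand the global seed into a stable per-module substream seed."""
    import zlib
    return int(np.random.SeedSequence(
        entropy=base, spawn_key=(zlib.crc32(module.encode()),)
    ).generate_state(1)[0]) % (2 ** 31)


def _sidecar(config: RunConfig) -> dict:
    return {"config_hash": config.hash, "seed": config.seed}


def _build_optics(config: RunConfig) -> DifferentiableOptics:
    param = "phase" if config.mask_type in ("phase", "cubic") else "height"
    optics = DifferentiableOptics(config.system, parameterization=param,
                                  pad_factor=config.eval_params["pad_factor"])
    if config.mask_type == "cubic":
        alpha = config.mask_params.get("alpha")
        mask = (CubicMask(alpha=float(alpha), grid_size=config.system.grid_size)
                if alpha is not None else
                CubicMask.for_dof_range(2 * (config.depth_spec.z_max -
                                             config.depth_spec.z0),
                                        config.system.grid_size))
        optics.set_mask_phase(cubic_phase(mask))
    return optics


def _dataset(config: RunConfig):
    return generate_split(config.data["n_train"], config.data["n_val"],
                          config.data["n_test"],
                          seed=_module_seed(config.seed, "synthetic_data"),
                          image_size=config.data["image_size"])


def _load_trained(config: RunConfig):
    ckpt = config.out_dir / "checkpoint.npz"
    if not ckpt.exists():
        raise FileNotFoundError(f"run the train stage first ({ckpt} missing)")
    net = load_checkpoint(ckpt)
    phase = np.loadtxt(config.out_dir / "mask_phase.csv", delimiter=",")
    optics = _build_optics(config)
    optics.set_mask_phase(phase)
    return optics, net


def run_pipeline(config: RunConfig, stages: list[str], force: bool = False) -> int:
    """Execute pipeline stages; returns 0 on success.

    Stage artifacts land in ``config.out_dir``; a stage whose primary
    artifact already exists is a no-op unless ``force`` is set.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; known: {STAGES}")

    for stage in stages:
        if stage == "design":
            target = out / "design.csv"
            if target.exists() and not force:
                continue
            dof_half = config.depth_spec.z_max - config.depth_spec.z0
            rows = []
            obj = config.mask_params.get("objective") or \
                config.raw.get("optical", {}).get("objective")
            names = [obj] if obj else sorted(OBJECTIVE_PRESETS)
            for name in names:
                rows.append(design_report(name, dof_half, config.system.wavelength))
            pd.DataFrame(rows).to_csv(target, index=False)
            eio.write_sidecar(target, _sidecar(config))

        elif stage == "synth":
            target = out / "data" / "manifest.csv"
            if target.exists() and not force:
                continue
            _dataset(config).save(out / "data")
            eio.write_sidecar(target, _sidecar(config))

        elif stage == "train":
            target = out / "checkpoint.npz"
            if target.exists() and not force:
                continue
            dataset = _dataset(config)
            optics = _build_optics(config)
            spec = NetworkSpec.desk_scale(config.train["channel_min"]) \
                if config.train["channel_min"] != 32 else NetworkSpec()
            net = UNet(spec, seed=_module_seed(config.seed, "deblur_net"))
            tcfg = TrainConfig(
                depth_spec=config.depth_spec,
                lr_optics=config.train["lr_optics"],
                lr_network=config.train["lr_network"],
                stage1_steps=config.train["stage1_steps"],
                joint_steps=config.train["joint_steps"],
                seed=_module_seed(config.seed, "training"),
                sigma_s=config.train["sigma_s"],
                patch_size=config.train["patch_size"],
                source_margin=config.train["source_margin"])
            net, log1 = train_stage1(tcfg, optics, net, dataset)
            logs = [log1]
            if config.mask_type != "cubic":
                optics, net, log2 = train_joint(tcfg, optics, net, dataset)
                logs.append(log2)
            pd.concat(logs, ignore_index=True).to_csv(out / "log.csv", index=False)
            np.savetxt(out / "mask_phase.csv", optics.mask_phase(), delimiter=",")
            if optics.parameterization == "height":
                eio.save_map(optics.theta.value, out / "mask_height.tiff",
                             {**_sidecar(config),
                              "sample_pitch_m": config.system.sample_pitch,
                              "wavelength_m": config.system.wavelength})
            save_checkpoint(net, target)
            eio.write_sidecar(target, _sidecar(config))

        elif stage == "eval":
            target = out / "metrics.csv"
            if target.exists() and not force:
                continue
            optics, net = _load_trained(config)
            dataset = _dataset(config)
            images = [dataset.image(i) for i in dataset.indices("test")]
            mask = (optics.export_doe() if optics.parameterization == "height"
                    else _PhaseOnlyMask(optics.mask_phase()))
            report = evaluate_system(
                config.system, mask, net, images, config.depth_spec,
                out_size=config.eval_params["out_size"],
                sensor_sigma=config.train["sigma_s"],
                seed=_module_seed(config.seed, "evaluation"))
            frame = report.to_frame()
            frame.to_csv(target, index=False)
            eio.write_sidecar(target, {**_sidecar(config),
                                       "mean_psnr_db": report.mean_psnr,
                                       "mean_ssim": report.mean_ssim})

        elif stage == "robustness":
            target = out / "robustness.csv"
            if target.exists() and not force:
                continue
            optics, net = _load_trained(config)
            if optics.parameterization != "height":
                raise ValueError("robustness stage needs a height (DOE) mask")
            dataset = _dataset(config)
            images = [dataset.image(i) for i in dataset.indices("test")]
            rob = RobustnessSpec(
                sigma_levels=tuple(config.eval_params["robustness_sigmas"]),
                n_trials=config.eval_params["n_trials"],
                seed=_module_seed(config.seed, "robustness"))
            table = fabrication_robustness(
                optics.export_doe(), rob, config.system, net, images,
                config.depth_spec, out_size=config.eval_params["out_size"],
                sensor_sigma=config.train["sigma_s"])
            table.to_csv(target, index=False)
            eio.write_sidecar(target, _sidecar(config))

        elif stage in ("psf", "mtf"):
            target = out / ("psf_stack.tiff" if stage == "psf" else "mtf.csv")
            if target.exists() and not force:
                continue
            optics = _build_optics(config)
            phase_file = out / "mask_phase.csv"
            if phase_file.exists():
                optics.set_mask_phase(np.loadtxt(phase_file, delimiter=","))
            from .training import sample_depths
            depths = sample_depths(config.depth_spec)
            stack = psf_stack(config.system, optics.mask_phase(), depths,
                              pad_factor=config.eval_params["pad_factor"])
            if stage == "psf":
                eio.save_psf_stack(stack, target, _sidecar(config))
            else:
                mid = stack.psfs[len(stack.psfs) // 2]
                eio.save_mtf_csv(mtf_from_psf(mid, config.system.sample_pitch),
                                 target, _sidecar(config))
    return 0


class _PhaseOnlyMask:
    """Adapter: a fixed phase map with the mask protocol."""

    def __init__(self, phase: np.ndarray):
        self._phase = phase

    def pupil_phase(self, system) -> np.ndarray:
        return self._phase
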