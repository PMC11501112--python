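"""Pupil-plane phase mask parameterizations and fabrication perturbations.

Three realizations of the learnable phase coding mask are provided:

* :class:`DOEMask` — a surface-relief diffractive element whose local height
  ``h`` imparts phase ``k (n - 1) h`` (lossless, refractive index n = 1.5 at
  the 550 nm design wavelength).
* :class:`MetalensMask` — a metasurface of nanopillars whose per-cell radius
  sets the local phase through a measured (or synthetic) phase-radius lookup
  table; the largest pillar diameter is 50 nm below the cell pitch.
* :class:`CubicMask` — the classic wavefront-coding cubic phase
  ``mod(alpha/N^3 (x^3 + y^3), 2 pi)`` on integer grid coordinates, used as
  a fixed baseline.

Every mask exposes ``pupil_phase(system)`` returning a phase map on the
system's pupil grid, directly consumable by
:func:`edofscope.optics_core.assemble_pupil`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .optics_core import OpticalSystem

__all__ = [
    "DOEMask",
    "MetalensMask",
    "CubicMask",
    "PhaseRadiusLUT",
    "synthetic_lut",
    "doe_phase",
    "cubic_phase",
    "radius_to_phase",
    "phase_to_radius",
    "perturb_mask",
    "CUBIC_ALPHA_PRESETS",
]

TWO_PI = 2.0 * np.pi

# Fixed cubic-mask strengths selected per targeted (full) depth-of-field
# range: 200 um, 2 mm and 3 mm.
CUBIC_ALPHA_PRESETS: dict[float, float] = {
    200e-6: 6 * np.pi,
    2e-3: 200 * np.pi,
    3e-3: 360 * np.pi,
}


@dataclass(frozen=True)
class PhaseRadiusLUT:
    """Tabulated nanopillar radius -> (phase, transmission) response.

    Radii are strictly increasing, phases must span at least 2 pi across the
    radius range so any wrapped target phase is realizable.
    """

    radii: np.ndarray
    phases: np.ndarray
    transmissions: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.radii, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        t = np.asarray(self.transmissions, dtype=float)
        if not (len(r) == len(p) == len(t)):
            raise ValueError("LUT columns differ in length")
        if np.any(np.diff(r) <= 0):
            raise ValueError("LUT radii must be strictly increasing")
        if p[-1] - p[0] < TWO_PI - 1e-9:
            raise ValueError("LUT phase span must cover at least 2 pi")
        if np.any((t < 0) | (t > 1)):
            raise ValueError("transmissions must lie in [0, 1]")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "phases", p)
        object.__setattr__(self, "transmissions", t)

    @property
    def r_min(self) -> float:
        return float(self.radii[0])

    @property
    def r_max(self) -> float:
        return float(self.radii[-1])

    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.phases) > 0))

    @classmethod
    def from_csv(cls, path) -> "PhaseRadiusLUT":
        """Read a LUT from CSV with columns radius_nm, phase_rad, transmission."""
        df = pd.read_csv(path)
        return cls(radii=df["radius_nm"].to_numpy() * 1e-9,
                   phases=df["phase_rad"].to_numpy(),
                   transmissions=df["transmission"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "radius_nm": self.radii * 1e9,
            "phase_rad": self.phases,
            "transmission": self.transmissions,
        }).to_csv(path, index=False)


def synthetic_lut(cell_pitch: float, n_points: int = 64,
                  r_min: float = 40e-9) -> PhaseRadiusLUT:
    """Synthetic unit-transmission LUT: phase linear in radius over 0..2 pi.

    A stand-in for a full-wave nanopillar simulation: radii run from
    ``r_min`` up to half the largest admissible diameter (cell pitch minus
    50 nm) and map linearly onto a full 2 pi of phase.  Real tabulated
    responses can be loaded with :meth:`PhaseRadiusLUT.from_csv`.
    """
    r_max = (cell_pitch - 50e-9) / 2.0
    if r_max <= r_min:
        raise ValueError(f"cell pitch {cell_pitch} too small for a {r_min} "
                         "minimum pillar radius")
    radii = np.linspace(r_min, r_max, n_points)
    phases = np.linspace(0.0, TWO_PI, n_points)
    return PhaseRadiusLUT(radii=radii, phases=phases,
                          transmissions=np.ones(n_points))


@dataclass(frozen=True)
class DOEMask:
    """Surface-relief phase plate parameterized by its height map (meters)."""

    height_map: np.ndarray
    refractive_index: float = 1.5

    def __post_init__(self):
        if self.refractive_index <= 1:
            raise ValueError("refractive index must exceed 1")
        if np.any(np.asarray(self.height_map) < 0):
            raise ValueError("heights must be non-negative")

    def pupil_phase(self, system: OpticalSystem) -> np.ndarray:
        self._check_grid(system)
        return doe_phase(self, system.wavenumber)

    def _check_grid(self, system: OpticalSystem) -> None:
        n = system.grid_size
        if self.height_map.shape != (n, n):
            raise ValueError(f"height map {self.height_map.shape} does not match "
                             f"pupil grid {(n, n)}")


def doe_phase(mask: DOEMask, wavenumber: float) -> np.ndarray:
    """Pointwise DOE phase k (n - 1) h; linear, hence trivially differentiable."""
    return wavenumber * (mask.refractive_index - 1.0) * mask.height_map


@dataclass(frozen=True)
class CubicMask:
    """Fixed cubic wavefront-coding mask on an N x N integer grid."""

    alpha: float
    grid_size: int

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")

    @classmethod
    def for_dof_range(cls, dof_range: float, grid_size: int) -> "CubicMask":
        """Select the preset alpha whose target DOF range is nearest."""
        key = min(CUBIC_ALPHA_PRESETS, key=lambda d: abs(d - dof_range))
        return cls(alpha=CUBIC_ALPHA_PRESETS[key], grid_size=grid_size)

    def raw_phase(self) -> np.ndarray:
        """Unwrapped cubic profile alpha/N^3 (x^3 + y^3); odd in (x, y)."""
        n = self.grid_size
        c = np.arange(n) - n // 2
        x = c[None, :].astype(float)
        y = c[:, None].astype(float)
        return self.alpha / n ** 3 * (x ** 3 + y ** 3)

    def pupil_phase(self, system: OpticalSystem) -> np.ndarray:
        if system.grid_size != self.grid_size:
            raise ValueError("mask and system grid sizes differ")
        return cubic_phase(self)


def cubic_phase(mask: CubicMask) -> np.ndarray:
    """Wrapped cubic phase mod(alpha/N^3 (x^3 + y^3), 2 pi), in [0, 2 pi)."""
    return np.mod(mask.raw_phase(), TWO_PI)


@dataclass(frozen=True)
class MetalensMask:
    """Metasurface mask: one nanopillar radius per mask cell plus its LUT."""

    radius_map: np.ndarray
    lut: PhaseRadiusLUT
    cell_pitch: float

    def __post_init__(self):
        r = np.asarray(self.radius_map, dtype=float)
        object.__setattr__(self, "radius_map", r)
        if np.any(r < self.lut.r_min - 1e-15) or np.any(r > self.lut.r_max + 1e-15):
            bad = np.argwhere((r < self.lut.r_min - 1e-15) | (r > self.lut.r_max + 1e-15))[0]
            raise ValueError(f"radius at cell {tuple(int(i) for i in bad)} outside LUT range "
                             f"[{self.lut.r_min}, {self.lut.r_max}]")
        if np.any(2 * r > self.max_diameter + 1e-15):
            bad = np.argwhere(2 * r > self.max_diameter + 1e-15)[0]
            raise ValueError(f"pillar diameter at cell {tuple(bad)} exceeds "
                             f"max diameter {self.max_diameter}")

    @property
    def max_diameter(self) -> float:
        """Largest admissible pillar diameter: cell pitch minus 50 nm."""
        return self.cell_pitch - 50e-9

    def pupil_phase(self, system: OpticalSystem) -> np.ndarray:
        n = system.grid_size
        if self.radius_map.shape != (n, n):
            raise ValueError(f"radius map {self.radius_map.shape} does not match "
                             f"pupil grid {(n, n)}")
        return radius_to_phase(self.radius_map, self.lut)

    def transmission_map(self) -> np.ndarray:
        """Per-cell amplitude transmission interpolated from the LUT."""
        return np.interp(self.radius_map, self.lut.radii, self.lut.transmissions)

    @classmethod
    def from_phase(cls, phase_map: np.ndarray, lut: PhaseRadiusLUT,
                   cell_pitch: float) -> "MetalensMask":
        """Quantize an optimized phase profile to a fabricable radius map."""
        return cls(radius_map=phase_to_radius(phase_map, lut), lut=lut,
                   cell_pitch=cell_pitch)


def radius_to_phase(radius_map: np.ndarray, lut: PhaseRadiusLUT) -> np.ndarray:
    """Per-cell phase by monotone linear interpolation of the LUT."""
    r = np.asarray(radius_map, dtype=float)
    below, above = r < lut.r_min - 1e-15, r > lut.r_max + 1e-15
    if np.any(below | above):
        bad = np.argwhere(below | above)[0]
        raise ValueError(f"radius at cell {tuple(int(i) for i in bad)} "
                         "outside LUT range")
    return np.interp(r, lut.radii, lut.phases)


def phase_to_radius(phase_map: np.ndarray, lut: PhaseRadiusLUT) -> np.ndarray:
    """Invert the LUT: wrap phases into [0, 2 pi), then interpolate radii.

    The wrapped phase is lifted into the LUT's own phase branch
    ``[phases[0], phases[0] + 2 pi]`` before inversion, so a LUT whose phase
    does not start at zero is handled correctly.
    """
    if not lut.is_monotone():
        raise ValueError("LUT phases must be strictly increasing to invert")
    wrapped = np.mod(phase_map, TWO_PI)  # exact multiples of 2 pi map to 0
    target = lut.phases[0] + np.mod(wrapped - lut.phases[0], TWO_PI)
    return np.interp(target, lut.phases, lut.radii)


def perturb_mask(mask, sigma: float, seed: int):
    """Fabrication-error model: i.i.d. Gaussian noise on heights or radii.

    Adds zero-mean Gaussian noise of standard deviation ``sigma`` (meters) to
    every height (DOE) or pillar radius (metalens), then clips back to the
    physical bounds; reproducible for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return mask
    rng = np.random.default_rng(seed)
    if isinstance(mask, DOEMask):
        noisy = mask.height_map + rng.normal(0.0, sigma, mask.height_map.shape)
        return replace(mask, height_map=np.clip(noisy, 0.0, None))
    if isinstance(mask, MetalensMask):
        noisy = mask.radius_map + rng.normal(0.0, sigma, mask.radius_map.shape)
        hi = min(mask.lut.r_max, mask.max_diameter / 2.0)
        return replace(mask, radius_map=np.clip(noisy, mask.lut.r_min, hi))
    raise TypeError(f"cannot perturb mask of type {type(mask).__name__}")
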