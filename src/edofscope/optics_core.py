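"""Wave-optics primitives for a 4f microscope with a pupil-plane phase mask.

The forward model is standard incoherent Fourier optics: the pupil function
``P(x1, y1) = A(x1, y1) exp(i phi(x1, y1))`` lives in the Fourier plane of a
4f relay, and the point spread function at a scene depth ``z`` is the squared
magnitude of its Fourier transform.  Defocus enters as a quadratic pupil
phase whose strength is the dimensionless defocus coefficient

    psi_z = (pi / lambda) * (1/z - 1/z0) * a**2,

with ``a`` the effective pupil radius and ``z0`` the in-focus depth.  The
module also provides the two design bounds used to size a phase mask: the
pupil radius needed to pass a spatial frequency (``r >= (f1/k) |k_xy|``) and
the anti-aliasing bound on the mask sample pitch
(``delta_s <= a pi / (8 psi_max)``).

Conventions
-----------
* All lengths are in meters.
* Pupil grids are square, with the origin at index ``N // 2`` on each axis.
* Vendor pupil-size tables in this field quote the aperture *diameter*;
  :class:`OpticalSystem` stores the diameter as ``pupil_aperture`` and uses
  the effective radius ``a = D / 2`` in every formula above.  Only this
  convention reproduces the tabulated defocus coefficients for standard
  objectives (see README).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalSystem",
    "DepthSpec",
    "PupilField",
    "PSFStack",
    "MTFCurve",
    "OBJECTIVE_PRESETS",
    "defocus_coefficient",
    "max_defocus",
    "max_sampling_pitch",
    "min_pupil_radius",
    "defocus_phase_map",
    "assemble_pupil",
    "psf_from_pupil",
    "mtf_from_psf",
    "radial_average",
    "design_report",
]


# Standard objectives: in-focus depth z0 (the objective focal length, from the
# stated magnification and reference tube length), pupil diameter D and NA.
OBJECTIVE_PRESETS: dict[str, dict[str, float]] = {
    # 180 mm RMS tube: f_obj = 180 mm / magnification
    "rms4x": {"z0": 45e-3, "pupil_diameter": 3.72e-3, "na": 0.13,
              "tube_focal_length": 180e-3},
    "rms20x": {"z0": 9e-3, "pupil_diameter": 2.87e-3, "na": 0.40,
               "tube_focal_length": 180e-3},
    # 200 mm reference tube: f_obj = 200 mm / 50
    "mitutoyo50x": {"z0": 4e-3, "pupil_diameter": 1.07e-3, "na": 0.42,
                    "tube_focal_length": 200e-3},
}


def defocus_coefficient(z: float, z0: float, a: float, wavelength: float) -> float:
    """Dimensionless defocus coefficient psi_z = (pi/lambda)(1/z - 1/z0) a^2.

    Parameters
    ----------
    z : actual scene depth (m), > 0.
    z0 : in-focus depth (m), > 0.
    a : effective pupil radius (m), > 0.
    wavelength : design wavelength (m).

    The sign of the result indicates the defocus direction (positive for
    depths nearer than ``z0``).
    """
    if z <= 0 or z0 <= 0:
        raise ValueError(f"depths must be positive, got z={z}, z0={z0}")
    if a <= 0 or wavelength <= 0:
        raise ValueError("pupil radius and wavelength must be positive")
    return (np.pi / wavelength) * (1.0 / z - 1.0 / z0) * a ** 2


@dataclass(frozen=True)
class DepthSpec:
    """Targeted scene depth range around the in-focus depth."""

    z_min: float
    z_max: float
    z0: float
    n_depths: int = 5

    def __post_init__(self):
        if not (0 < self.z_min < self.z0 < self.z_max):
            raise ValueError(
                f"need 0 < z_min < z0 < z_max, got {self.z_min}, {self.z0}, {self.z_max}")
        if self.n_depths < 1:
            raise ValueError("n_depths must be >= 1")

    @classmethod
    def symmetric(cls, z0: float, half_range: float, n_depths: int = 5) -> "DepthSpec":
        return cls(z0 - half_range, z0 + half_range, z0, n_depths)


def max_defocus(depth_spec: DepthSpec, a: float, wavelength: float) -> float:
    """Maximum |psi| over the depth range (attained at one of the endpoints).

    Because 1/z is convex, the near endpoint dominates for a symmetric range.
    """
    psi_near = defocus_coefficient(depth_spec.z_min, depth_spec.z0, a, wavelength)
    psi_far = defocus_coefficient(depth_spec.z_max, depth_spec.z0, a, wavelength)
    return max(abs(psi_near), abs(psi_far))


def max_sampling_pitch(a: float, psi_max: float) -> float:
    """Anti-aliasing bound on the mask sample pitch: a*pi / (8*psi_max).

    Raises
    ------
    ValueError
        If ``psi_max`` is not positive (the bound is unbounded at zero
        defocus).
    """
    if psi_max <= 0:
        raise ValueError("psi_max must be > 0; the pitch bound is unbounded "
                         "for a zero-defocus scene")
    return a * np.pi / (8.0 * psi_max)


def min_pupil_radius(f1: float, wavenumber: float, kx: float, ky: float) -> float:
    """Pupil radius needed to pass spatial frequency (kx, ky): (f1/k)*|k_xy|."""
    if wavenumber <= 0:
        raise ValueError("wavenumber must be positive")
    return f1 / wavenumber * np.hypot(kx, ky)


@dataclass(frozen=True)
class OpticalSystem:
    """Geometry of the 4f system and its pupil-plane sampling grid.

    ``pupil_aperture`` is the full aperture diameter D; the effective radius
    ``a = D/2`` enters the defocus and sampling formulas.
    """

    wavelength: float
    tube_focal_length: float
    objective_focal_length: float  # doubles as the in-focus depth z0
    pupil_aperture: float
    grid_size: int
    sample_pitch: float
    numerical_aperture: float = 0.0

    def __post_init__(self):
        for name in ("wavelength", "tube_focal_length", "objective_focal_length",
                     "pupil_aperture", "sample_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        if self.sample_pitch * self.grid_size < self.pupil_aperture * (1 - 1e-12):
            raise ValueError("grid does not span the aperture: "
                             f"{self.sample_pitch * self.grid_size} < {self.pupil_aperture}")

    @property
    def effective_radius(self) -> float:
        """a = D/2."""
        return self.pupil_aperture / 2.0

    @property
    def wavenumber(self) -> float:
        return 2.0 * np.pi / self.wavelength

    @property
    def z0(self) -> float:
        return self.objective_focal_length

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x1, y1) coordinate grids, origin at index N//2."""
        n = self.grid_size
        c = np.arange(n) - n // 2
        x = c[None, :] * self.sample_pitch
        y = c[:, None] * self.sample_pitch
        return x, y

    def aperture_mask(self) -> np.ndarray:
        x, y = self.grid_coords()
        return (x ** 2 + y ** 2) <= self.effective_radius ** 2 + 1e-18

    @classmethod
    def from_objective(cls, name: str, wavelength: float = 550e-9,
                       grid_size: int | None = None,
                       depth_spec: DepthSpec | None = None,
                       sample_pitch: float | None = None) -> "OpticalSystem":
        """Build a system from a named objective preset.

        If ``sample_pitch`` is omitted it is set from the anti-aliasing bound
        for ``depth_spec`` (required in that case); ``grid_size`` defaults to
        ceil(D / pitch) rounded up to the next even integer, one sample per
        mask cell.
        """
        key = name.lower()
        if key not in OBJECTIVE_PRESETS:
            raise KeyError(f"unknown objective {name!r}; "
                           f"known: {sorted(OBJECTIVE_PRESETS)}")
        p = OBJECTIVE_PRESETS[key]
        d = p["pupil_diameter"]
        if sample_pitch is None and grid_size is None:
            if depth_spec is None:
                raise ValueError(
                    "need depth_spec, sample_pitch or grid_size to set the grid")
            psi = max_defocus(depth_spec, d / 2.0, wavelength)
            sample_pitch = max_sampling_pitch(d / 2.0, psi)
        if grid_size is None:
            grid_size = int(np.ceil(d / sample_pitch))
            grid_size += grid_size % 2
            # keep the grid spanning the aperture after rounding
            sample_pitch = d / grid_size if sample_pitch * grid_size < d else sample_pitch
        else:
            sample_pitch = d / grid_size
        return cls(wavelength=wavelength, tube_focal_length=p["tube_focal_length"],
                   objective_focal_length=p["z0"], pupil_aperture=d,
                   grid_size=grid_size, sample_pitch=sample_pitch,
                   numerical_aperture=p["na"])


@dataclass
class PupilField:
    """Amplitude and phase of the generalized pupil on the shared grid."""

    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase grids differ in shape")
        if np.any(self.amplitude < 0) or np.any(self.amplitude > 1 + 1e-12):
            raise ValueError("amplitude must lie in [0, 1]")

    def complex_field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)


@dataclass
class PSFStack:
    """Depth-indexed, unit-sum incoherent PSFs."""

    depths: list[float]
    psfs: list[np.ndarray]

    def __post_init__(self):
        if len(self.depths) != len(self.psfs):
            raise ValueError("depths and psfs length mismatch")


@dataclass
class MTFCurve:
    """Magnitude of the PSF's Fourier transform, 1 at zero frequency.

    ``frequencies`` is the centered 1-D frequency axis (cycles / m) of the
    square ``magnitude`` map; ``radial`` holds the radially averaged profile
    with its own frequency axis ``radial_frequencies``.
    """

    frequencies: np.ndarray
    magnitude: np.ndarray
    radial_frequencies: np.ndarray = field(default=None)  # type: ignore[assignment]
    radial: np.ndarray = field(default=None)  # type: ignore[assignment]


def defocus_phase_map(system: OpticalSystem, psi: float) -> np.ndarray:
    """Quadratic defocus phase psi * (x1^2 + y1^2) / a^2 on the pupil grid."""
    x, y = system.grid_coords()
    return psi * (x ** 2 + y ** 2) / system.effective_radius ** 2


def assemble_pupil(system: OpticalSystem, mask_phase: np.ndarray,
                   defocus_phase: np.ndarray) -> PupilField:
    """Clear circular aperture carrying the summed mask + defocus phase."""
    n = system.grid_size
    if mask_phase.shape != (n, n) or defocus_phase.shape != (n, n):
        raise ValueError(
            f"phase maps must be {(n, n)}, got {mask_phase.shape} and {defocus_phase.shape}")
    amplitude = system.aperture_mask().astype(float)
    return PupilField(amplitude=amplitude, phase=mask_phase + defocus_phase)


def centered_fft2(field: np.ndarray) -> np.ndarray:
    """2-D DFT with the zero-frequency sample at index N//2 on both axes."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field)))


def psf_from_pupil(pupil: PupilField, pad_factor: int = 2) -> np.ndarray:
    """Centered, unit-sum incoherent PSF |F{P}|^2 of a zero-padded pupil.

    The pupil is embedded in a grid ``pad_factor`` times larger before the
    transform to avoid wrap-around; the returned PSF has that padded size.
    """
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    p = pupil.complex_field()
    n = p.shape[0]
    m = n * pad_factor
    padded = np.zeros((m, m), dtype=complex)
    lo = (m - n) // 2
    padded[lo:lo + n, lo:lo + n] = p
    psf = np.abs(centered_fft2(padded)) ** 2
    total = psf.sum()
    if total <= 0:
        raise ValueError("pupil carries no energy (all-zero amplitude)")
    return psf / total


def mtf_from_psf(psf: np.ndarray, sample_pitch: float = 1.0) -> MTFCurve:
    """MTF of a PSF: |F{h}| normalized to 1 at zero frequency.

    ``sample_pitch`` is the spatial sampling of the PSF grid; the frequency
    axis is reported in cycles per the same unit.
    """
    total = psf.sum()
    if total <= 0:
        raise ValueError("PSF must have positive total energy")
    mag = np.abs(centered_fft2(psf)) / total
    n = psf.shape[0]
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=sample_pitch))
    rf, rprof = radial_average(mag, freqs)
    return MTFCurve(frequencies=freqs, magnitude=mag,
                    radial_frequencies=rf, radial=rprof)


def radial_average(mag: np.ndarray, freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radially average a centered square map by nearest-bin assignment."""
    n = mag.shape[0]
    c = n // 2
    iy, ix = np.indices(mag.shape)
    r = np.rint(np.hypot(iy - c, ix - c)).astype(int)
    nbins = (n + 1) // 2
    keep = r < nbins
    sums = np.bincount(r[keep], weights=mag[keep], minlength=nbins)
    counts = np.bincount(r[keep], minlength=nbins)
    profile = sums / np.maximum(counts, 1)
    df = freqs[c + 1] - freqs[c] if n > 1 else 1.0
    return np.arange(nbins) * df, profile


def psf_stack(system: OpticalSystem, mask_phase: np.ndarray,
              depths, amplitude: np.ndarray | None = None,
              pad_factor: int = 2) -> PSFStack:
    """Depth-indexed unit-sum PSFs for a fixed mask phase.

    ``amplitude`` optionally replaces the clear circular aperture (e.g. to
    carry a metalens transmission map); it is still gated by the aperture.
    """
    psfs = []
    for z in depths:
        psi = defocus_coefficient(z, system.z0, system.effective_radius,
                                  system.wavelength)
        pupil = assemble_pupil(system, mask_phase, defocus_phase_map(system, psi))
        if amplitude is not None:
            pupil = PupilField(amplitude=pupil.amplitude * amplitude,
                               phase=pupil.phase)
        psfs.append(psf_from_pupil(pupil, pad_factor=pad_factor))
    return PSFStack(depths=list(depths), psfs=psfs)


def design_report(objective: str, dof_half_range: float,
                  wavelength: float = 550e-9) -> dict[str, float]:
    """Sampling-design summary for an objective and a symmetric depth range.

    Returns the effective radius ``a``, maximum defocus coefficient
    ``psi_max`` over z0 +/- dof_half_range, and the mask pitch bound
    ``delta_s_max``; the quantities a designer reads off to choose between a
    DOE and a metalens realization.
    """
    p = OBJECTIVE_PRESETS[objective.lower()]
    a = p["pupil_diameter"] / 2.0
    spec = DepthSpec.symmetric(p["z0"], dof_half_range)
    psi = max_defocus(spec, a, wavelength)
    return {
        "objective": objective.lower(),
        "na": p["na"],
        "effective_radius_m": a,
        "psi_max": psi,
        "delta_s_max_m": max_sampling_pitch(a, psi),
    }
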