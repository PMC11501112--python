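"""Differentiable image-formation layer for end-to-end mask learning.

Forward path (per depth):

    phase  = psi_z * (x^2 + y^2)/a^2  +  phi_mask(theta)
    pupil  P = A exp(i phase)
    PSF    h = |F{P_padded}|^2 / sum(...)
    sensor = clip( crop( I * h ) + noise, 0, 1 )

``theta`` is either a DOE height map (phase = k (n-1) theta) or a raw pupil
phase map (the metalens route, quantized to pillar radii only at export).
The backward pass propagates the sensor-plane gradient through the linear
convolution, the PSF normalization, the squared modulus and the Fourier
transform down to ``theta``; the complex-step bookkeeping uses the
convention grad_z = dL/dRe(z) + i dL/dIm(z), under which the adjoint of the
unnormalized FFT is ``x -> conj(fft(conj(x)))``.  Correctness is pinned by
finite-difference tests on small pupils.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import next_fast_len

from .grad import Param
from .optics_core import OpticalSystem, defocus_coefficient
from .phase_masks import DOEMask, MetalensMask, PhaseRadiusLUT, phase_to_radius

__all__ = ["DifferentiableOptics"]


def _centered_fft2(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x)))


def _adjoint_centered_fft2(g: np.ndarray) -> np.ndarray:
    # adjoint of (fftshift . F . ifftshift): fftshift . F^H . ifftshift
    return np.fft.fftshift(np.conj(np.fft.fft2(np.conj(np.fft.ifftshift(g)))))


class DifferentiableOptics:
    """Learnable pupil mask plus the wave-optics forward model.

    Parameters
    ----------
    system : OpticalSystem
        Geometry and pupil grid.
    parameterization : {"height", "phase"}
        Learn a DOE height map (meters) or a raw pupil phase map (radians).
    refractive_index : float
        DOE material index (phase per height k (n - 1)).
    pad_factor : int
        Zero-padding factor before the pupil transform.
    """

    def __init__(self, system: OpticalSystem, parameterization: str = "height",
                 refractive_index: float = 1.5, pad_factor: int = 2,
                 init: np.ndarray | None = None):
        if parameterization not in ("height", "phase"):
            raise ValueError("parameterization must be 'height' or 'phase'")
        self.system = system
        self.parameterization = parameterization
        self.refractive_index = refractive_index
        self.pad_factor = pad_factor
        n = system.grid_size
        value = np.zeros((n, n)) if init is None else np.array(init, dtype=float)
        if value.shape != (n, n):
            raise ValueError(f"init must be {(n, n)}, got {value.shape}")
        self.theta = Param(value, name=f"mask.{parameterization}")
        self.aperture = system.aperture_mask().astype(float)
        x, y = system.grid_coords()
        self._defocus_unit = (x ** 2 + y ** 2) / system.effective_radius ** 2
        self._cache = None

    # -- mask plumbing ----------------------------------------------------

    def params(self) -> list[Param]:
        return [self.theta]

    def mask_phase(self) -> np.ndarray:
        if self.parameterization == "height":
            return (self.system.wavenumber * (self.refractive_index - 1.0)
                    * self.theta.value)
        return self.theta.value

    def export_doe(self) -> DOEMask:
        if self.parameterization != "height":
            raise ValueError("phase-parameterized optics export a metalens")
        return DOEMask(height_map=np.clip(self.theta.value, 0.0, None),
                       refractive_index=self.refractive_index)

    def export_metalens(self, lut: PhaseRadiusLUT,
                        cell_pitch: float | None = None) -> MetalensMask:
        """Quantize the learned phase to a fabricable nanopillar radius map.

        ``cell_pitch`` sets the unit-cell pitch recorded on the exported mask;
        it defaults to the simulation sample pitch, but a fabrication-scale
        pitch (matching the LUT) may be supplied when the simulation grid is
        coarser than the physical nanopillar lattice.
        """
        if cell_pitch is None:
            cell_pitch = self.system.sample_pitch
        return MetalensMask(radius_map=phase_to_radius(self.mask_phase(), lut),
                            lut=lut, cell_pitch=cell_pitch)

    def set_mask_phase(self, phase: np.ndarray) -> None:
        """Load a fixed phase profile (e.g. a cubic mask or a perturbed export)."""
        if self.parameterization == "height":
            k = self.system.wavenumber * (self.refractive_index - 1.0)
            self.theta.value = np.asarray(phase, dtype=float) / k
        else:
            self.theta.value = np.asarray(phase, dtype=float)

    # -- PSF --------------------------------------------------------------

    def psi(self, depth: float) -> float:
        return defocus_coefficient(depth, self.system.z0,
                                   self.system.effective_radius,
                                   self.system.wavelength)

    def psf(self, depth: float) -> np.ndarray:
        """Unit-sum PSF at a depth for the current mask (no caching)."""
        return self._psf_forward(self.psi(depth))[0]

    def _psf_forward(self, psi: float):
        n = self.system.grid_size
        phase = psi * self._defocus_unit + self.mask_phase()
        pupil = self.aperture * np.exp(1j * phase)
        m = n * self.pad_factor
        lo = (m - n) // 2
        padded = np.zeros((m, m), dtype=complex)
        padded[lo:lo + n, lo:lo + n] = pupil
        u = _centered_fft2(padded)
        p = np.abs(u) ** 2
        total = p.sum()
        return p / total, (pupil, u, p, total, lo)

    # -- forward / backward ------------------------------------------------

    def forward(self, image: np.ndarray, depth: float, out_size: int,
                noise: np.ndarray | None = None) -> np.ndarray:
        """Render the noisy sensor patch for one depth slice.

        ``noise`` is an additive array (same shape as the output) drawn by
        the caller; it is treated as a constant in the backward pass.
        """
        h, w = image.shape
        if h < out_size or w < out_size:
            raise ValueError(f"image {image.shape} smaller than crop {out_size}")
        psf, psf_cache = self._psf_forward(self.psi(depth))
        k = psf.shape[0]
        lsize = (next_fast_len(h + k - 1), next_fast_len(w + k - 1))
        fi = np.fft.fft2(image, lsize)
        fh = np.fft.fft2(psf, lsize)
        yfull = np.fft.ifft2(fi * fh).real
        c = k // 2
        ysame = yfull[c:c + h, c:c + w]
        top, left = (h - out_size) // 2, (w - out_size) // 2
        ycrop = ysame[top:top + out_size, left:left + out_size]
        pre = ycrop if noise is None else ycrop + noise
        out = np.clip(pre, 0.0, 1.0)
        self._cache = (psf, psf_cache, fi, lsize, (h, w), c, (top, left),
                       (pre > 0) & (pre < 1))
        return out

    def backward(self, dout: np.ndarray) -> None:
        """Accumulate dL/dtheta for the most recent forward call."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        (psf, (pupil, u, p, total, lo), fi, lsize, (h, w), c,
         (top, left), clip_mask) = self._cache
        self._cache = None
        k = psf.shape[0]
        dcrop = dout * clip_mask
        # un-crop to the 'same' window, then embed in the full linear-conv grid
        dsame = np.zeros((h, w))
        dsame[top:top + dcrop.shape[0], left:left + dcrop.shape[1]] = dcrop
        gfull = np.zeros(lsize)
        gfull[c:c + h, c:c + w] = dsame
        # dL/dpsf[u] = sum_s gfull[s] * image[s - u]  (correlation)
        dpsf = np.fft.ifft2(np.fft.fft2(gfull) * np.conj(fi)).real[:k, :k]
        # PSF normalization p / total
        gp = (dpsf - (dpsf * psf).sum()) / total
        # squared modulus
        gu = 2.0 * gp * u
        # centered FFT adjoint, then un-pad
        gpad = _adjoint_centered_fft2(gu)
        n = self.system.grid_size
        gpupil = gpad[lo:lo + n, lo:lo + n]
        # pupil = A exp(i phase): dL/dphase = Re(conj(g) * i * pupil)
        gphase = -np.imag(pupil * np.conj(gpupil))
        if self.parameterization == "height":
            gphase = gphase * self.system.wavenumber * (self.refractive_index - 1.0)
        self.theta.grad += gphase
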