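"""Sensor image synthesis: depth-wise PSF convolution, integration, noise.

A transparent specimen is modeled as a stack of depth slices; each slice
contributes its image convolved with the depth-dependent PSF, slices are
integrated (averaged here, to keep intensities on the [0, 1] scale without a
radiometric model), and zero-mean Gaussian read noise is added before
clipping to the sensor range.  To avoid border distortion, convolution runs
on the full (larger) source image and the result is center-cropped to the
training patch size afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["ScenePatch", "SensorImage", "render_slice", "render_sensor",
           "center_crop"]

DEFAULT_SENSOR_SIGMA = 0.01  # std of Gaussian read noise on the [0,1] scale


@dataclass(frozen=True)
class ScenePatch:
    """A single depth slice of the specimen stack, values in [0, 1]."""

    image: np.ndarray
    depth: float

    def __post_init__(self):
        img = np.asarray(self.image, dtype=float)
        if not np.all(np.isfinite(img)):
            raise ValueError("scene patch contains non-finite values")
        if img.min() < -1e-9 or img.max() > 1 + 1e-9:
            raise ValueError("scene patch values must lie in [0, 1]")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class SensorImage:
    """Encoded, noisy measurement, clipped to [0, 1]."""

    image: np.ndarray
    noise_sigma: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.image)):
            raise ValueError("sensor image contains non-finite values")


def center_crop(image: np.ndarray, size: int | tuple[int, int]) -> np.ndarray:
    """Center-crop a 2-D array to the requested size."""
    th, tw = (size, size) if np.isscalar(size) else size
    h, w = image.shape
    if h < th or w < tw:
        raise ValueError(f"cannot crop {image.shape} to {(th, tw)}")
    top, left = (h - th) // 2, (w - tw) // 2
    return image[top:top + th, left:left + tw]


def render_slice(patch: ScenePatch, psf: np.ndarray,
                 out_size: int | tuple[int, int] = 256) -> np.ndarray:
    """Blur one depth slice with its PSF, then center-crop.

    The convolution is linear (zero-padded by the PSF support via the FFT)
    and evaluated at the source image's own grid, so interior content keeps
    its flux for a unit-sum PSF; the crop discards the distorted border.
    """
    if not np.isclose(psf.sum(), 1.0, atol=1e-6):
        raise ValueError("PSF must be normalized to unit sum")
    th, tw = (out_size, out_size) if np.isscalar(out_size) else out_size
    h, w = patch.image.shape
    if h < th or w < tw:
        raise ValueError(f"patch {patch.image.shape} smaller than crop target "
                         f"{(th, tw)}")
    blurred = fftconvolve(patch.image, psf, mode="same")
    return center_crop(blurred, (th, tw))


def render_sensor(slices: list[np.ndarray], sigma: float = DEFAULT_SENSOR_SIGMA,
                  seed: int = 0) -> SensorImage:
    """Integrate rendered slices and add Gaussian sensor noise.

    Slices are averaged (a single-slice scene passes through unchanged),
    i.i.d. zero-mean Gaussian noise of standard deviation ``sigma`` is added,
    and the result is clipped to [0, 1].  Deterministic for a fixed seed.
    """
    if len(slices) == 0:
        raise ValueError("need at least one rendered slice")
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"slices disagree in shape: {shapes}")
    stack = np.mean(slices, axis=0)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, sigma, stack.shape)
    return SensorImage(image=np.clip(stack, 0.0, 1.0), noise_sigma=sigma)
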