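"""Synthetic grayscale specimen textures for training and testing.

The training corpus this emulates mixes fluorescence micrographs,
histopathology slides and natural photographs — its important property for
mask learning being a broad range of feature scales, not any particular
semantic content.  Four procedural kinds are provided:

* ``blobs`` — sparse anisotropic Gaussian spots (fluorescent puncta/nuclei);
  the ``feature_scale_range`` is the targeted autocorrelation FWHM in px.
* ``filaments`` — smoothed random-walk curves (fibers, vasculature).
* ``tissue`` — soft-thresholded band-pass Gaussian random field over a slow
  illumination gradient (histology-like cellular texture).
* ``mixed`` — blobs + filaments + multi-octave noise, guaranteeing spectral
  energy in several octave bands at once.

Everything is generated locally and deterministically per seed; no data is
downloaded or bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["TextureSpec", "generate_image", "generate_split", "SyntheticDataset"]

KINDS = ("blobs", "filaments", "tissue", "mixed")
# kinds cycled over when building a split: spots / slide-like / broad-spectrum
SPLIT_KIND_CYCLE = ("blobs", "tissue", "mixed")


@dataclass(frozen=True)
class TextureSpec:
    kind: str = "mixed"
    image_size: int = 1000
    feature_scale_range: tuple[float, float] = (5.0, 40.0)
    contrast: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.image_size < 256:
            raise ValueError("image_size must be >= 256")
        lo, hi = self.feature_scale_range
        if lo < 1 or hi < lo:
            raise ValueError("feature scales must be >= 1 px and ordered")
        clo, chi = self.contrast
        if not (0 <= clo < chi <= 1):
            raise ValueError("contrast interval must be ordered within [0, 1]")


def _blobs(rng: np.random.Generator, n: int, scale_range) -> np.ndarray:
    lo, hi = scale_range
    img = np.zeros((n, n))
    yy, xx = np.mgrid[0:n, 0:n]
    mean_scale = 0.5 * (lo + hi)
    count = max(12, int(0.5 * (n / mean_scale) ** 2))
    for _ in range(count):
        cy, cx = rng.uniform(0, n, 2)
        # autocorrelation of a Gaussian of width s has FWHM s*sqrt(2), so
        # draw the blob FWHM at scale/sqrt(2) to land inside the target range
        fwhm = rng.uniform(lo, hi) / np.sqrt(2.0)
        sig = fwhm / 2.3548
        aspect = rng.uniform(1.0, 2.0)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        amp = rng.uniform(0.3, 1.0)
        img += amp * np.exp(-0.5 * ((u / (sig * aspect)) ** 2 + (v / (sig / aspect)) ** 2))
    return img


def _filaments(rng: np.random.Generator, n: int, scale_range) -> np.ndarray:
    img = np.zeros((n, n))
    n_curves = max(6, n // 60)
    for _ in range(n_curves):
        pos = rng.uniform(0, n, 2)
        ang = rng.uniform(0, 2 * np.pi)
        length = int(rng.uniform(0.5, 1.5) * n)
        amp = rng.uniform(0.4, 1.0)
        for _ in range(length):
            ang += rng.normal(0, 0.12)
            pos = pos + np.array([np.cos(ang), np.sin(ang)])
            iy, ix = int(pos[0]) % n, int(pos[1]) % n
            img[iy, ix] += amp
    width = max(1.0, scale_range[0] / 3.0)
    return gaussian_filter(img, width)


def _tissue(rng: np.random.Generator, n: int, scale_range) -> np.ndarray:
    noise = rng.standard_normal((n, n))
    lo, hi = scale_range
    band = gaussian_filter(noise, lo / 2.355) - gaussian_filter(noise, hi / 2.355)
    band /= band.std() + 1e-12
    cells = 1.0 / (1.0 + np.exp(-3.0 * band))  # soft threshold: cell-like patches
    illum = gaussian_filter(rng.standard_normal((n, n)), n / 6.0)
    illum = (illum - illum.min()) / (np.ptp(illum) + 1e-12)
    return cells * (0.6 + 0.4 * illum)


def _multi_octave(rng: np.random.Generator, n: int) -> np.ndarray:
    img = np.zeros((n, n))
    for octave, sigma in enumerate([2.0, 4.0, 8.0, 16.0, 32.0]):
        layer = gaussian_filter(rng.standard_normal((n, n)), sigma)
        layer /= layer.std() + 1e-12
        img += layer / (octave + 1)
    return img


def generate_image(spec: TextureSpec) -> np.ndarray:
    """Deterministic [0, 1] texture; same seed always gives the same image."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    if spec.kind == "blobs":
        img = _blobs(rng, n, spec.feature_scale_range)
    elif spec.kind == "filaments":
        img = _filaments(rng, n, spec.feature_scale_range)
    elif spec.kind == "tissue":
        img = _tissue(rng, n, spec.feature_scale_range)
    else:  # mixed: several feature families so >= 3 octave bands carry energy
        img = (_blobs(rng, n, spec.feature_scale_range)
               + 0.8 * _filaments(rng, n, spec.feature_scale_range)
               + 0.6 * _multi_octave(rng, n))
    lo, hi = spec.contrast
    span = img.max() - img.min()
    if span <= 0:
        return np.full((n, n), 0.5 * (lo + hi))
    return lo + (hi - lo) * (img - img.min()) / span


@dataclass
class SyntheticDataset:
    """Lazy, seeded image collection with a reproducible manifest."""

    manifest: pd.DataFrame
    image_size: int
    _cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.manifest)

    def indices(self, split: str) -> np.ndarray:
        return self.manifest.index[self.manifest["split"] == split].to_numpy()

    def image(self, idx: int) -> np.ndarray:
        if idx not in self._cache:
            row = self.manifest.loc[idx]
            spec = TextureSpec(kind=row["kind"], image_size=self.image_size,
                               seed=int(row["seed"]))
            self._cache[idx] = generate_image(spec)
        return self._cache[idx]

    def sample_patch(self, rng: np.random.Generator, size: int,
                     split: str = "train") -> np.ndarray:
        """Random crop from a random image of the split."""
        idxs = self.indices(split)
        if len(idxs) == 0:
            raise ValueError(f"split {split!r} is empty")
        img = self.image(int(rng.choice(idxs)))
        n = img.shape[0]
        if size > n:
            raise ValueError(f"crop {size} exceeds image size {n}")
        top = int(rng.integers(0, n - size + 1))
        left = int(rng.integers(0, n - size + 1))
        return img[top:top + size, left:left + size]

    def save(self, out_dir) -> None:
        """Write 8-bit PNGs plus manifest.csv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for idx, row in self.manifest.iterrows():
            img = (np.round(self.image(idx) * 255)).astype(np.uint8)
            iio.imwrite(out / row["filename"], img)
        self.manifest.to_csv(out / "manifest.csv", index=False)


def generate_split(n_train: int, n_val: int, n_test: int, seed: int,
                   image_size: int = 1000) -> SyntheticDataset:
    """Build train/val/test image sets with disjoint per-split seed streams."""
    if min(n_train, n_val, n_test) < 0:
        raise ValueError("split sizes must be >= 0")
    streams = np.random.SeedSequence(seed).spawn(3)
    rows = []
    for split, count, stream in zip(("train", "val", "test"),
                                    (n_train, n_val, n_test), streams):
        child_seeds = stream.generate_state(max(count, 1))[:count]
        for i in range(count):
            kind = SPLIT_KIND_CYCLE[i % len(SPLIT_KIND_CYCLE)]
            rows.append({"split": split, "index": i, "kind": kind,
                         "seed": int(child_seeds[i]),
                         "filename": f"{split}_{i:05d}_{kind}.png"})
    manifest = pd.DataFrame(rows, columns=["split", "index", "kind", "seed",
                                           "filename"])
    return SyntheticDataset(manifest=manifest, image_size=image_size)
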