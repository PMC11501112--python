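# Methods

This note records the physical model, numerical conventions, parameter
choices and limitations of `edofscope`. Everything here is implemented and
tested in the package; nothing depends on external data or hardware.

## Optical model

The instrument is a 4f microscope: objective (focal length `f_obj`,
focused at `z0 = f_obj`), pupil plane carrying the phase mask, tube lens,
sensor. Light is treated as scalar, monochromatic at λ = 550 nm, and
spatially incoherent.

* **Pupil.** On an N×N grid of pitch `Δs` the pupil is
  `P = A · exp(i(φ_mask + φ_defocus))`, where `A` is the circular
  indicator of the aperture (radius `a`) — optionally multiplied by a
  metalens transmission map — and phases add.
* **Defocus.** A point at depth `z` contributes
  `φ_defocus = ψ (x² + y²)/a²` with `ψ = (π/λ)(1/z − 1/z0) a²`. Over a
  symmetric range `z0 ± Δz` the near side dominates: `ψ_max = |ψ(z0 − Δz)|`.
* **PSF.** Incoherent PSF `h = |F{P}|²`, computed with a centered FFT
  (`fftshift ∘ fft2 ∘ ifftshift`, zero frequency at index ⌊N/2⌋),
  zero-padded by a factor 2 by default to suppress circular wrap-around,
  and normalized to unit sum so that image formation is flux-preserving.
  Correctness is pinned by an O(N⁴) direct-DFT oracle, the Parseval
  identity, and the clear-aperture OTF = pupil-autocorrelation identity.
* **MTF.** `|F{h}|` normalized to 1 at DC, with a nearest-bin radial
  average. The pass-band is the largest radial frequency where the radial
  MTF still reaches 0.1. The *depth-invariance score* of a PSF stack is
  the mean pairwise RMS distance between radial MTF profiles — zero iff
  the blur is depth-invariant.
* **Sampling bound.** The steepest wavefront in the range fixes the mask
  pitch: `Δs ≤ a π / (8 ψ_max)`; the default grid is ⌈D/Δs⌉ rounded up to
  even, one sample per mask cell.

### Conventions behind the reference design table

Two values needed by the design table are not stated explicitly and were
fixed as follows (both choices reproduce the tabulated ψ_max and Δs
within 1%, except the 4× rows at ≤1.05%, and are unit-tested):

* the tabulated aperture column is read as the pupil **diameter** D, with
  `a = D/2` used in all formulas;
* `z0` equals the standard focal length of each objective class: 45 mm
  (4×, 180 mm tube), 9 mm (20×, 180 mm tube), 4 mm (50×, 200 mm tube).

## Phase-mask parameterizations

* **DOE**: etch-height map `h ≥ 0`, refractive index n = 1.5, phase
  `k (n − 1) h`.
* **Cubic (baseline)**: `α (x³ + y³)/a³` wrapped to [0, 2π), zero at the
  grid center, odd before wrapping; preset strengths α ∈ {6π, 200π, 360π}
  keyed to full depth ranges {0.2, 2, 3} mm.
* **Metalens**: per-cell nanopillar radius from a strictly monotone
  phase-vs-radius lookup table covering ≥2π; pillar diameters are bounded
  by cell pitch − 50 nm. Phase→radius inversion wraps into the table's
  branch and is exact at the knots.
* **Fabrication noise**: i.i.d. Gaussian on heights (clipped at 0) or
  radii (clipped into the LUT), σ_h ∈ {30, 50} nm, σ_r ∈ {5, 12} nm,
  seeded and reproducible.

## Differentiable layer and autodiff core

No deep-learning framework is used. `edofscope.grad` provides
reverse-mode layers (3×3/1×1 convolutions, 2×2 stride-2 transposed
convolutions, batch norm, ReLU, tanh, max-pool, Adam); every backward pass
is validated against central finite differences. The optical layer
(`optical_layer.DifferentiableOptics`) implements the adjoint of the whole
chain mask-parameter → pupil → centered FFT → |·|² → unit-sum
normalization → linear convolution → crop → noise-add → clip by hand;
its mask gradient matches finite differences to ≲2×10⁻⁶ relative error
(asserted at 10⁻³ in tests).

## Deblurring network

A residual U-Net with exactly 23 convolution layers: 5 encoder levels of
two 3×3 convolutions (each conv → ReLU → batch norm), 4 max-pools, 4
2×2-stride-2 transposed convolutions with skip concatenation, 4 decoder
double-conv blocks, and a final 1×1 head. Channels run 32 → 512 at full
width. The head output passes through tanh, is added to the input, and
clamped to [0, 1]; inputs must be multiples of 16 on each side.

## Training

Two stages over patches drawn from the synthetic corpus, augmented by
90° rotations, flips and ±10% brightness:

1. **network only** against the fixed initial optics;
2. **joint**, with separate Adam optimizers — 10⁻⁷ for the mask
   parameters, 10⁻⁴ for the network.

Each step renders the patch through the PSF of one of M = 5 depths spaced
uniformly in diopters across the target range (cycled across steps), adds
Gaussian sensor noise σ_s = 0.01, reconstructs, and minimizes the
depth-averaged RMSE. No PSF-similarity term is needed; depth invariance
emerges from the loss.

## Synthetic data

Training images are generated procedurally (sparse Gaussian puncta,
random-walk filaments, band-pass "tissue" fields, and a broad-spectrum
mixture), deterministically per seed with disjoint train/val/test seed
streams. Their relevant property is a broad range of feature scales, not
semantic content; tests pin the autocorrelation width of the puncta
fields and the multi-octave spectral support of the mixture.

## Desk-scale sizing (this package's choice)

The full-scale study configuration (32–512-channel U-Net, thousands of
1000×1000 images, ~10⁵ training steps) is far beyond a CPU test budget.
For end-to-end properties the package defines a *desk-scale* setup: the
same 23-layer topology at base width 8, a 64×64 pupil with the 50×/±100 µm
geometry (ψ_max ≈ 10.48), 32×32 patches from 256×256 images, 200 + 300
training steps, three fixed-seed replicates. Under these conditions each
replicate reduces the training loss (≈0.32 → ≈0.18) and reduces the MTF
depth-invariance score of the optics (≈0.22 → ≈0.04). These sizes are a
package decision for testability, not a claim about the full-scale
configuration.

## Limitations

* Scalar, paraxial, monochromatic, isoplanatic model: no vectorial
  high-NA effects, chromatics, or field-dependent PSFs.
* Desk-scale training is a trend check, not a quality benchmark; absolute
  PSNR/SSIM at this scale sit near the predict-the-mean floor.
* **Fabrication-robustness monotonicity does not reproduce at desk
  scale.** The σ = 0 branch of the protocol is exact by construction and
  verified. However, after only 300 joint steps the learned height map is
  a far-from-converged quasi-random diffuser (height std ≈ 0.49 µm ≈ 2.8
  rad of phase), and perturbing it at fabrication levels changes mean
  PSNR by only ±0.01–0.04 dB — not monotonically, and a deliberate sweep
  shows *large* height noise (0.2–1 µm) slightly **improves** the
  depth-averaged PSNR by acting as a weak extended-depth diffuser. The
  "noise only degrades" property evidently requires a converged
  full-scale design; the corresponding test asserts the property
  faithfully and is expected to fail (2 tests) on this desk-scale system.
* The tabulated pupil diameters of the reference designs do not follow
  the frequency-support bound with a single consistent margin; the
  package reports the bound but takes the aperture as explicit input.
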