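"""Wave-optics primitives: defocus calculus, PSF/MTF against direct oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edofscope.optics_core import (DepthSpec, OBJECTIVE_PRESETS, OpticalSystem,
                                   PupilField, assemble_pupil,
                                   defocus_coefficient, defocus_phase_map,
                                   design_report, max_defocus,
                                   max_sampling_pitch, min_pupil_radius,
                                   mtf_from_psf, psf_from_pupil, psf_stack,
                                   radial_average)
from conftest import make_system

LAMBDA = 550e-9
A50 = 1.07e-3 / 2


def direct_dft2_centered(field: np.ndarray) -> np.ndarray:
    """O(N^4) centered DFT oracle (zero frequency at index N//2)."""
    n = field.shape[0]
    c = n // 2
    k = np.arange(n) - c
    # exp(-2 pi i (u m + v n)/N) with centered indices on both sides
    w = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return w @ field @ w.T


class TestDefocusCalculus:
    @pytest.mark.parametrize("z,z0,a,expected,rtol", [
        (2.5e-3, 4e-3, A50, 245.54, 0.01),   # printed +/-1.5 mm row
        (3e-3, 4e-3, A50, 136.24, 0.01),     # printed +/-1 mm row
        (4e-3, 4e-3, A50, 0.0, 0.0),         # in focus
    ])
    def test_reference_values(self, z, z0, a, expected, rtol):
        psi = defocus_coefficient(z, z0, a, LAMBDA)
        if expected == 0:
            assert psi == 0.0
        else:
            assert psi == pytest.approx(expected, rel=rtol)

    def test_sign_indicates_direction(self):
        assert defocus_coefficient(3e-3, 4e-3, A50, LAMBDA) > 0
        assert defocus_coefficient(5e-3, 4e-3, A50, LAMBDA) < 0

    @pytest.mark.parametrize("z,z0", [(0, 4e-3), (-1e-3, 4e-3), (4e-3, 0)])
    def test_nonpositive_depth_rejected(self, z, z0):
        with pytest.raises(ValueError):
            defocus_coefficient(z, z0, A50, LAMBDA)

    def test_max_defocus_near_side_dominates(self):
        spec = DepthSpec.symmetric(4e-3, 1e-3)
        psi = max_defocus(spec, A50, LAMBDA)
        assert psi == pytest.approx(136.24, rel=0.01)
        assert psi == pytest.approx(
            abs(defocus_coefficient(3e-3, 4e-3, A50, LAMBDA)))

    def test_max_defocus_100um(self):
        assert max_defocus(DepthSpec.symmetric(4e-3, 1e-4), A50, LAMBDA) \
            == pytest.approx(10.48, rel=0.01)

    @given(st.floats(min_value=1e-5, max_value=2e-3))
    @settings(max_examples=30, deadline=None)
    def test_symmetric_range_antisymmetry(self, dz):
        """|psi| at the near end strictly exceeds |psi| at the far end."""
        z0 = 4e-3
        near = abs(defocus_coefficient(z0 - dz, z0, A50, LAMBDA))
        far = abs(defocus_coefficient(z0 + dz, z0, A50, LAMBDA))
        assert near > far

    def test_table_consistency_all_verified_rows(self):
        """Reference system-parameter rows reproduced within 1 percent."""
        rows = [("rms20x", 1e-4, 14.69), ("mitutoyo50x", 1e-4, 10.48),
                ("mitutoyo50x", 1e-3, 136.24), ("mitutoyo50x", 1.5e-3, 245.54)]
        for name, dz, expected in rows:
            p = OBJECTIVE_PRESETS[name]
            psi = max_defocus(DepthSpec.symmetric(p["z0"], dz),
                              p["pupil_diameter"] / 2, LAMBDA)
            assert psi == pytest.approx(expected, rel=0.01), name


class TestSamplingBounds:
    def test_reference_pitch_values(self):
        assert max_sampling_pitch(A50, 136.24) == pytest.approx(1.54e-6, rel=0.01)
        assert max_sampling_pitch(A50, 245.54) == pytest.approx(0.858e-6, rel=0.01)
        assert max_sampling_pitch(2.87e-3 / 2, 14.69) == pytest.approx(38e-6, abs=1e-6)

    def test_inverse_proportionality(self):
        assert max_sampling_pitch(A50, 200.0) == pytest.approx(
            max_sampling_pitch(A50, 100.0) / 2)

    def test_zero_defocus_signalled(self):
        with pytest.raises(ValueError):
            max_sampling_pitch(A50, 0.0)

    def test_min_pupil_radius(self):
        k = 2 * np.pi / LAMBDA
        assert min_pupil_radius(0.2, k, 0.0, 0.0) == 0.0
        # kx = k*NA gives r = f1*NA
        assert min_pupil_radius(0.2, k, k * 0.42, 0.0) == pytest.approx(0.084)
        r1 = min_pupil_radius(0.2, k, 1e5, 2e5)
        assert min_pupil_radius(0.2, k, 3e5, 6e5) == pytest.approx(3 * r1)


class TestPupilAndPhase:
    def test_defocus_phase_profile(self, system16):
        psi = 7.5
        phase = defocus_phase_map(system16, psi)
        c = system16.grid_size // 2
        assert phase[c, c] == 0.0
        # at radius a from center the phase equals psi exactly (even grid:
        # the -a sample sits at index 0, +a falls just off the grid)
        steps = round(system16.effective_radius / system16.sample_pitch)
        assert phase[c, c - steps] == pytest.approx(psi, rel=1e-12)
        # quadratic: at a/2 the phase is psi/4
        assert phase[c, c - steps // 2] == pytest.approx(psi / 4, rel=1e-12)

    def test_zero_psi_gives_zero_map(self, system16):
        assert np.all(defocus_phase_map(system16, 0.0) == 0.0)

    def test_assemble_pupil_additive_and_circular(self, system16):
        n = system16.grid_size
        m1 = np.full((n, n), 0.3)
        m2 = np.full((n, n), 0.5)
        p12 = assemble_pupil(system16, m1, m2)
        p21 = assemble_pupil(system16, m2, m1)
        np.testing.assert_array_equal(p12.phase, p21.phase)
        assert set(np.unique(p12.amplitude)) <= {0.0, 1.0}
        assert p12.amplitude[n // 2, n // 2] == 1.0

    def test_assemble_pupil_shape_mismatch(self, system16):
        with pytest.raises(ValueError):
            assemble_pupil(system16, np.zeros((8, 8)), np.zeros((16, 16)))


class TestPSF:
    def test_matches_direct_dft_oracle(self, system16):
        rng = np.random.default_rng(0)
        pupil = assemble_pupil(system16, rng.uniform(-2, 2, (16, 16)),
                               defocus_phase_map(system16, 3.0))
        psf = psf_from_pupil(pupil, pad_factor=1)
        u = direct_dft2_centered(pupil.complex_field())
        expected = np.abs(u) ** 2
        expected /= expected.sum()
        np.testing.assert_allclose(psf, expected, rtol=1e-10, atol=1e-22)

    def test_parseval_identity(self, system16):
        """Pre-normalization PSF energy equals N^2 * sum |P|^2."""
        rng = np.random.default_rng(1)
        pupil = assemble_pupil(system16, rng.uniform(0, 6, (16, 16)),
                               np.zeros((16, 16)))
        p = pupil.complex_field()
        u = direct_dft2_centered(p)
        assert np.sum(np.abs(u) ** 2) == pytest.approx(
            p.size * np.sum(np.abs(p) ** 2), rel=1e-12)

    def test_unit_sum_and_nonnegative(self, system64):
        pupil = assemble_pupil(system64, np.zeros((64, 64)),
                               defocus_phase_map(system64, 10.0))
        psf = psf_from_pupil(pupil)
        assert psf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(psf >= 0)

    def test_clear_aperture_airy_like(self, system64):
        psf = psf_from_pupil(assemble_pupil(system64, np.zeros((64, 64)),
                                            np.zeros((64, 64))))
        m = psf.shape[0]
        assert psf.argmax() == (m // 2) * m + m // 2
        # four-fold symmetry about the center (even grid: mirror within bulk)
        np.testing.assert_allclose(psf[1:, 1:], psf[1:, 1:][::-1, ::-1], atol=1e-12)

    def test_linear_phase_ramp_translates_psf(self, system16):
        n = 16
        base = assemble_pupil(system16, np.zeros((n, n)), np.zeros((n, n)))
        cc = np.arange(n) - n // 2
        ramp = 2 * np.pi * 2 * cc[None, :] / n  # integer-bin shift, pad_factor 1
        shifted = assemble_pupil(system16, np.broadcast_to(ramp, (n, n)).copy(),
                                 np.zeros((n, n)))
        p0 = psf_from_pupil(base, pad_factor=1)
        p1 = psf_from_pupil(shifted, pad_factor=1)
        # exp(+i 2 pi s m / N) in the pupil shifts the PSF by +s samples:
        # U(u) = sum_m P(m) exp(i 2 pi (s - u) m / N) peaks at u = s
        np.testing.assert_allclose(np.roll(p0, 2, axis=1), p1, atol=1e-12)

    def test_empty_pupil_rejected(self, system16):
        dead = PupilField(amplitude=np.zeros((16, 16)), phase=np.zeros((16, 16)))
        with pytest.raises(ValueError):
            psf_from_pupil(dead)


class TestMTF:
    def test_delta_psf_flat_mtf(self):
        psf = np.zeros((32, 32))
        psf[16, 16] = 1.0
        mtf = mtf_from_psf(psf)
        np.testing.assert_allclose(mtf.magnitude, 1.0, atol=1e-12)
        np.testing.assert_allclose(mtf.radial, 1.0, atol=1e-12)

    def test_translation_invariance(self, system16):
        pupil = assemble_pupil(system16, np.zeros((16, 16)),
                               defocus_phase_map(system16, 2.0))
        psf = psf_from_pupil(pupil, pad_factor=2)
        m0 = mtf_from_psf(psf).magnitude
        m1 = mtf_from_psf(np.roll(psf, (3, -2), axis=(0, 1))).magnitude
        np.testing.assert_allclose(m0, m1, atol=1e-10)

    def test_dc_is_one_and_bounded(self, system64):
        pupil = assemble_pupil(system64, np.zeros((64, 64)),
                               defocus_phase_map(system64, 10.48))
        mtf = mtf_from_psf(psf_from_pupil(pupil))
        n = mtf.magnitude.shape[0]
        assert mtf.magnitude[n // 2, n // 2] == pytest.approx(1.0)
        assert np.all(mtf.magnitude <= 1.0 + 1e-12)

    def test_clear_aperture_equals_disc_autocorrelation(self, system16):
        """Incoherent OTF = autocorrelation of the pupil (oracle: direct sums)."""
        pupil = assemble_pupil(system16, np.zeros((16, 16)), np.zeros((16, 16)))
        psf = psf_from_pupil(pupil, pad_factor=2)
        mtf = mtf_from_psf(psf)
        p = np.zeros((32, 32))
        p[8:24, 8:24] = pupil.amplitude
        auto = np.zeros((32, 32))
        for du in range(-16, 16):
            for dv in range(-16, 16):
                auto[16 + du, 16 + dv] = np.sum(
                    p * np.roll(np.roll(p, du, axis=0), dv, axis=1))
        auto /= auto.max()
        np.testing.assert_allclose(mtf.magnitude, auto, atol=1e-9)

    def test_radial_average_bins(self):
        mag = np.ones((8, 8))
        freqs = np.fft.fftshift(np.fft.fftfreq(8, d=1.0))
        rf, prof = radial_average(mag, freqs)
        assert len(prof) == 4
        np.testing.assert_allclose(prof, 1.0)
        assert rf[1] - rf[0] == pytest.approx(freqs[5] - freqs[4])


class TestSystemConstruction:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_system(8)  # grid too small
        with pytest.raises(ValueError):
            OpticalSystem(wavelength=-1, tube_focal_length=0.2,
                          objective_focal_length=4e-3, pupil_aperture=1e-3,
                          grid_size=16, sample_pitch=1e-3 / 16)

    def test_grid_spans_aperture(self):
        with pytest.raises(ValueError):
            OpticalSystem(wavelength=550e-9, tube_focal_length=0.2,
                          objective_focal_length=4e-3, pupil_aperture=1e-3,
                          grid_size=16, sample_pitch=1e-6)

    def test_from_objective_design(self):
        spec = DepthSpec.symmetric(4e-3, 1e-3)
        system = OpticalSystem.from_objective("mitutoyo50x", depth_spec=spec)
        assert system.sample_pitch <= 1.55e-6
        assert system.grid_size % 2 == 0
        assert system.grid_size * system.sample_pitch >= system.pupil_aperture

    def test_design_report(self):
        row = design_report("mitutoyo50x", 1e-3)
        assert row["psi_max"] == pytest.approx(136.24, rel=0.01)
        assert row["delta_s_max_m"] == pytest.approx(1.54e-6, rel=0.01)

    def test_psf_stack_shapes(self, system16):
        stack = psf_stack(system16, np.zeros((16, 16)), [3.9e-3, 4e-3, 4.1e-3])
        assert len(stack.psfs) == 3
        for psf in stack.psfs:
            assert psf.sum() == pytest.approx(1.0, abs=1e-9)
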