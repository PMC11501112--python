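"""Phase-mask parameterizations: DOE, cubic, metalens LUT, perturbations."""

import numpy as np
import pytest

from edofscope.optics_core import assemble_pupil, psf_from_pupil
from edofscope.phase_masks import (CUBIC_ALPHA_PRESETS, CubicMask, DOEMask,
                                   MetalensMask, PhaseRadiusLUT, cubic_phase,
                                   doe_phase, perturb_mask, phase_to_radius,
                                   radius_to_phase, synthetic_lut)

TWO_PI = 2 * np.pi
K550 = TWO_PI / 550e-9


class TestDOE:
    def test_zero_height_zero_phase(self):
        mask = DOEMask(height_map=np.zeros((8, 8)))
        assert np.all(doe_phase(mask, K550) == 0.0)

    @pytest.mark.parametrize("height,expected", [
        (1100e-9, TWO_PI),   # one full wave at n = 1.5
        (550e-9, np.pi),
    ])
    def test_phase_per_height(self, height, expected):
        mask = DOEMask(height_map=np.full((4, 4), height))
        np.testing.assert_allclose(doe_phase(mask, K550), expected, rtol=1e-12)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            DOEMask(height_map=np.full((4, 4), -1e-9))

    def test_bad_index_rejected(self):
        with pytest.raises(ValueError):
            DOEMask(height_map=np.zeros((4, 4)), refractive_index=1.0)


class TestCubic:
    def test_origin_zero_and_range(self):
        phase = cubic_phase(CubicMask(alpha=6 * np.pi, grid_size=16))
        assert phase[8, 8] == 0.0
        assert np.all((phase >= 0) & (phase < TWO_PI))

    def test_raw_profile_is_odd(self):
        mask = CubicMask(alpha=200 * np.pi, grid_size=17)
        raw = mask.raw_phase()
        # raw(-x, -y) = -raw(x, y) about the central sample
        np.testing.assert_allclose(raw, -raw[::-1, ::-1], atol=1e-9)

    def test_presets_by_dof_target(self):
        assert CubicMask.for_dof_range(200e-6, 16).alpha == pytest.approx(6 * np.pi)
        assert CubicMask.for_dof_range(2e-3, 16).alpha == pytest.approx(200 * np.pi)
        assert CubicMask.for_dof_range(3e-3, 16).alpha == pytest.approx(360 * np.pi)
        assert set(CUBIC_ALPHA_PRESETS) == {200e-6, 2e-3, 3e-3}


class TestLUT:
    def test_validation(self):
        with pytest.raises(ValueError):  # non-increasing radii
            PhaseRadiusLUT(radii=[1e-7, 1e-7], phases=[0, TWO_PI],
                           transmissions=[1, 1])
        with pytest.raises(ValueError):  # insufficient phase span
            PhaseRadiusLUT(radii=[1e-7, 2e-7], phases=[0, np.pi],
                           transmissions=[1, 1])

    def test_synthetic_lut_respects_cell_pitch(self):
        lut = synthetic_lut(1e-6)
        assert lut.r_max == pytest.approx((1e-6 - 50e-9) / 2)
        assert lut.phases[-1] - lut.phases[0] >= TWO_PI - 1e-9
        assert np.all(lut.transmissions == 1.0)

    def test_radius_to_phase_endpoints_and_monotone(self):
        lut = synthetic_lut(1e-6)
        assert radius_to_phase(np.array(lut.r_min), lut) == pytest.approx(lut.phases[0])
        r = np.linspace(lut.r_min, lut.r_max, 50)
        phases = radius_to_phase(r, lut)
        assert np.all(np.diff(phases) >= 0)

    def test_midpoint_linear_interpolation(self):
        lut = PhaseRadiusLUT(radii=[100e-9, 200e-9, 300e-9],
                             phases=[0.0, 2.0, TWO_PI],
                             transmissions=[1, 1, 1])
        assert radius_to_phase(np.array(150e-9), lut) == pytest.approx(1.0)

    def test_out_of_range_names_cell(self):
        lut = synthetic_lut(1e-6)
        bad = np.full((3, 3), lut.r_min)
        bad[1, 2] = lut.r_max * 2
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            radius_to_phase(bad, lut)

    def test_round_trip_phase_radius_phase(self):
        """phase -> radius -> phase is the identity mod 2 pi (100 samples)."""
        lut = synthetic_lut(1e-6, n_points=256)
        rng = np.random.default_rng(0)
        phases = rng.uniform(-10, 10, 100)
        radii = phase_to_radius(phases, lut)
        back = radius_to_phase(radii, lut)
        np.testing.assert_allclose(np.mod(back - phases, TWO_PI) % TWO_PI, 0,
                                   atol=1e-3)

    def test_inversion_exact_at_knots(self):
        lut = synthetic_lut(1e-6, n_points=32)
        knot_phases = lut.phases[:-1]  # 2 pi wraps to 0 by convention
        np.testing.assert_allclose(phase_to_radius(knot_phases, lut),
                                   lut.radii[:-1], rtol=1e-12)

    def test_exact_two_pi_maps_to_zero_phase_radius(self):
        lut = synthetic_lut(1e-6)
        assert phase_to_radius(np.array(TWO_PI), lut) == pytest.approx(lut.r_min)

    def test_output_diameters_respect_pitch(self):
        lut = synthetic_lut(1e-6)
        rng = np.random.default_rng(1)
        radii = phase_to_radius(rng.uniform(0, TWO_PI, (16, 16)), lut)
        assert np.all(2 * radii <= 1e-6 - 50e-9 + 1e-15)

    def test_non_monotone_lut_rejected(self):
        lut = PhaseRadiusLUT(radii=[1e-7, 2e-7, 3e-7], phases=[0, 7.0, TWO_PI],
                             transmissions=[1, 1, 1])
        with pytest.raises(ValueError):
            phase_to_radius(np.zeros((2, 2)), lut)

    def test_csv_round_trip(self, tmp_path):
        lut = synthetic_lut(1e-6, n_points=16)
        path = tmp_path / "lut.csv"
        lut.to_csv(path)
        back = PhaseRadiusLUT.from_csv(path)
        np.testing.assert_allclose(back.radii, lut.radii, rtol=1e-9)
        np.testing.assert_allclose(back.phases, lut.phases, rtol=1e-12)


class TestMetalens:
    def test_constraints(self):
        lut = synthetic_lut(1e-6)
        with pytest.raises(ValueError):
            MetalensMask(radius_map=np.full((4, 4), 1e-6), lut=lut,
                         cell_pitch=1e-6)

    def test_pupil_phase_on_grid(self, system16):
        lut = synthetic_lut(system16.sample_pitch)
        radii = np.full((16, 16), (lut.r_min + lut.r_max) / 2)
        mask = MetalensMask(radius_map=radii, lut=lut,
                            cell_pitch=system16.sample_pitch)
        phase = mask.pupil_phase(system16)
        assert phase.shape == (16, 16)
        np.testing.assert_allclose(mask.transmission_map(), 1.0)


class TestLosslessContract:
    def test_phase_only_masks_preserve_energy(self, system16):
        """Replacing the mask phase never changes total PSF energy."""
        rng = np.random.default_rng(2)
        defocus = np.zeros((16, 16))
        base = psf_from_pupil(assemble_pupil(system16, np.zeros((16, 16)), defocus))
        for _ in range(3):
            phase = rng.uniform(-np.pi, np.pi, (16, 16))
            psf = psf_from_pupil(assemble_pupil(system16, phase, defocus))
            assert psf.sum() == pytest.approx(base.sum(), rel=1e-12)


class TestPerturbation:
    def test_sigma_zero_identity(self):
        mask = DOEMask(height_map=np.full((8, 8), 100e-9))
        assert perturb_mask(mask, 0.0, seed=1) is mask

    def test_reproducible_and_correct_std(self):
        mask = DOEMask(height_map=np.full((100, 100), 500e-9))
        a = perturb_mask(mask, 30e-9, seed=42)
        b = perturb_mask(mask, 30e-9, seed=42)
        np.testing.assert_array_equal(a.height_map, b.height_map)
        resid = a.height_map - mask.height_map
        assert np.std(resid) == pytest.approx(30e-9, rel=0.05)

    @pytest.mark.parametrize("sigma", [5e-9, 12e-9])
    def test_metalens_levels_stay_in_lut(self, sigma):
        lut = synthetic_lut(1e-6)
        radii = np.full((50, 50), lut.r_min + 5e-9)  # near the lower bound
        mask = MetalensMask(radius_map=radii, lut=lut, cell_pitch=1e-6)
        noisy = perturb_mask(mask, sigma, seed=0)
        assert np.all(noisy.radius_map >= lut.r_min)
        assert np.all(2 * noisy.radius_map <= mask.max_diameter + 1e-15)

    def test_doe_heights_clipped_nonnegative(self):
        mask = DOEMask(height_map=np.full((50, 50), 10e-9))
        noisy = perturb_mask(mask, 50e-9, seed=3)
        assert np.all(noisy.height_map >= 0)

    def test_unknown_type_rejected(self):
        with pytest.raises(TypeError):
            perturb_mask(object(), 1e-9, seed=0)
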