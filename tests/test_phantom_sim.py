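"""Phantom FEM, scatterer handling and the convolution RF model."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import label

from ultrastrain.phantom_sim import (PhantomSpec, Scatterers, TransducerSpec,
                                     _region_ratio, calibrate_contrast,
                                     displace_scatterers, make_pair,
                                     make_scatterers, simulate_rf, solve_fem)
from ultrastrain.rf_frames import ValidationError
from ultrastrain.strain_metrics import binarize


def homog_spec(compression=0.6e-3, mesh_n=32, E=2.0e4):
    return PhantomSpec(e_inclusion=E, e_background=E, inclusion_radius=0.0,
                       compression=compression, mesh_n=mesh_n)


SMALL_TSPEC = TransducerSpec(n_lines=32, line_spacing=0.020 / 32)


class TestFEM:
    def test_homogeneous_patch_test(self):
        # uniform closed form: strain = compression / height, here 3%
        truth = solve_fem(homog_spec())
        interior = truth.strain_axial[2:-2, 2:-2]
        assert np.all(np.abs(interior - 0.03) < 0.01 * 0.03)

    def test_transducer_frame_boundary_conditions(self):
        truth = solve_fem(homog_spec())
        assert truth.axial_at(0.0, 0.010) == pytest.approx(0.0, abs=1e-12)
        assert truth.axial_at(0.020, 0.010) == pytest.approx(-0.6e-3, abs=1e-12)
        assert truth.axial_at(0.010, 0.010) == pytest.approx(-0.3e-3, rel=1e-6)

    def test_zero_compression_zero_fields(self):
        truth = solve_fem(homog_spec(compression=0.0))
        assert np.all(truth.axial_disp == 0.0)
        assert np.all(truth.lateral_disp == 0.0)
        assert np.all(truth.strain_axial == 0.0)

    def test_lateral_expansion_near_incompressible(self):
        # plane strain: lateral strain = nu/(1-nu) * axial ~ 0.98 * 3%
        truth = solve_fem(homog_spec())
        edge = truth.lateral_at(0.010, 0.0199)
        expected = 0.495 / (1 - 0.495) * 0.03 * 0.010   # half-width expansion
        assert edge == pytest.approx(expected, rel=0.02)

    def test_stiff_inclusion_strains_less(self):
        spec = PhantomSpec(compression=0.6e-3, e_background=1.3e4, mesh_n=40)
        truth = solve_fem(spec)
        zz, xx = np.meshgrid(truth.z_el, truth.x_el, indexing="ij")
        inside = (zz - 0.010) ** 2 + (xx - 0.010) ** 2 <= 0.003 ** 2
        assert truth.strain_axial[inside].mean() < truth.strain_axial[~inside].mean()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(poisson=0.5)
        with pytest.raises(ValidationError):
            PhantomSpec(compression=0.003)     # > 10% of height
        with pytest.raises(ValidationError):
            PhantomSpec(inclusion_center=(0.001, 0.010))

    def test_mesh_convergence_of_contrast_ratio(self):
        spec = PhantomSpec(compression=0.6e-3, e_background=1.3e4, mesh_n=40)
        r40 = _region_ratio(solve_fem(spec), spec)
        spec80 = dataclasses.replace(spec, mesh_n=80)
        r80 = _region_ratio(solve_fem(spec80), spec80)
        assert abs(r80 - r40) / r80 < 0.02


class TestCalibration:
    def test_target_one_returns_inclusion_modulus(self):
        spec = PhantomSpec(compression=0.6e-3, mesh_n=32)
        assert calibrate_contrast(spec, 1.0) == spec.e_inclusion

    def test_target_five_verified_by_rerun(self):
        spec = PhantomSpec(compression=0.6e-3, mesh_n=40)
        e_bg = calibrate_contrast(spec, 5.0)
        check = dataclasses.replace(spec, e_background=e_bg)
        assert _region_ratio(solve_fem(check), check) == pytest.approx(5.0, abs=0.1)

    def test_softer_background_strains_more(self):
        spec = PhantomSpec(compression=0.6e-3, mesh_n=32)
        ratios = []
        for e_bg in (5.0e4, 2.0e4, 1.0e4):
            s = dataclasses.replace(spec, e_background=e_bg)
            ratios.append(_region_ratio(solve_fem(s), s))
        assert ratios[0] < ratios[1] < ratios[2]

    def test_invalid_target_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_contrast(PhantomSpec(mesh_n=32), 0.5)

    def test_truth_map_metrics(self, small_pair, small_cfg):
        # on the FEM truth itself: ratio ~ configured contrast; the
        # mean-thresholded binary image blackens the inclusion center
        from ultrastrain import pipeline as pl
        _, _, truth, spec = small_pair
        grid = np.zeros((64, 64))
        from ultrastrain.rf_frames import StrainMap
        z = np.linspace(0, spec.height, 64)
        x = np.linspace(0, spec.width, 64)
        zz, xx = np.meshgrid(z, x, indexing="ij")
        smap = StrainMap(truth.strain_at(zz, xx),
                         z * 2 * small_cfg.fs / small_cfg.c,
                         x / small_cfg.line_spacing,
                         fs=small_cfg.fs, c=small_cfg.c,
                         line_spacing=small_cfg.line_spacing)
        from ultrastrain.strain_metrics import strain_ratio
        inc, bg = pl.default_rois(small_cfg)
        measured = strain_ratio(smap, inc, bg)
        expected = _region_ratio(truth, spec, roi_radius=small_cfg.roi_radius,
                                 bg_offset=small_cfg.roi_bg_offset)
        assert measured == pytest.approx(expected, rel=0.15)
        binary = binarize(smap)
        iz = np.argmin(np.abs(z - spec.inclusion_center[0]))
        ix = np.argmin(np.abs(x - spec.inclusion_center[1]))
        assert binary[iz, ix]
        lab, _ = label(binary)
        assert (lab == lab[iz, ix]).sum() >= 0.5 * np.pi * (
            spec.inclusion_radius / (z[1] - z[0])) ** 2


class TestScatterers:
    spec = PhantomSpec(compression=0.6e-3, mesh_n=16)

    def test_reproducible_from_seed(self):
        a = make_scatterers(self.spec, SMALL_TSPEC, 5)
        b = make_scatterers(self.spec, SMALL_TSPEC, 5)
        assert np.array_equal(a.z, b.z) and np.array_equal(a.amp, b.amp)

    def test_count_within_poisson_bounds(self):
        lam = SMALL_TSPEC.scatterer_density * 400.0   # 20/mm^2 * 400 mm^2
        n = len(make_scatterers(self.spec, SMALL_TSPEC, 6).z)
        assert abs(n - lam) < 3 * np.sqrt(lam)

    def test_different_seeds_decorrelated(self):
        a = make_scatterers(self.spec, SMALL_TSPEC, 1)
        b = make_scatterers(self.spec, SMALL_TSPEC, 2)
        ha, _, _ = np.histogram2d(a.z, a.x, bins=20,
                                  range=[[0, 0.02], [0, 0.02]])
        hb, _, _ = np.histogram2d(b.z, b.x, bins=20,
                                  range=[[0, 0.02], [0, 0.02]])
        r = np.corrcoef(ha.ravel(), hb.ravel())[0, 1]
        assert abs(r) < 0.15

    def test_displacement_follows_truth_field(self):
        truth = solve_fem(homog_spec())
        sc = Scatterers(z=np.array([0.0, 0.010, 0.020]),
                        x=np.full(3, 0.010), amp=np.ones(3))
        moved = displace_scatterers(sc, truth)
        assert moved.z[0] == pytest.approx(0.0, abs=1e-9)         # top: no shift
        assert moved.z[1] == pytest.approx(0.010 - 0.3e-3, rel=1e-6)
        assert moved.z[2] == pytest.approx(0.020 - 0.6e-3, rel=1e-6)

    def test_outside_domain_clipped_with_warning(self):
        truth = solve_fem(homog_spec())
        sc = Scatterers(z=np.array([0.025]), x=np.array([0.010]),
                        amp=np.ones(1))
        with pytest.warns(UserWarning, match="clipped"):
            displace_scatterers(sc, truth)


class TestRFModel:
    def test_single_scatterer_peak_position(self):
        tspec = dataclasses.replace(SMALL_TSPEC, noise_snr=200.0)
        z0 = 0.008
        sc = Scatterers(z=np.array([z0]),
                        x=np.array([tspec.line_positions()[10]]),
                        amp=np.ones(1))
        frame = simulate_rf(sc, tspec, 0)
        expected = round(2 * z0 * tspec.fs / tspec.c)
        peak = np.argmax(np.abs(frame.samples[:, 10]))
        # RF magnitude peaks within half a carrier period of the echo center
        assert abs(peak - expected) <= tspec.fs / tspec.f0 / 2

    def test_moving_scatterer_shifts_echo(self):
        tspec = dataclasses.replace(SMALL_TSPEC, noise_snr=200.0)
        x0 = tspec.line_positions()[5]
        dz = 0.4e-3
        a = simulate_rf(Scatterers(np.array([0.008]), np.array([x0]),
                                   np.ones(1)), tspec, 0)
        b = simulate_rf(Scatterers(np.array([0.008 + dz]), np.array([x0]),
                                   np.ones(1)), tspec, 0)
        shift = np.argmax(np.abs(b.samples[:, 5])) - np.argmax(np.abs(a.samples[:, 5]))
        assert shift == pytest.approx(2 * dz * tspec.fs / tspec.c, abs=2)

    def test_speckle_spectrum_peaks_near_carrier(self):
        spec = PhantomSpec(compression=0.6e-3, mesh_n=16)
        sc = make_scatterers(spec, SMALL_TSPEC, 3)
        frame = simulate_rf(sc, SMALL_TSPEC, 3)
        power = np.mean(np.abs(np.fft.rfft(frame.samples, axis=0)) ** 2, axis=1)
        freqs = np.fft.rfftfreq(frame.n_samples, 1 / frame.fs)
        peak_f = freqs[np.argmax(power)]
        assert abs(peak_f - frame.f0) / frame.f0 < 0.10


class TestMakePair:
    def test_same_seed_bitwise_identical(self):
        spec = homog_spec(mesh_n=16)
        truth = solve_fem(spec)
        a = make_pair(spec, SMALL_TSPEC, 11, truth=truth)
        b = make_pair(spec, SMALL_TSPEC, 11, truth=truth)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert np.array_equal(a[1].samples, b[1].samples)

    def test_zero_compression_pair_identical_up_to_noise(self):
        spec = homog_spec(compression=0.0, mesh_n=16)
        pre, post, _ = make_pair(spec, SMALL_TSPEC, 12)
        r = np.corrcoef(pre.samples.ravel(), post.samples.ravel())[0, 1]
        assert r > 0.99       # only the independent noise draws differ

    def test_line_layout_must_fit_phantom(self):
        spec = homog_spec(mesh_n=16)
        bad = dataclasses.replace(SMALL_TSPEC, line_spacing=0.001)
        with pytest.raises(ValidationError, match="width"):
            make_pair(spec, bad, 0)
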