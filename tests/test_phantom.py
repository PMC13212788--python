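"""Phantom generator: geometry, CEUS loops, analytic bolus, SWE, histology."""

import numpy as np
import pytest

from mpuscad.cudi_temporal import mldrw_curve
from mpuscad.phantom import (
    AliasingError,
    InfeasiblePrevalenceError,
    PhantomConfig,
    generate_geometry,
    generate_study,
    iq_from_velocity,
    simulate_ceus_loop,
    simulate_dispersion_field,
    simulate_swe_planes,
    slice_histology,
)


class TestGeometry:
    def test_no_lesions_empty_mask(self):
        study = generate_geometry(PhantomConfig(n_lesions=0, seed=1))
        assert not study.lesion_mask.any()

    def test_determinism(self):
        a = generate_geometry(PhantomConfig(seed=5))
        b = generate_geometry(PhantomConfig(seed=5))
        for name in ("prostate_mask", "pz_mask", "tz_mask", "lesion_mask"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_zone_partition(self):
        s = generate_geometry(PhantomConfig(seed=2))
        assert not (s.pz_mask & s.tz_mask).any()
        assert np.array_equal(s.pz_mask | s.tz_mask, s.prostate_mask)
        assert np.all(s.lesion_mask <= s.prostate_mask)

    def test_prevalence_hits_target_on_large_grid(self):
        s = generate_geometry(
            PhantomConfig(grid_shape=(48, 48, 48), voxel_size_mm=1.5, seed=3)
        )
        assert 0.04 <= s.prevalence <= 0.06

    @pytest.mark.parametrize("seed", range(10))
    def test_prevalence_within_band_across_seeds(self, seed):
        s = generate_geometry(PhantomConfig(seed=seed))
        assert abs(s.prevalence - 0.05) / 0.05 <= 0.20

    def test_infeasible_prevalence_raises(self):
        with pytest.raises(InfeasiblePrevalenceError):
            generate_geometry(
                PhantomConfig(
                    n_lesions=1, lesion_radius_mm_range=(20.0, 22.0),
                    target_prevalence=0.01, seed=1,
                )
            )


class TestCeusLoop:
    def test_zero_noise_matches_forward_model(self, small_study):
        loop = small_study.ceus_loop
        m = small_study.prostate_mask
        tm = small_study.truth_maps
        expected = mldrw_curve(
            loop.time_s, tm["true_kappa"][m], tm["true_mu"][m],
            tm["true_t0"][m], tm["true_auc"][m],
        )
        assert np.array_equal(loop.data[m], expected)

    def test_higher_lesion_kappa_peaks_earlier(self, small_study):
        loop = small_study.ceus_loop
        les = small_study.lesion_mask
        bg = small_study.prostate_mask & ~les
        t_peak_les = loop.time_s[loop.data[les].mean(axis=0).argmax()]
        t_peak_bg = loop.time_s[loop.data[bg].mean(axis=0).argmax()]
        assert t_peak_les < t_peak_bg

    def test_truth_maps_differ_across_seeds(self):
        cfg = dict(grid_shape=(16, 16, 16), voxel_size_mm=3.0)
        a = generate_geometry(PhantomConfig(seed=1, **cfg))
        simulate_ceus_loop(a)
        b = generate_geometry(PhantomConfig(seed=2, **cfg))
        simulate_ceus_loop(b)
        assert not np.array_equal(
            np.nan_to_num(a.truth_maps["true_kappa"]),
            np.nan_to_num(b.truth_maps["true_kappa"]),
        )

    def test_short_duration_warns(self):
        cfg = PhantomConfig(grid_shape=(16, 16, 16), voxel_size_mm=3.0,
                            duration_s=30.0, seed=4)
        s = generate_geometry(cfg)
        with pytest.warns(UserWarning, match="truncated"):
            simulate_ceus_loop(s, cfg)


class TestDispersionField:
    def test_zero_velocity_spherically_symmetric(self):
        t = np.arange(0, 5, 0.5)
        vol, _ = simulate_dispersion_field((15, 15, 15), 1.0, t, (0, 0, 0), 1.0)
        frame = vol.data[..., 3]
        assert np.allclose(frame, frame[::-1, :, :])
        assert np.allclose(frame, np.swapaxes(frame, 0, 2))

    def test_peak_moves_with_velocity(self):
        t = np.arange(0, 4.1, 1.0)
        vox = 0.5
        vol, _ = simulate_dispersion_field((41, 21, 21), vox, t, (2.0, 0, 0), 0.2,
                                           x0_mm=(-4.0, 0.0, 0.0))
        for i, ti in enumerate(t):
            idx = np.unravel_index(np.argmax(vol.data[..., i]), vol.grid_shape)
            x_mm = (idx[0] - 20) * vox
            assert abs(x_mm - (-4.0 + 2.0 * ti)) <= vox

    def test_mass_conserved(self):
        # numeric quadrature: total integral constant over t within 1%
        t = np.arange(0, 6, 1.0)
        vol, _ = simulate_dispersion_field((41, 41, 41), 0.5, t, (0, 0, 0), 0.5,
                                           t_ref_s=5.0)
        masses = vol.data.sum(axis=(0, 1, 2))
        assert np.ptp(masses) / masses[0] < 0.01

    def test_nonpositive_diffusion_rejected(self):
        with pytest.raises(ValueError):
            simulate_dispersion_field((9, 9, 9), 1.0, np.arange(3.0), d_mm2_s=0.0)


class TestSwePlanes:
    def test_homogeneous_delay_closed_form(self):
        # c = 2 m/s, traces 1 mm apart -> inter-trace delay 0.5 ms
        cfg = PhantomConfig(
            grid_shape=(16, 16, 16), voxel_size_mm=1.0, n_lesions=0, seed=6,
            stiffness_benign=(2.0, 2.0), n_swe_planes=2,
        )
        s = generate_geometry(cfg)
        planes = simulate_swe_planes(s, cfg)
        pv = planes[0].particle_velocity
        i0, i1 = 4, 5
        d0 = planes[0].frame_interval_s * pv[i0, 8].argmax()
        d1 = planes[0].frame_interval_s * pv[i1, 8].argmax()
        assert abs((d1 - d0) - 0.5e-3) < planes[0].frame_interval_s

    def test_zero_velocity_constant_iq_phase(self):
        v = np.zeros((4, 3, 16))
        iq = iq_from_velocity(v, 4000.0, 6e6, 1540.0)
        assert np.allclose(np.angle(iq), np.angle(iq[..., :1]))

    def test_aliasing_raises(self):
        v = np.full((2, 2, 8), 0.5)  # 0.5 m/s particle velocity aliases
        with pytest.raises(AliasingError):
            iq_from_velocity(v, 4000.0, 6e6, 1540.0)

    def test_pulse_bandwidth_vs_prf_guard(self):
        cfg = PhantomConfig(grid_shape=(12, 12, 12), voxel_size_mm=2.0,
                            n_lesions=0,
                            swe_prf_hz=1000.0, swe_pulse_sigma_s=0.0008, seed=1)
        s = generate_geometry(cfg)
        with pytest.raises(AliasingError):
            simulate_swe_planes(s, cfg)

    def test_lesion_speed_recovered_end_to_end(self):
        from mpuscad.swe import stack_planes, sws_crosscorr

        cfg = PhantomConfig(
            grid_shape=(24, 24, 24), seed=3,
            stiffness_benign=(2.0, 2.0), stiffness_malignant=(4.0, 4.0),
            n_swe_planes=12,
        )
        s = generate_geometry(cfg)
        planes = simulate_swe_planes(s, cfg)
        maps = [sws_crosscorr(p) for p in planes]
        vols = stack_planes(maps, planes, cfg.grid_shape, cfg.voxel_size_mm,
                            cfg.probe_standoff_mm)
        les = s.lesion_mask & np.isfinite(vols["sws"])
        bg = s.prostate_mask & ~s.lesion_mask & np.isfinite(vols["sws"])
        assert np.nanmean(vols["sws"][les]) > np.nanmean(vols["sws"][bg]) + 1.0


class TestHistology:
    def test_identity_at_voxel_spacing(self, small_study):
        slices = slice_histology(small_study, spacing_mm=small_study.config.voxel_size_mm)
        assert len(slices) == small_study.config.grid_shape[2]
        for z, m in slices:
            assert np.array_equal(m, small_study.lesion_mask[:, :, z])

    def test_no_lesions_all_empty(self):
        s = generate_geometry(PhantomConfig(n_lesions=0, seed=2))
        for _, m in slice_histology(s):
            assert not m.any()

    def test_slices_subset_of_lesion_mask(self, small_study):
        for z, m in slice_histology(small_study):
            assert np.all(m <= small_study.lesion_mask[:, :, z])

    def test_subvoxel_spacing_rejected(self, small_study):
        with pytest.raises(ValueError):
            slice_histology(small_study, spacing_mm=0.5)


def test_full_study_determinism():
    cfg = PhantomConfig(grid_shape=(16, 16, 16), voxel_size_mm=3.0, seed=9,
                        n_swe_planes=4)
    a = generate_study(cfg)
    b = generate_study(cfg)
    assert np.array_equal(a.ceus_loop.data, b.ceus_loop.data)
    assert np.array_equal(a.truth_maps["true_sws"], b.truth_maps["true_sws"],
                          equal_nan=True)
    assert a.clinical == b.clinical
    for pa, pb in zip(a.swe_planes, b.swe_planes):
        assert np.array_equal(pa.particle_velocity, pb.particle_velocity)
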