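"""Generator invariants: seed determinism, growth-model exactness,
subpopulation structure, mass bookkeeping in the renderer."""
import numpy as np
import pytest

from mqpi.cell_detection import MassConstants, compute_cell_mass
from mqpi.synthetic_data import (DrugEffectSpec, MassComponent,
                                 PopulationSpec, SceneSpec, bandlimited_phase,
                                 render_dpc_intensities, render_phase_movie,
                                 sample_sgr_mixture, simulate_tracks)


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [
        {"n_cells": 0},
        {"initial_mass_mix": ((0.5, 300.0, 50.0),)},      # weights != 1
        {"frame_interval_h": 0.0},
        {"duration_h": -1.0},
        {"noise_sd_mass": -1.0},
        {"mass_distribution": "uniform"},
    ])
    def test_bad_population(self, kw):
        with pytest.raises(ValueError):
            PopulationSpec(**kw)

    @pytest.mark.parametrize("kw", [{"ec50": 0.0}, {"ec50": -1.0},
                                    {"resistant_fraction": 1.5}])
    def test_bad_drug(self, kw):
        with pytest.raises(ValueError):
            DrugEffectSpec(**kw)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            simulate_tracks(PopulationSpec(n_cells=2, seed=0), dose=-1.0)


class TestSimulateTracks:
    def test_noiseless_control_exact_slope(self):
        """dose=0, no noise: every track's log-slope equals sgr_control."""
        pop = PopulationSpec(n_cells=5, sgr_control=0.02, sgr_sd=0.0,
                             noise_sd_mass=0.0, seed=1)
        for tr in simulate_tracks(pop):
            slopes = np.diff(np.log(tr.masses_pg)) / np.diff(tr.times_h)
            assert np.allclose(slopes, 0.02, atol=1e-12)

    def test_linear_growth_toggle_exact_line(self):
        pop = PopulationSpec(n_cells=3, sgr_control=0.02, sgr_sd=0.0,
                             noise_sd_mass=0.0, linear_growth=True, seed=1)
        for tr in simulate_tracks(pop):
            m0 = tr.masses_pg[0]
            assert np.allclose(tr.masses_pg, m0 * (1 + 0.02 * tr.times_h),
                               rtol=1e-12)

    def test_hill_midpoint_at_ec50(self):
        """dose = EC50, tau = 0, noiseless: non-resistant SGR = (E0+Emax)/2."""
        pop = PopulationSpec(n_cells=4, sgr_sd=0.0, noise_sd_mass=0.0, seed=2)
        drug = DrugEffectSpec(e0=0.02, emax=-0.01, ec50=0.5, hs=1.3)
        for tr in simulate_tracks(pop, drug, dose=0.5):
            assert tr.meta["true_sgr"] == pytest.approx((0.02 - 0.01) / 2)
            slopes = np.diff(np.log(tr.masses_pg)) / np.diff(tr.times_h)
            assert np.allclose(slopes, 0.005, atol=1e-12)

    def test_resistant_mixture_bimodal(self):
        """50/50 resistant mix: slopes recomputed from masses are bimodal."""
        pop = PopulationSpec(n_cells=2000, sgr_sd=0.0, noise_sd_mass=0.0,
                             duration_h=12.0, seed=3)
        drug = DrugEffectSpec(e0=0.02, emax=-0.01, ec50=1e-4, hs=2.0,
                              resistant_fraction=0.5, resistant_sgr=0.02)
        tracks = simulate_tracks(pop, drug, dose=100.0)  # >> EC50
        slopes = np.array([np.polyfit(tr.times_h, np.log(tr.masses_pg), 1)[0]
                           for tr in tracks])
        near_lo = np.abs(slopes - (-0.01)) < 2e-3
        near_hi = np.abs(slopes - 0.02) < 2e-3
        assert near_lo.sum() > 800 and near_hi.sum() > 800
        assert (near_lo | near_hi).all()

    def test_onset_delay_limits(self):
        """tau: early rate = control rate, late rate = dosed rate."""
        pop = PopulationSpec(n_cells=1, sgr_control=0.02, sgr_sd=0.0,
                             noise_sd_mass=0.0, duration_h=96.0, seed=4)
        drug = DrugEffectSpec(e0=0.02, emax=-0.02, ec50=0.1,
                              response_delay_tau_h=6.0)
        (tr,) = simulate_tracks(pop, drug, dose=1e4)
        early = np.log(tr.masses_pg[1] / tr.masses_pg[0]) / (1 / 3)
        g_late = np.log(tr.masses_pg[-1]) - np.log(tr.masses_pg[0])
        assert early > 0.0  # drug not yet acting
        # late cumulative rate approaches the dosed rate (~ -0.02)
        assert g_late / tr.times_h[-1] < -0.015

    def test_mass_component_overrides(self):
        comp = (MassComponent(0.5, 30.0, 1.0, sgr=0.0, drug_responsive=False),
                MassComponent(0.5, 300.0, 1.0))
        pop = PopulationSpec(n_cells=400, initial_mass_mix=comp, sgr_sd=0.0,
                             noise_sd_mass=0.0, duration_h=6.0, seed=5)
        drug = DrugEffectSpec(e0=0.02, emax=-0.02, ec50=0.01)
        tracks = simulate_tracks(pop, drug, dose=100.0)
        for tr in tracks:
            g = np.log(tr.masses_pg[-1] / tr.masses_pg[0]) / tr.times_h[-1]
            if tr.meta["subpopulation"] == "bystander":
                assert abs(g) < 1e-9 and tr.masses_pg[0] < 100
            else:
                assert g < -0.015 and tr.masses_pg[0] > 100

    def test_seed_determinism(self):
        pop = PopulationSpec(n_cells=20, seed=42)
        a = simulate_tracks(pop)
        b = simulate_tracks(pop)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.masses_pg, tb.masses_pg)

    def test_dose_response_consistency(self):
        """Mean generated SGR vs dose lies on the Hill curve (tau=0)."""
        drug = DrugEffectSpec(e0=0.02, emax=-0.012, ec50=0.1, hs=1.0)
        rng = np.random.default_rng(6)
        for dose in [0.01, 0.1, 1.0]:
            pop = PopulationSpec(n_cells=600, sgr_sd=0.004, noise_sd_mass=0.0)
            tracks = simulate_tracks(pop, drug, dose=dose, rng=rng)
            mean_g = np.mean([tr.meta["true_sgr"] for tr in tracks])
            expected = -0.012 + 0.032 / (1 + dose / 0.1)
            assert mean_g == pytest.approx(expected, abs=3 * 0.004 / np.sqrt(600))

    def test_sgr_mixture_sampler(self, rng):
        s = sample_sgr_mixture(5000, 0.3, -0.01, 0.02, 0.002, rng)
        frac_hi = (s > 0.005).mean()
        assert frac_hi == pytest.approx(0.3, abs=0.02)
        with pytest.raises(ValueError):
            sample_sgr_mixture(10, 1.2, 0, 1, 1, rng)


class TestRenderer:
    def test_single_cell_mass_bookkeeping(self):
        """Rendered disk integrates to the scheduled 300 pg within 0.5%."""
        pop = PopulationSpec(n_cells=1, initial_mass_mix=((1.0, 300.0, 0.0),),
                             sgr_control=0.0, sgr_sd=0.0, noise_sd_mass=0.0,
                             duration_h=1.0, seed=1)
        scene = SceneSpec(image_shape=(200, 200), motion_step_um=0.0,
                          min_separation_um=5.0, seed=2)
        mov = render_phase_movie(simulate_tracks(pop), scene)
        const = MassConstants(wavelength_nm=scene.wavelength_nm,
                              pixel_area_um2=scene.pixel_size_um ** 2)
        m = compute_cell_mass(mov.phase[0], mov.labels[0] == 1, const)
        assert m == pytest.approx(300.0, rel=0.005)

    def test_empty_scene_all_zero(self):
        mov = render_phase_movie([], SceneSpec(image_shape=(64, 64), seed=0))
        assert mov.phase.shape == (1, 64, 64)
        assert np.all(mov.phase == 0) and mov.truth.empty

    def test_two_cells_two_components(self):
        pop = PopulationSpec(n_cells=2, duration_h=0.5, seed=3)
        scene = SceneSpec(image_shape=(300, 300), seed=4)
        mov = render_phase_movie(simulate_tracks(pop), scene)
        assert set(np.unique(mov.labels[0])) == {0, 1, 2}

    def test_overlapping_cells_flagged(self):
        pop = PopulationSpec(n_cells=12, duration_h=0.5, seed=5)
        scene = SceneSpec(image_shape=(150, 150), min_separation_um=8.0,
                          cell_radius_um_mean=7.0, margin_um=8.0, seed=6)
        mov = render_phase_movie(simulate_tracks(pop), scene)
        assert mov.truth["overlaps"].any()

    def test_motion_bounded(self):
        pop = PopulationSpec(n_cells=5, duration_h=48.0, seed=7)
        scene = SceneSpec(seed=8, motion_step_um=1.0, motion_bound_um=5.0)
        mov = render_phase_movie(simulate_tracks(pop), scene)
        for cid, g in mov.truth.groupby("cell_id"):
            dx = g["x_um"].to_numpy() - g["x_um"].iloc[0]
            dy = g["y_um"].to_numpy() - g["y_um"].iloc[0]
            assert np.hypot(dx, dy).max() <= 5.0 + 1e-6


class TestDpcForward:
    def test_flat_phase_uniform_intensities(self):
        from mqpi.phase_reconstruction import OpticsSpec
        out = render_dpc_intensities(np.zeros((64, 64)), OpticsSpec(),
                                     background=2.0)
        for stack in out.values():
            assert np.allclose(stack, 2.0)

    def test_gradient_axis_symmetry(self):
        """Pure top-bottom gradient: lr pair identical, tb pair differ."""
        from mqpi.phase_reconstruction import OpticsSpec
        yy = np.arange(128)[:, None] * np.ones((1, 128))
        phi = 1e-3 * (yy - yy.mean())
        out = render_dpc_intensities(phi, OpticsSpec())
        assert np.allclose(out["left"], out["right"])
        assert np.abs(out["top"] - out["bottom"]).max() > 1e-4

    def test_shot_noise_seeded(self, rng):
        from mqpi.phase_reconstruction import OpticsSpec
        phi = np.full((32, 32), 0.01)
        a = render_dpc_intensities(phi, OpticsSpec(), photons=1000,
                                   rng=np.random.default_rng(0))
        b = render_dpc_intensities(phi, OpticsSpec(), photons=1000,
                                   rng=np.random.default_rng(0))
        np.testing.assert_array_equal(a["top"], b["top"])

    def test_bandlimited_object_spectrum(self, rng):
        from mqpi.phase_reconstruction import OpticsSpec
        optics = OpticsSpec()
        phi = bandlimited_phase((128, 128), optics, rng)
        assert np.abs(phi).max() == pytest.approx(0.3)
        spec = np.abs(np.fft.fft2(phi))
        f = np.fft.fftfreq(128, d=optics.pixel_size_um)
        rho = np.hypot(*np.meshgrid(f, f, indexing="ij")) / optics.cutoff_um
        assert spec[rho > 0.95].max() < 1e-8 * spec.max()
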