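"""Forward model: band library, diffusion solver, renderer, design generators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erfc

from ramangrad import (
    AcquisitionMeta,
    NoiseSettings,
    closed_form_diffusion,
    generate_dilution_series,
    generate_experiment,
    generate_ph_series,
    generate_zscan,
    make_axis,
    render_spectrum,
    simulate_reaction_diffusion,
)
from ramangrad.synthdata import (
    ExperimentDesign,
    HEPES_PKA,
    ReactionDiffusionParams,
    PeakComponent,
)


class TestAnalyteLibrary:
    @pytest.mark.parametrize(
        "analyte, center",
        [("glucose", 1125.0), ("lactate", 853.0), ("adenine", 725.0), ("stress_marker", 680.0)],
    )
    def test_principal_band_positions(self, library, analyte, center):
        assert library[analyte].principal_center() == center

    def test_every_center_within_default_axis(self, axis, library):
        for model in library.values():
            comps = model.components + model.acid_components + model.base_components
            for c in comps:
                assert axis[0] <= c.center <= axis[-1]

    def test_hepes_protonation_states_equal_at_pka(self, library):
        # Henderson-Hasselbalch midpoint: acid and base weights are 0.5 each
        hepes = library["hepes"]
        assert hepes.base_fraction(HEPES_PKA) == pytest.approx(0.5)
        assert hepes.base_fraction(HEPES_PKA - 2) < 0.01
        assert hepes.base_fraction(HEPES_PKA + 2) > 0.99

    def test_medium_background_includes_980_band(self, library):
        centers = [c.center for c in library["medium_background"].components]
        assert 980.0 in centers

    def test_peak_component_validation(self):
        with pytest.raises(ValueError):
            PeakComponent(700.0, -1.0)
        with pytest.raises(ValueError):
            PeakComponent(700.0, 5.0, shape="voigt")


class TestClosedFormDiffusion:
    def test_source_face_equals_reservoir_concentration(self):
        assert closed_form_diffusion(0.0, 1.0, 2.0, 5.0) == pytest.approx(5.0)

    def test_value_at_one_diffusion_length(self):
        # x = 2 sqrt(D t) gives C0 * erfc(1)
        D, t, C0 = 2.4, 0.5, 10.0
        x = 2.0 * np.sqrt(D * t)
        assert closed_form_diffusion(x, t, D, C0) == pytest.approx(C0 * erfc(1.0), rel=1e-12)
        assert closed_form_diffusion(x, t, D, C0) == pytest.approx(0.1573 * C0, rel=1e-3)

    @settings(max_examples=30, derandomize=True)
    @given(D=st.floats(0.1, 10.0), t=st.floats(0.01, 10.0))
    def test_profile_non_increasing_in_x(self, D, t):
        x = np.linspace(0.0, 15.0, 200)
        c = closed_form_diffusion(x, t, D, 1.0)
        assert np.all(np.diff(c) <= 1e-15)

    def test_rejects_nonpositive_time(self):
        with pytest.raises(ValueError):
            closed_form_diffusion(1.0, 0.0, 1.0, 1.0)


class TestReactionDiffusionSolver:
    def test_matches_erfc_oracle_in_semi_infinite_regime(self):
        # no cells, early time, fine grid: < 2% relative error where C/C0 > 0.05
        D = 2.3
        p = ReactionDiffusionParams(
            n_cells=300, cell_density=0.0, reservoir_volume_ratio=None,
            reservoir_mM={"adenine": 1.0}, initial_mM={"adenine": 0.0},
            diffusion_mm2_h={"adenine": D}, output_dt_h=0.05,
        )
        f = simulate_reaction_diffusion(p, duration_h=0.25)
        sim = f.conc["adenine"][-1]
        truth = closed_form_diffusion(f.x_mm, 0.25, D, 1.0)
        m = truth > 0.05
        assert np.max(np.abs(sim[m] - truth[m]) / truth[m]) < 0.02

    def test_mass_conserved_with_closed_boundaries(self):
        # zero-flux both ends, no reactions, non-uniform start
        n = 80
        profile = 1.0 + np.sin(np.linspace(0, np.pi, n)) * 4.0
        p = ReactionDiffusionParams(
            n_cells=n, cell_density=0.0, left_boundary="zero_flux",
            initial_mM={"glucose": profile}, reservoir_mM={"glucose": 0.0},
        )
        f = simulate_reaction_diffusion(p, duration_h=10.0)
        masses = f.conc["glucose"].sum(axis=1)
        assert np.max(np.abs(masses - masses[0]) / masses[0]) < 1e-8

    def test_dirichlet_source_profile_monotone_in_x(self):
        p = ReactionDiffusionParams(
            n_cells=100, cell_density=0.0, reservoir_volume_ratio=None,
            reservoir_mM={"adenine": 1.0}, initial_mM={"adenine": 0.0},
            output_dt_h=0.05,
        )
        f = simulate_reaction_diffusion(p, duration_h=10.0 / 60.0)
        for frame in f.conc["adenine"][1:]:
            assert np.all(np.diff(frame) <= 1e-12)

    def test_zero_diffusion_leaves_interior_unchanged(self):
        p = ReactionDiffusionParams(
            cell_density=0.0, diffusion_mm2_h={"glucose": 0.0},
            initial_mM={"glucose": 7.0}, reservoir_mM={"glucose": 25.0},
        )
        f = simulate_reaction_diffusion(p, duration_h=5.0)
        assert np.all(f.conc["glucose"] == 7.0)

    def test_unstable_time_step_refused(self):
        p = ReactionDiffusionParams(dt_h=1.0)  # D*dt/dx^2 >> 0.5 at dx = 0.25
        with pytest.raises(ValueError, match="unstable"):
            simulate_reaction_diffusion(p, duration_h=2.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            ReactionDiffusionParams(vmax_glucose_mM_h=-1.0)
        with pytest.raises(ValueError):
            ReactionDiffusionParams(diffusion_mm2_h={"glucose": -0.1})

    def test_default_study_field_invariants(self):
        f = simulate_reaction_diffusion(duration_h=96.0)
        g, l = f.conc["glucose"], f.conc["lactate"]
        # monotone supply: reservoir-adjacent glucose >= distal at every time
        assert np.all(g[:, 0] >= g[:, -1] - 1e-9)
        # lactate non-decreasing in time at every position
        assert np.all(np.diff(l, axis=0) >= -1e-9)
        # spatial means: glucose falls, lactate rises day over day
        assert np.all(np.diff(g.mean(axis=1)) <= 1e-9)
        assert np.all(np.diff(l.mean(axis=1)) >= -1e-9)
        assert np.all(f.ph >= 0) and np.all(f.ph <= 14)


class TestRenderer:
    def test_glucose_only_field_peaks_at_1125(self):
        p = ReactionDiffusionParams(cell_density=0.0)
        f = simulate_reaction_diffusion(p, duration_h=1.0)
        s = render_spectrum(f, 7.5, 1.0, AcquisitionMeta(zone="z2", x_mm=7.5),
                            noise=NoiseSettings.noiseless(), seed=0, include_medium=False)
        assert s.axis[np.argmax(s.intensity)] == 1125.0

    def test_zero_concentrations_zero_noise_gives_zero_spectrum(self):
        p = ReactionDiffusionParams(cell_density=0.0,
                                    initial_mM={"glucose": 0.0}, reservoir_mM={"glucose": 0.0})
        f = simulate_reaction_diffusion(p, duration_h=1.0)
        s = render_spectrum(f, 7.5, 1.0, AcquisitionMeta(zone="z2", x_mm=7.5),
                            noise=NoiseSettings.noiseless(), seed=0, include_medium=False)
        assert np.all(s.intensity == 0.0)

    def test_same_seed_gives_identical_spectra(self):
        f = simulate_reaction_diffusion(duration_h=1.0)
        meta = AcquisitionMeta(zone="z2", x_mm=7.5)
        s1 = render_spectrum(f, 7.5, 1.0, meta, seed=42)
        s2 = render_spectrum(f, 7.5, 1.0, meta, seed=42)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_out_of_grid_rejected(self):
        f = simulate_reaction_diffusion(duration_h=1.0)
        with pytest.raises(ValueError):
            render_spectrum(f, 20.0, 1.0, AcquisitionMeta(), seed=0)
        with pytest.raises(ValueError):
            render_spectrum(f, 7.5, 5.0, AcquisitionMeta(), seed=0)


class TestDesignGenerators:
    def test_full_design_yields_180_cell_spectra(self):
        sset = generate_experiment(ExperimentDesign(replicates=15, include_control=False), seed=0)
        assert sset.n_spectra == 3 * 4 * 15 == 180
        assert set(sset.meta["condition"]) == {"cells"}

    def test_minimal_design_single_row(self):
        d = ExperimentDesign(zones=("z2",), days=(1,), replicates=1, include_control=False)
        assert generate_experiment(d, seed=0).n_spectra == 1

    def test_control_condition_matched(self):
        d = ExperimentDesign(zones=("z1",), days=(1,), replicates=2, include_control=True)
        sset = generate_experiment(d, seed=0)
        assert (sset.meta["condition"] == "control").sum() == 2
        assert set(sset.meta.loc[sset.meta["condition"] == "control", "cell_line"]) == {"none"}

    def test_zone_centers_ordered_from_reservoir(self):
        d = ExperimentDesign(replicates=1, include_control=False)
        sset = generate_experiment(d, seed=0)
        x = sset.meta.groupby("zone")["x_mm"].first()
        assert x["z1"] < x["z2"] < x["z3"]

    def test_experiment_deterministic_under_seed(self):
        d = ExperimentDesign(zones=("z2",), days=(1, 2), replicates=2)
        a = generate_experiment(d, seed=7)
        b = generate_experiment(d, seed=7)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_zscan_0_to_1500um_at_100um_yields_16_spectra(self):
        zs = generate_zscan(0.0, 1.5, 0.1, seed=0)
        assert zs.n_spectra == 16
        np.testing.assert_allclose(np.diff(zs.meta["z_mm"]), 0.1)

    def test_dilution_blank_is_noise_and_baseline_only(self, axis):
        from ramangrad import preprocess_pipeline
        from ramangrad.spatial import band_intensity, resolve_band

        blank = generate_dilution_series("glucose", [0.0], replicates=1, seed=0)
        loaded = generate_dilution_series("glucose", [25.0], replicates=1, seed=0)
        proc, _ = preprocess_pipeline(blank)
        # after baseline removal the band carries no analyte signal
        band = resolve_band("glucose")
        assert abs(band_intensity(proc.axis, proc.intensities[0], band)) < 3.0
        assert band_intensity(loaded.axis, loaded.intensities[0], band) > \
            band_intensity(blank.axis, blank.intensities[0], band) + 5.0

    def test_ph_extremes_change_hepes_band_profile(self, axis):
        quiet = NoiseSettings.noiseless()
        s4 = generate_ph_series([4.0], seed=0, noise=quiet).intensities[0]
        s10 = generate_ph_series([10.0], seed=0, noise=quiet).intensities[0]
        region = (axis >= 1030) & (axis <= 1060)
        assert not np.allclose(s4[region], s10[region], rtol=0.05)
        # deprotonation moves the band maximum upward in wavenumber
        assert axis[region][np.argmax(s10[region])] > axis[region][np.argmax(s4[region])]
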