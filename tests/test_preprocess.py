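"""Despiking, smoothing, ALS baseline, centering, averaging, full chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ramangrad import (
    AcquisitionMeta,
    PreprocessConfig,
    Spectrum,
    SpectrumSet,
    als_baseline,
    average_replicates,
    make_axis,
    preprocess_pipeline,
    remove_cosmic_rays,
    savgol_smooth,
    subtract_and_center,
)
from ramangrad.synthdata import ExperimentDesign, NoiseSettings, generate_experiment


def _lorentzian(axis, center, fwhm, amp):
    g = fwhm / 2.0
    return amp * g * g / ((axis - center) ** 2 + g * g)


def _as_set(axis, rows):
    return SpectrumSet(axis, np.atleast_2d(rows))


class TestDespike:
    def test_spike_free_spectrum_unchanged(self, axis, rng):
        y = _lorentzian(axis, 850, 10, 20) + rng.normal(0, 1, axis.size)
        out = remove_cosmic_rays(_as_set(axis, y))
        np.testing.assert_array_equal(out.intensities[0], y)

    def test_single_spike_repaired_close_to_truth(self, axis, rng):
        sd = 1.0
        truth = _lorentzian(axis, 850, 10, 20)
        y = truth + rng.normal(0, sd, axis.size)
        spiked = y.copy()
        spiked[300] += 50 * sd
        out = remove_cosmic_rays(_as_set(axis, spiked))
        assert abs(out.intensities[0][300] - truth[300]) < 3 * sd
        untouched = np.ones(axis.size, dtype=bool)
        untouched[299:302] = False
        np.testing.assert_array_equal(out.intensities[0][untouched], spiked[untouched])

    def test_spikes_in_different_spectra_removed_independently(self, axis, rng):
        base = rng.normal(0, 1, (2, axis.size))
        base[0, 100] += 200.0
        base[1, 400] += 200.0
        out = remove_cosmic_rays(_as_set(axis, base))
        assert out.intensities[0, 100] < 50
        assert out.intensities[1, 400] < 50
        # the other spectrum's channel is untouched
        assert out.intensities[1, 100] == base[1, 100]

    def test_wide_genuine_band_not_repaired(self, axis, rng):
        y = _lorentzian(axis, 725, 8, 30) + rng.normal(0, 1.0, axis.size)
        out = remove_cosmic_rays(_as_set(axis, y))
        i = np.argmin(np.abs(axis - 725))
        assert out.intensities[0][i] == y[i]


class TestSavgol:
    def test_quadratic_reproduced_exactly(self, axis):
        y = 3.0 + 0.5 * axis + 0.01 * axis**2
        np.testing.assert_allclose(savgol_smooth(y), y, rtol=1e-9)

    def test_constant_unchanged(self, axis):
        y = np.full(axis.size, 7.0)
        np.testing.assert_allclose(savgol_smooth(y), y, rtol=1e-12)

    def test_noisy_lorentzian_peak_shift_below_one_channel(self, axis, rng):
        truth = _lorentzian(axis, 853, 12, 30)
        y = truth + rng.normal(0, 1, axis.size)
        sm = savgol_smooth(y)
        assert abs(axis[np.argmax(sm)] - 853) <= 1.0

    def test_invalid_window_rejected(self, axis):
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(axis.size), window=34)
        with pytest.raises(ValueError):
            savgol_smooth(np.ones(10), window=35)


class TestAlsBaseline:
    def test_straight_line_is_its_own_baseline(self, axis):
        y = 2.0 + 0.05 * axis
        res = als_baseline(y, lam=1e6)
        np.testing.assert_allclose(res.baseline, y, atol=1e-8)
        res_small = als_baseline(y, lam=10.0)
        np.testing.assert_allclose(res_small.baseline, y, atol=1e-8)

    @pytest.mark.parametrize("make_base", [
        lambda x: 50.0 + 0.08 * (x - x[0]),                       # linear
        lambda x: 60.0 + 2e-5 * (x - 900.0) ** 2,                 # gentle quadratic
    ])
    def test_known_baseline_recovered_under_peaks(self, axis, make_base):
        base = make_base(axis)
        peaks = (_lorentzian(axis, 700, 10, 40) + _lorentzian(axis, 900, 10, 60)
                 + _lorentzian(axis, 1100, 10, 50))
        res = als_baseline(base + peaks, lam=1e6, p=0.01)
        peak_free = peaks < 0.2
        rel = np.abs(res.baseline[peak_free] - base[peak_free]) / np.abs(base[peak_free])
        assert np.max(rel) < 0.02

    def test_final_weights_follow_update_rule(self, axis):
        y = 10.0 + _lorentzian(axis, 900, 10, 50)
        res = als_baseline(y, lam=1e6, p=0.01)
        above = y > res.baseline
        np.testing.assert_allclose(res.weights[above], 0.01)
        np.testing.assert_allclose(res.weights[~above], 0.99)

    def test_baseline_stays_below_peaked_signal(self, axis):
        p = 0.01
        peak_height = 80.0
        y = 20.0 + _lorentzian(axis, 800, 12, peak_height) + _lorentzian(axis, 1050, 12, 60)
        res = als_baseline(y, lam=1e6, p=p)
        # below the signal up to a sub-percent-of-peak numerical tolerance
        over = res.baseline - y
        assert np.mean(over <= 0.0025 * peak_height) >= 1 - 2 * p
        assert over.max() < 0.01 * peak_height

    def test_parameter_validation(self, axis):
        y = np.ones(axis.size)
        with pytest.raises(ValueError):
            als_baseline(y, lam=0.0)
        with pytest.raises(ValueError):
            als_baseline(y, p=1.5)
        with pytest.raises(ValueError):
            als_baseline(np.array([1.0, np.nan, 2.0]))


class TestCentering:
    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_output_mean_is_zero_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(50, 10, 64)
        z = rng.normal(45, 5, 64)
        out = subtract_and_center(y, z)
        assert abs(out.mean()) < 1e-10
        np.testing.assert_allclose(subtract_and_center(out, np.zeros_like(out)), out, atol=1e-12)

    def test_identical_signal_and_baseline_gives_zero(self):
        y = np.linspace(0, 10, 50)
        assert np.all(subtract_and_center(y, y) == 0)


class TestAveraging:
    def _design_set(self):
        d = ExperimentDesign(replicates=15, include_control=False)
        return generate_experiment(d, seed=3, noise=NoiseSettings(sd=0.5, spike_probability=0.0))

    def test_group_count_for_zone_day_design(self):
        out = average_replicates(self._design_set(), ["zone", "day"])
        assert out.n_spectra == 12
        assert set(out.meta["n_averaged"]) == {15}

    def test_identical_spectra_average_to_themselves(self, axis):
        row = _lorentzian(axis, 900, 10, 5)
        sset = SpectrumSet(axis, np.tile(row, (15, 1)))
        out = average_replicates(sset, ["zone"])
        np.testing.assert_allclose(out.intensities[0], row, rtol=1e-12)

    def test_mean_of_centered_spectra_is_centered(self, axis, rng):
        X = rng.normal(0, 1, (6, axis.size))
        X -= X.mean(axis=1, keepdims=True)
        out = average_replicates(SpectrumSet(axis, X), ["zone"])
        assert abs(out.intensities[0].mean()) < 1e-12

    def test_missing_group_key_rejected(self, axis):
        with pytest.raises(KeyError):
            average_replicates(SpectrumSet(axis, np.ones((2, axis.size))), ["nope"])


class TestPipeline:
    def test_peak_position_survives_full_chain(self, axis):
        sset = SpectrumSet(axis, _lorentzian(axis, 725, 8, 30))
        out, _ = preprocess_pipeline(sset)
        assert out.axis[np.argmax(out.intensities[0])] == pytest.approx(725, abs=1)

    def test_every_output_spectrum_has_zero_mean(self):
        d = ExperimentDesign(zones=("z2",), days=(1,), replicates=4, include_control=False)
        sset = generate_experiment(d, seed=5)
        out, _ = preprocess_pipeline(sset)
        assert np.max(np.abs(out.intensities.mean(axis=1))) < 1e-9

    def test_log_echoes_parameters_used(self):
        d = ExperimentDesign(zones=("z2",), days=(1,), replicates=2, include_control=False)
        sset = generate_experiment(d, seed=5)
        cfg = PreprocessConfig(sg_window=21, sg_order=3, als_lambda=1e5, als_iters=7)
        _, log = preprocess_pipeline(sset, cfg)
        assert log["parameters"]["sg_window"] == 21
        assert log["parameters"]["als_lambda"] == 1e5
        steps = {s["step"] for s in log["steps"]}
        assert {"remove_cosmic_rays", "savgol_smooth",
                "als_baseline_subtract_center", "average_replicates"} <= steps

    def test_empty_set_rejected(self, axis):
        sset = SpectrumSet(axis, np.ones((1, axis.size)))
        empty = sset.select(np.zeros(1, dtype=bool))
        with pytest.raises(ValueError):
            preprocess_pipeline(empty)

    def test_isolated_band_argmax_moves_under_two_channels(self, axis, rng):
        # SNR >= 10 synthetic band through the whole chain
        truth = _lorentzian(axis, 980, 12, 20)
        X = truth + rng.normal(0, 1.5, (5, axis.size))
        out, _ = preprocess_pipeline(SpectrumSet(axis, X))
        for row in out.intensities:
            assert abs(axis[np.argmax(row)] - 980) < 2.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sg_window=34)
        with pytest.raises(ValueError):
            PreprocessConfig(als_p=0.0)
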