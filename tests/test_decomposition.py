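"""Tonic windowing, epoch extraction and overlap-weighted window means."""

import numpy as np
import pandas as pd
import pytest

import neurochron as nc
from neurochron.decoder import ConcentrationSeries
from neurochron.decomposition import compute_tonic, extract_epochs, window_mean


def _series(values, rate=10.0):
    t = np.arange(len(values)) / rate
    v = np.asarray(values, dtype=float)
    return ConcentrationSeries(t, v, v * 0.5)


def _trials(onsets):
    return pd.DataFrame(
        {"onset_s": onsets, "duration_s": 0.8, "response": "long", "truth_phasic_amp": 0.0}
    )


class TestTonic:
    def test_constant_input_gives_constant_windows(self):
        s = _series(np.full(3000, 2.5))
        tonic = compute_tonic(s, window_length=60.0)
        np.testing.assert_allclose(tonic.tonic_da, 2.5)
        np.testing.assert_allclose(tonic.tonic_sert, 1.25)

    def test_linear_ramp_means_hit_window_centers(self):
        rate = 10.0
        t = np.arange(6000) / rate
        s = ConcentrationSeries(t, 0.01 * t, 0.01 * t)
        tonic = compute_tonic(s, window_length=100.0)
        # mean of a ramp over [a, a+L) sampled at dt equals ramp at center - dt/2 shift
        expected = 0.01 * (tonic.window_centers - 0.5 / rate)
        np.testing.assert_allclose(tonic.tonic_da, expected, atol=1e-12)

    def test_window_longer_than_recording_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            compute_tonic(_series(np.ones(100)), window_length=1000.0)

    def test_recovers_ground_truth_tonic(self, default_session, truth_series):
        tonic = compute_tonic(truth_series, 240.0)
        rec = default_session
        truth = [
            rec.truth_tonic_da[
                (rec.timestamps >= c - 120.0) & (rec.timestamps < c + 120.0)
            ].mean()
            for c in tonic.window_centers
        ]
        assert np.corrcoef(tonic.tonic_da, truth)[0, 1] >= 0.99


class TestEpochs:
    def test_constant_series_zero_after_baseline_correction(self):
        s = _series(np.full(400, 3.0))
        ep = extract_epochs(s, _trials([10.0, 20.0]))
        np.testing.assert_allclose(ep.da, 0.0, atol=1e-12)
        assert 0.0 in ep.epoch_times

    def test_baseline_correction_is_idempotent(self, truth_series, default_session):
        ep = extract_epochs(truth_series, default_session.trials)
        b = (ep.epoch_times >= -0.5) & (ep.epoch_times < 0.0)
        twice = ep.da - ep.da[:, b].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(twice, ep.da, atol=1e-10)
        # per-trial baseline means vanish
        assert np.abs(ep.da[:, b].mean(axis=1)).max() < 1e-10

    def test_injected_transient_peaks_where_placed(self):
        rate = 10.0
        t = np.arange(400) / rate
        v = np.zeros(400)
        onset = 10.0
        peak_at = onset + 0.5
        v += np.exp(-((t - peak_at) ** 2) / (2 * 0.05**2))
        s = ConcentrationSeries(t, v, v)
        ep = extract_epochs(s, _trials([onset]))
        tmax = ep.epoch_times[np.argmax(ep.da[0])]
        assert 0.4 <= tmax <= 0.7

    def test_full_session_epoch_count(self, truth_series, default_session):
        ep = extract_epochs(truth_series, default_session.trials)
        assert ep.n_trials == 300
        assert ep.n_dropped == 0

    def test_out_of_bounds_trials_dropped_with_warning(self):
        s = _series(np.ones(200))  # 20 s recording
        with pytest.warns(UserWarning, match="dropped 1"):
            ep = extract_epochs(s, _trials([10.0, 19.5]))
        assert ep.n_trials == 1
        assert ep.n_dropped == 1

    def test_zscore_mode_unit_variance(self, truth_series, default_session):
        ep = extract_epochs(truth_series, default_session.trials, mode="zscore")
        np.testing.assert_allclose(ep.da.std(axis=1), 1.0, atol=1e-9)


class TestWindowMean:
    @pytest.fixture()
    def unit_epochs(self, truth_series, default_session):
        return extract_epochs(truth_series, default_session.trials)

    def test_cluster_window_weights_match_overlap_arithmetic(self, unit_epochs):
        """At 10 Hz the 625-670 ms window mixes the 0.6/0.7 s samples 25:20."""
        ep = unit_epochs
        got = window_mean(ep, 0.625, 0.670).values
        i6 = np.argmin(np.abs(ep.epoch_times - 0.6))
        i7 = np.argmin(np.abs(ep.epoch_times - 0.7))
        expected = (25.0 * ep.da[:, i6] + 20.0 * ep.da[:, i7]) / 45.0
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_overlap_weights_equal_brute_force_step_integration(self, unit_epochs):
        """Oracle: integrate the sample-and-hold step function on a fine grid."""
        ep = unit_epochs
        t0, t1 = 0.583, 0.912
        fine = np.linspace(t0, t1, 200_001)
        idx = np.clip(
            np.round((fine - ep.epoch_times[0]) / ep.dt).astype(int), 0, len(ep.epoch_times) - 1
        )
        oracle = ep.da[:, idx].mean(axis=1)
        got = window_mean(ep, t0, t1).values
        np.testing.assert_allclose(got, oracle, atol=2e-4)

    def test_single_sample_window_returns_that_sample(self, unit_epochs):
        ep = unit_epochs
        i = np.argmin(np.abs(ep.epoch_times - 0.3))
        got = window_mean(ep, 0.3 - ep.dt / 2, 0.3 + ep.dt / 2).values
        np.testing.assert_allclose(got, ep.da[:, i], atol=1e-12)

    def test_all_ones_epoch_gives_one(self):
        s = _series(np.ones(400))
        ep = extract_epochs(s, _trials([10.0]), mode="baseline")
        ep.da[:] = 1.0
        assert window_mean(ep, 0.21, 0.93).values == pytest.approx(1.0)

    def test_linear_in_epoch_values(self, unit_epochs):
        ep = unit_epochs
        a = window_mean(ep, 0.6, 0.8).values
        scaled = type(ep)(
            da=3.0 * ep.da + 2.0,
            sert=ep.sert,
            epoch_times=ep.epoch_times,
            baseline_window=ep.baseline_window,
            trial_index=ep.trial_index,
            n_dropped=0,
        )
        np.testing.assert_allclose(window_mean(scaled, 0.6, 0.8).values, 3.0 * a + 2.0, atol=1e-12)

    def test_window_outside_epoch_errors(self, unit_epochs):
        with pytest.raises(ValueError, match="epoch span"):
            window_mean(unit_epochs, 1.3, 1.5)
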