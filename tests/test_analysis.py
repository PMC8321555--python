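"""Quantification toolbox: fits, spike statistics, event distributions."""

import numpy as np
import pytest

from mocsim.analysis import (
    EventSet,
    adaptation_ratio,
    amplitude_stats,
    detect_spikes,
    fi_slope,
    firing_sensitivity,
    first_spike_latency,
    fit_decay,
    iei_histogram_fit,
    mean_instantaneous_rate,
)
from mocsim.errors import (
    DegenerateInputError,
    InsufficientDataError,
    InvalidParameterError,
)


class TestFitDecay:
    T = np.arange(0, 20, 0.01)

    def test_double_round_trip_noiseless(self):
        y = -60 * np.exp(-self.T / 0.6) - 15 * np.exp(-self.T / 3.4)
        fit = fit_decay(self.T, y, model="double")
        assert fit.params["tau_fast"] == pytest.approx(0.6, rel=0.01)
        assert fit.params["tau_slow"] == pytest.approx(3.4, rel=0.01)

    def test_weighted_tau_formula(self):
        """tau_w from the published mEPSC component values is ~0.34 ms."""
        y = -47.07 * np.exp(-self.T / 0.17) - 5.63 * np.exp(-self.T / 1.72)
        fit = fit_decay(self.T, y, model="double")
        assert fit.tau_weighted == pytest.approx(0.17 * 0.893 + 1.72 * 0.107, abs=0.01)
        assert fit.tau_weighted == pytest.approx(0.34, abs=0.01)

    def test_single_round_trip(self):
        y = -100 * np.exp(-self.T / 2.2)
        fit = fit_decay(self.T, y, model="single")
        assert fit.params["tau"] == pytest.approx(2.2, rel=0.01)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_double_nests_single(self):
        """Fitting a pure single exponential with the double model: one
        component vanishes (or the fit falls back), and tau is recovered."""
        y = -80 * np.exp(-self.T / 1.5)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_decay(self.T, y, model="double")
        if fit.model == "double_exp":
            amps = abs(fit.params["a_fast"]), abs(fit.params["a_slow"])
            taus = fit.params["tau_fast"], fit.params["tau_slow"]
            dominant_tau = taus[int(np.argmax(amps))]
            assert min(amps) / max(amps) < 0.02 or fit.tau_weighted == pytest.approx(1.5, rel=0.02)
            assert dominant_tau == pytest.approx(1.5, rel=0.02)
        else:
            assert fit.params["tau"] == pytest.approx(1.5, rel=0.01)

    def test_too_short_trace(self):
        with pytest.raises(InsufficientDataError):
            fit_decay(self.T[:10], np.ones(10))


class TestFiSlope:
    def test_exact_line_through_origin(self):
        x = np.array([100.0, 300, 500, 900])
        fit = fi_slope(x, 0.15 * x, force_zero_intercept=True)
        assert fit.params["slope"] == pytest.approx(0.150)
        assert fit.r_squared == pytest.approx(1.0)

    def test_free_intercept_returns_both(self):
        x = np.array([200.0, 400, 600, 900])
        fit = fi_slope(x, 0.255 * x - 4.69)
        assert fit.params["slope"] == pytest.approx(0.255)
        assert fit.params["intercept"] == pytest.approx(-4.69)

    def test_single_point_forced_origin(self):
        fit = fi_slope([200.0], [30.0], force_zero_intercept=True)
        assert fit.params["slope"] == pytest.approx(0.15)

    def test_degenerate_currents(self):
        with pytest.raises(DegenerateInputError):
            fi_slope([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestAdaptationRatio:
    def test_regular_train_is_unity(self):
        assert adaptation_ratio(np.arange(20) * 10.0) == pytest.approx(1.0)

    def test_fourteen_spikes_rejected(self):
        with pytest.raises(InsufficientDataError):
            adaptation_ratio(np.arange(14) * 10.0)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        times = np.cumsum(rng.uniform(5, 15, size=30))
        a = adaptation_ratio(times)
        b = adaptation_ratio(times * 3.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_known_slowdown(self):
        # 10-ms ISIs early, 20-ms ISIs late -> ratio 0.5
        times = np.concatenate([np.arange(12) * 10.0, 110 + np.arange(1, 8) * 20.0])
        assert adaptation_ratio(times) == pytest.approx(0.5)


class TestFiringSensitivityAndLatency:
    def test_exact_proportionality(self):
        n = np.array([10.0, 20, 40, 80])
        fit = firing_sensitivity(n, 0.5 * n)
        assert fit.params["slope"] == pytest.approx(0.5)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            firing_sensitivity([10, 20], [1, 2])

    def test_first_spike_latency(self):
        assert first_spike_latency([]) is None
        assert first_spike_latency([12.0, 40.0, 80.0]) == 12.0

    def test_mean_instantaneous_rate(self):
        assert mean_instantaneous_rate([0.0, 10.0, 20.0]) == pytest.approx(100.0)


class TestDetectSpikes:
    def test_detects_peaks_above_level(self):
        dt = 0.1
        v = np.full(1000, -70.0)
        for i in (100, 500, 900):
            v[i - 2 : i + 3] = [-30, 10, 25, 10, -30]
        times = detect_spikes(v, dt, level=-20.0)
        np.testing.assert_allclose(times, [10.0, 50.0, 90.0])

    def test_subthreshold_trace_empty(self):
        assert detect_spikes(np.full(100, -60.0), 0.1).size == 0


class TestEventDistributions:
    def test_iei_fit_recovers_exponential_tau(self, rng):
        ieis = rng.exponential(0.20, size=1873)
        fit = iei_histogram_fit(ieis, bin_width=0.02)
        # the histogram fit tracks the sample mean (the MLE) closely
        assert fit.params["tau"] == pytest.approx(ieis.mean(), rel=0.03)
        assert fit.params["tau"] == pytest.approx(0.20, rel=0.08)

    def test_tau_close_to_sample_mean_for_exponential(self, rng):
        ieis = rng.exponential(0.20, size=5000)
        fit = iei_histogram_fit(ieis, bin_width=0.02)
        assert fit.params["tau"] == pytest.approx(ieis.mean(), rel=0.05)
        mle = iei_histogram_fit(ieis, bin_width=0.02, method="mle")
        assert mle.params["tau"] == pytest.approx(ieis.mean(), rel=1e-12)

    def test_regular_events_fit_poorly(self):
        ieis = np.full(500, 0.2) + np.linspace(0, 1e-3, 500)
        fit = iei_histogram_fit(ieis, bin_width=0.02)
        assert fit.r_squared < 0.5

    def test_too_few_events(self):
        with pytest.raises(InsufficientDataError):
            iei_histogram_fit(np.ones(50))

    def test_amplitude_stats_single_event(self):
        ev = EventSet(np.array([10.0]), np.array([57.5]))
        s = amplitude_stats(ev)
        assert s.mean == s.median == 57.5
        assert s.n == 1

    def test_amplitude_histogram_reproducible_bins(self):
        ev = EventSet(np.arange(5.0) + 1, np.array([30.0, 31.4, 45.0, 52.5, 100.0]))
        s = amplitude_stats(ev, bin_width=1.5)
        assert s.bin_edges[0] == 0.0
        assert np.diff(s.bin_edges) == pytest.approx(1.5)
        assert s.counts.sum() == 5

    def test_event_set_validation(self):
        with pytest.raises(InvalidParameterError):
            EventSet(np.array([1.0, 1.0]), np.array([5.0, 5.0]))
        with pytest.raises(InvalidParameterError):
            EventSet(np.array([1.0, 2.0]), np.array([5.0, -5.0]))
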