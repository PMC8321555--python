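"""MOC point-neuron model: passive behavior, spiking, adaptation, block."""

import numpy as np
import pytest
from dataclasses import replace

from mocsim.epsg import ConductanceWaveform, SynapseSpec, synthesize
from mocsim.errors import CalibrationError, InsufficientDataError
from mocsim.neuron import (
    NeuronParams,
    VoltageTrace,
    calibrate,
    extrapolate_blocked_rate,
    fi_curve,
    run_conductance_clamp,
    run_current_clamp,
)
from mocsim.analysis import adaptation_ratio, fi_slope
from mocsim.trains import generate_paradigm


class TestPassive:
    def test_silent_at_rest(self):
        trace = run_current_clamp(NeuronParams(), [0.0])[0]
        assert trace.n_spikes == 0
        assert np.allclose(trace.v, NeuronParams().e_rest, atol=1e-9)

    def test_membrane_time_constant(self):
        assert NeuronParams().tau_m == pytest.approx(4.49, abs=0.01)

    def test_subthreshold_step_matches_rc_charging(self):
        """Hyperpolarizing step follows the analytic exponential (no sag)."""
        p = NeuronParams()
        i_amp = -100.0  # pA, hyperpolarizing: no spikes, pure RC
        dt = 0.02
        trace = run_current_clamp(p, [i_amp], duration=100.0, dt=dt)[0]
        t = np.arange(trace.v.size) * dt
        v_inf = p.e_rest + i_amp * p.r_m / 1000.0
        analytic = v_inf + (p.e_rest - v_inf) * np.exp(-(t + dt) / p.tau_m)
        err = np.max(np.abs(trace.v - analytic)) / abs(v_inf - p.e_rest)
        assert err < 0.01
        assert trace.v.min() >= v_inf - 1e-9  # monotone approach, no sag

    def test_constant_conductance_steady_state(self):
        """Small steady g: V settles at the two-conductance divider voltage."""
        p = NeuronParams()
        g0 = 0.5  # nS, subthreshold
        wave = ConductanceWaveform(dt=0.02, g=np.full(10_000, g0), e_rev=10.0)
        trace = run_conductance_clamp(p, wave)
        g_l = p.g_leak
        expected = (g_l * p.e_rest + g0 * wave.e_rev) / (g_l + g0)
        assert trace.n_spikes == 0
        assert trace.v[-1] == pytest.approx(expected, abs=1e-3)


class TestSpiking:
    def test_fi_monotone_up_to_block(self):
        cur, rates = fi_curve(NeuronParams(), np.arange(100, 1000, 100))
        assert np.all(np.diff(rates) >= 0)

    def test_calibrated_slope_and_adaptation(self):
        """Frozen defaults reproduce the published f-I slope and 900-pA ratio."""
        p = NeuronParams()
        cur, rates = fi_curve(p)
        slope = fi_slope(cur, rates, force_zero_intercept=True).params["slope"]
        assert slope == pytest.approx(0.150, rel=0.05)
        trace = run_current_clamp(p, [900.0])[0]
        assert adaptation_ratio(trace.spike_times) == pytest.approx(0.69, abs=0.05)

    def test_adaptation_disabled_flattens_rate(self):
        """With w_inc = 0 the initial and steady-state rates coincide."""
        p = replace(NeuronParams(), w_inc=0.0)
        trace = run_current_clamp(p, [500.0])[0]
        assert trace.n_spikes >= 15
        assert adaptation_ratio(trace.spike_times) == pytest.approx(1.0, abs=0.01)

    def test_dt_halving_changes_count_by_at_most_one(self):
        for i_amp in (200.0, 900.0):
            n = [run_current_clamp(NeuronParams(), [i_amp], dt=dt)[0].n_spikes
                 for dt in (0.02, 0.01)]
            assert abs(n[0] - n[1]) <= 1

    def test_dt_halving_conductance_clamp(self):
        p = NeuronParams()
        counts = []
        for dt in (0.02, 0.01):
            ens = generate_paradigm("high", 20, seed=31)
            wave = synthesize(ens, SynapseSpec.depressing(), n_inputs=20, dt=dt)
            counts.append(run_conductance_clamp(p, wave).n_spikes)
        assert abs(counts[0] - counts[1]) <= 1


class TestRectification:
    def test_synaptic_current_zero_above_reversal(self):
        """With V pinned above E_rev, a rectifying synapse passes no current."""
        p = replace(NeuronParams(), v_thresh=100.0, e_rest=20.0)  # no spikes
        g = np.full(5000, 50.0)
        rect = run_conductance_clamp(p, ConductanceWaveform(dt=0.02, g=g, e_rev=10.0,
                                                            rectifying=True))
        lin = run_conductance_clamp(p, ConductanceWaveform(dt=0.02, g=g, e_rev=10.0,
                                                           rectifying=False))
        # rectifying: V stays at rest (20 mV > E_rev); linear: pulled toward E_rev
        assert rect.v[-1] == pytest.approx(20.0, abs=1e-6)
        assert lin.v[-1] < 15.0


class TestBlock:
    def test_no_block_at_900pA(self):
        assert run_current_clamp(NeuronParams(), [900.0])[0].blocked_from is None

    def test_strong_step_blocks(self):
        trace = run_current_clamp(NeuronParams(), [3000.0])[0]
        assert trace.blocked_from is not None

    def test_extrapolation_rule_halves_instantaneous_rate(self):
        """Steady 100-Hz firing blocked at 300 ms extrapolates to 50 spikes."""
        spikes = np.arange(0.0, 300.0, 10.0)
        trace = VoltageTrace(dt=0.02, v=np.zeros(10), spike_times=spikes,
                             blocked_from=300.0, duration=500.0)
        assert extrapolate_blocked_rate(trace) == pytest.approx(50.0)

    def test_no_block_returns_raw_count(self):
        spikes = np.arange(0.0, 500.0, 10.0)
        trace = VoltageTrace(dt=0.02, v=np.zeros(10), spike_times=spikes,
                             blocked_from=None, duration=500.0)
        assert extrapolate_blocked_rate(trace) == float(spikes.size)

    def test_too_few_preblock_spikes_rejected(self):
        trace = VoltageTrace(dt=0.02, v=np.zeros(10), spike_times=np.array([5.0]),
                             blocked_from=10.0, duration=500.0)
        with pytest.raises(InsufficientDataError):
            extrapolate_blocked_rate(trace)


class TestCalibrate:
    def test_empty_targets_returns_start_unchanged(self):
        p = NeuronParams()
        assert calibrate(None, start=p) is p
        assert calibrate({}, start=p) is p

    def test_frozen_defaults_already_satisfy_targets(self):
        """A zero-iteration calibration run accepts the shipped defaults."""
        p = calibrate(
            {"fi_slope": 0.150, "adaptation_ratio": {900: 0.69}},
            start=NeuronParams(), maxiter=1,
        )
        assert isinstance(p, NeuronParams)

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            calibrate({"fi_slope": 5.0}, start=NeuronParams(), maxiter=2)


def test_cohort_jitter_changes_passive_only(rng):
    base = NeuronParams()
    j = base.jittered(rng)
    assert (j.c_m, j.r_m, j.e_rest) != (base.c_m, base.r_m, base.e_rest)
    assert (j.v_thresh, j.w_inc, j.tau_w) == (base.v_thresh, base.w_inc, base.tau_w)
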