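import numpy as np
import pytest

from olfephys import intrinsic, synth
from olfephys.intrinsic import (
    MeasurementError,
    ap_features,
    capacitance,
    detect_spikes,
    dvdt,
    fi_curve,
    input_resistance,
    rheobase,
    sag_ratio,
    series_resistance_qc,
    time_constant,
)
from olfephys.traces import CC_VOLTAGE, VC_CURRENT, StepStimulus, SweepSet, Trace


def _vc_transient_sweep(step_mv=-1.0, peak_pa=100.0, dt=5e-5, tau=5e-4):
    """Idealized capacitive transient: exponential from `peak_pa` to 0."""
    n = int(0.2 / dt)
    t = np.arange(n) * dt
    onset = 0.05
    i = np.zeros(n)
    mask = t >= onset
    i[mask] = -peak_pa * np.exp(-(t[mask] - onset) / tau)
    return Trace(samples=i, dt=dt, signal_kind=VC_CURRENT,
                 stimulus=StepStimulus(step_mv, onset, 0.1))


class TestSeriesResistance:
    def test_ohms_law_on_ideal_transient(self):
        rs, qc = series_resistance_qc(SweepSet([_vc_transient_sweep(-1.0, 100.0)]))
        assert rs == pytest.approx(10.0, rel=1e-6)
        assert qc

    def test_variation_above_30_percent_fails_qc(self):
        sweeps = SweepSet([_vc_transient_sweep(-1.0, 50.0), _vc_transient_sweep(-1.0, 1000.0 / 28)])
        rs, qc = series_resistance_qc(sweeps)  # 20 → 28 MΩ is a 40 % rise
        assert not qc

    def test_absolute_limit_30_mohm(self):
        _, qc = series_resistance_qc(SweepSet([_vc_transient_sweep(-1.0, 1000.0 / 35)]))
        assert not qc

    def test_recovery_from_generator(self):
        mem = synth.MembraneParams(input_resistance=300, capacitance=80,
                                   series_resistance=12, noise_sd=2.0)
        rs, qc = series_resistance_qc(synth.gen_vc_test_pulses(mem, seed=0))
        assert rs == pytest.approx(12.0, rel=0.10)
        assert qc

    def test_flat_sweep_is_an_error(self):
        flat = Trace(samples=np.zeros(4000), dt=5e-5, signal_kind=VC_CURRENT,
                     stimulus=StepStimulus(-1.0, 0.05, 0.1))
        with pytest.raises(MeasurementError, match="transient"):
            series_resistance_qc(SweepSet([flat]))


class TestCapacitance:
    def test_exact_two_point_slope(self):
        """Q–V pairs (1 mV, 50 fC) and (2 mV, 100 fC) → 50 pF."""
        # rectangle transient of width w: Q = peak·w; choose peaks for the target charges
        def rect(step_mv, q_pc, dt=5e-5, width=5e-3):
            n = int(0.2 / dt)
            t = np.arange(n) * dt
            i = np.zeros(n)
            i[(t >= 0.05) & (t < 0.05 + width)] = -q_pc / width
            return Trace(samples=i, dt=dt, signal_kind=VC_CURRENT,
                         stimulus=StepStimulus(step_mv, 0.05, 0.1))

        sweeps = SweepSet([rect(-1.0, 0.05), rect(-2.0, 0.10)])
        assert capacitance(sweeps, correct_rs=False) == pytest.approx(50.0, rel=0.02)

    def test_single_step_level_is_singular(self):
        sweeps = SweepSet([_vc_transient_sweep(-1.0, 100.0)] * 3)
        with pytest.raises(MeasurementError, match="distinct"):
            capacitance(sweeps)

    @pytest.mark.parametrize("noise,tol", [(0.0, 0.01), (2.0, 0.05)])
    def test_recovery_from_generator(self, noise, tol):
        mem = synth.MembraneParams(input_resistance=500, capacitance=50,
                                   series_resistance=10, noise_sd=noise)
        cm = capacitance(synth.gen_vc_test_pulses(mem, seed=1))
        assert cm == pytest.approx(50.0, rel=tol)


class TestInputResistance:
    def test_exact_on_noise_free_cell(self):
        mem = synth.MembraneParams(input_resistance=150, capacitance=80, noise_sd=0)
        ss = synth.gen_passive_step_traces(mem, synth.StepProtocol([-60, -50, -40, -30, -20]))
        assert input_resistance(ss) == pytest.approx(150.0, rel=1e-3)

    def test_recovery_with_noise(self):
        mem = synth.MembraneParams(input_resistance=133, capacitance=90, noise_sd=0.3)
        ss = synth.gen_passive_step_traces(mem, synth.StepProtocol([-60, -50, -40, -30, -20]), seed=2)
        assert input_resistance(ss) == pytest.approx(133.0, rel=0.05)

    def test_depolarizing_steps_rejected(self):
        mem = synth.MembraneParams(noise_sd=0)
        ss = synth.gen_passive_step_traces(mem, synth.StepProtocol([20.0, 40.0]))
        with pytest.raises(MeasurementError, match="hyperpolarizing"):
            input_resistance(ss)

    def test_single_level_rejected(self):
        mem = synth.MembraneParams(noise_sd=0)
        ss = synth.gen_passive_step_traces(mem, synth.StepProtocol([-20.0, -20.0]))
        with pytest.raises(MeasurementError, match="two current levels"):
            input_resistance(ss)


class TestTimeConstant:
    def test_noise_free_within_one_percent(self):
        mem = synth.MembraneParams(input_resistance=133, capacitance=90.2256, noise_sd=0)  # τ = 12 ms
        ss = synth.gen_passive_step_traces(mem, synth.StepProtocol([-20.0], duration=0.1))
        assert time_constant(ss) == pytest.approx(12.0, rel=0.01)

    def test_recovery_from_ten_noisy_sweeps(self):
        mem = synth.MembraneParams(input_resistance=133, capacitance=90.2256, noise_sd=0.5)
        ss = synth.gen_passive_step_traces(mem, synth.StepProtocol([-20.0] * 10, duration=0.1), seed=3)
        assert time_constant(ss) == pytest.approx(12.0, rel=0.10)

    def test_flat_trace_is_an_error(self):
        flat = Trace(samples=np.full(6000, -85.0), dt=5e-5, signal_kind=CC_VOLTAGE,
                     stimulus=StepStimulus(-20.0, 0.1, 0.1))
        with pytest.raises(MeasurementError, match="flat"):
            time_constant(SweepSet([flat]))


class TestSag:
    def test_no_sag_gives_zero(self):
        mem = synth.MembraneParams(sag_fraction=0.0, noise_sd=0)
        per, summary = sag_ratio(synth.gen_passive_step_traces(mem, synth.StepProtocol([-120.0])))
        assert summary == pytest.approx(0.0, abs=0.1)

    def test_recovers_generator_sag_fraction(self):
        mem = synth.MembraneParams(sag_fraction=0.05, noise_sd=0)
        prot = synth.StepProtocol([-120, -150, -180])
        per, summary = sag_ratio(synth.gen_passive_step_traces(mem, prot))
        assert summary == pytest.approx(5.0, abs=0.3)
        assert per.shape == (3,)

    def test_null_with_noise_stays_below_one_percent(self):
        mem = synth.MembraneParams(sag_fraction=0.0, noise_sd=0.3)
        prot = synth.StepProtocol([-300.0])
        vals = [sag_ratio(synth.gen_passive_step_traces(mem, prot, seed=s))[1] for s in range(5)]
        assert max(abs(v) for v in vals) < 1.0

    def test_literal_ratio_method(self):
        mem = synth.MembraneParams(sag_fraction=0.05, noise_sd=0)
        _, ratio = sag_ratio(synth.gen_passive_step_traces(mem, synth.StepProtocol([-300.0])),
                             method="ratio")
        assert ratio == pytest.approx(1 / 0.95, rel=0.01)

    def test_depolarizing_step_is_an_error(self):
        mem = synth.MembraneParams(noise_sd=0)
        with pytest.raises(MeasurementError):
            sag_ratio(synth.gen_passive_step_traces(mem, synth.StepProtocol([100.0])))


class TestSpikeDetection:
    def test_subthreshold_trace_empty(self):
        mem = synth.MembraneParams(noise_sd=0)
        tr = synth.gen_passive_step_traces(mem, synth.StepProtocol([-20.0]))[0]
        assert detect_spikes(tr).size == 0

    def test_generator_spikes_found_at_true_times(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=100, gain_true=0.1), synth.StepProtocol([300.0])
        )
        tr = ss[0]
        detected = detect_spikes(tr)
        truth = tr.meta["true_spike_times"]
        assert detected.size == truth.size == 10
        assert np.max(np.abs(detected - truth)) <= 0.5e-3

    def test_doublet_within_refractory_counts_once(self):
        dt = 5e-5
        v = np.full(2000, -70.0)
        for i0 in (1000, 1016):  # second crossing 0.8 ms after the first
            v[i0 : i0 + 6] = [-70, 20, 40, 20, -20, -70]
        tr = Trace(samples=v, dt=dt, signal_kind=CC_VOLTAGE)
        assert detect_spikes(tr).size == 1


class TestFICurve:
    def test_gain_recovery_and_frequency_definition(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=100, gain_true=0.1),
            synth.StepProtocol(list(range(25, 626, 50))),
        )
        fic = fi_curve(ss)
        np.testing.assert_allclose(fic.frequencies, fic.spike_counts / 0.5)
        assert fic.gain == pytest.approx(0.1, rel=0.10)
        # dual route: the gain must equal an independent regression on the recorded region
        lo, hi = fic.linear_region
        oracle = np.polyfit(fic.step_currents[lo : hi + 1], fic.frequencies[lo : hi + 1], 1)[0]
        assert fic.gain == pytest.approx(oracle, rel=1e-9)

    def test_gain_robust_to_noise(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=100, gain_true=0.1),
            synth.StepProtocol(list(range(25, 626, 50))), noise_sd=0.3, seed=1,
        )
        assert fi_curve(ss).gain == pytest.approx(0.1, rel=0.10)

    def test_all_silent_flags_undefined_gain(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=1000), synth.StepProtocol([25.0, 75.0])
        )
        with pytest.warns(UserWarning, match="no spikes"):
            fic = fi_curve(ss)
        assert fic.gain is None and fic.rheobase is None


class TestRheobase:
    def test_definition_on_fine_grid(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=113.0),
            synth.StepProtocol(list(np.arange(100, 131, 5.0))),
        )
        assert rheobase(ss) == 115.0  # first grid point at/above 113

    def test_recovers_within_grid_resolution(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=120.0),
            synth.StepProtocol(list(np.arange(100, 146, 5.0))),
        )
        assert abs(rheobase(ss) - 120.0) <= 5.0

    def test_all_spiking_warns_and_returns_smallest(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=50.0), synth.StepProtocol([100.0, 150.0])
        )
        with pytest.warns(UserWarning, match="every sweep"):
            assert rheobase(ss) == 100.0

    def test_no_spikes_is_an_error(self):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=500.0), synth.StepProtocol([100.0, 150.0])
        )
        with pytest.raises(MeasurementError):
            rheobase(ss)


class TestAPFeatures:
    def _first_suprathreshold(self, noise=0.0, thr=-56.0, seed=0):
        ss = synth.gen_spiking_traces(
            synth.SpikingParams(rheobase_true=120.0, threshold_true=thr),
            synth.StepProtocol(list(np.arange(100, 146, 5.0))), noise_sd=noise, seed=seed,
        )
        return next(t for t in ss if t.stimulus.amplitude >= 120.0)

    def test_threshold_at_slope_change_of_piecewise_linear_spike(self):
        """5 mV/ms ramp to −60 mV then a 50 mV/ms upstroke: threshold = −60."""
        dt = 5e-5
        seg1 = -70 + 5e3 * np.arange(0, 2e-3, dt)        # to −60 over 2 ms
        seg2 = -60 + 50e3 * np.arange(dt, 2.1e-3, dt)    # to +45
        seg3 = seg2[-1] - 60e3 * np.arange(dt, 2.2e-3, dt)
        v = np.concatenate([np.full(2000, -70.0), seg1, seg2, seg3, np.full(1000, -70.0)])
        tr = Trace(samples=v, dt=dt, signal_kind=CC_VOLTAGE,
                   stimulus=StepStimulus(200.0, 0.05, 0.2))
        f = ap_features(tr, stimulus_onset=0.05)
        assert f.threshold == pytest.approx(-60.0, abs=0.6)

    def test_amplitude_and_overshoot_arithmetic(self):
        f = ap_features(self._first_suprathreshold())
        assert f.amplitude == pytest.approx(f.overshoot - f.threshold, abs=1e-9)
        assert f.overshoot == pytest.approx(44.0, abs=0.5)
        assert f.fahp == pytest.approx(-8.0, abs=0.5)
        assert f.half_width > 0
        assert f.latency > 0

    @pytest.mark.parametrize("noise", [0.0, 0.05, 0.1])
    def test_threshold_recovery_across_noise_levels(self, noise):
        f = ap_features(self._first_suprathreshold(noise=noise, seed=4))
        assert f.threshold == pytest.approx(-56.0, abs=1.5)

    def test_no_spike_is_an_error(self):
        mem = synth.MembraneParams(noise_sd=0)
        tr = synth.gen_passive_step_traces(mem, synth.StepProtocol([-20.0]))[0]
        with pytest.raises(MeasurementError, match="no spike"):
            ap_features(tr, stimulus_onset=0.1)


class TestDvdt:
    def test_central_difference_matches_forward_difference_oracle(self):
        rng = np.random.default_rng(0)
        v = np.cumsum(rng.normal(0, 0.1, 500)) - 70
        tr = Trace(samples=v, dt=5e-5, signal_kind=CC_VOLTAGE)
        central = dvdt(tr)[1:-1]
        forward = np.diff(v) / 5e-5 * 1e-3
        brute = (forward[:-1] + forward[1:]) / 2  # average of adjacent forward differences
        np.testing.assert_allclose(central, brute, rtol=1e-12)
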