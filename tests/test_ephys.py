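"""Tests for current-clamp feature extraction against generator ground truth."""
import numpy as np
import pytest

from aisquant import ephys, synth
from aisquant.ephys import CurrentClampRecording, CurrentClampSweep, StepProtocol
from aisquant.errors import EphysError
from aisquant.synth import PASSIVE_PROTOCOL, SyntheticCellConfig


def noiseless_cell(**kw):
    base = dict(noise_sd_mv=0.0, seed=2)
    base.update(kw)
    return SyntheticCellConfig(**base)


def _ramp_sweep(v_start=-60.0, thr=-40.0, slow=5.0, fast=50.0, dt=0.05):
    """Piecewise-linear upstroke: slow rise to thr, then a fast rise."""
    n_slow = int(round((thr - v_start) / (slow * dt)))
    n_fast = int(round(30.0 / (fast * dt)))
    v = np.concatenate([
        np.full(100, v_start),
        v_start + slow * dt * np.arange(1, n_slow + 1),
        thr + fast * dt * np.arange(1, n_fast + 1),
    ])
    v = np.concatenate([v, np.full(100, v[-1])])
    t = np.arange(v.size) * dt
    return CurrentClampSweep(t, v, 50.0, step_onset_ms=2.0, step_offset_ms=t[-1] - 2.0)


class TestDetectSpikes:
    def test_subthreshold_sweep_has_no_spikes(self):
        rec = synth.generate_sweep_family(noiseless_cell(rin_mohm=100.0))
        assert all(ephys.detect_spikes(s).size == 0 for s in rec.sweeps)

    def test_counts_and_times_match_pasted_templates(self):
        rec = synth.generate_sweep_family(noiseless_cell())
        for sweep, truth in zip(rec.sweeps, rec.ground_truth.spike_times_ms):
            got = ephys.detect_spikes(sweep)
            assert got.size == truth.size
            if truth.size:
                assert np.allclose(got, truth, atol=sweep.dt_ms)

    def test_noisy_counts_match_ground_truth(self):
        rec = synth.generate_sweep_family(SyntheticCellConfig(noise_sd_mv=0.3, seed=8))
        for sweep, truth in zip(rec.sweeps, rec.ground_truth.spike_times_ms):
            assert ephys.detect_spikes(sweep).size == truth.size


class TestVoltageThreshold:
    def test_piecewise_linear_knee_is_recovered(self):
        sweep = _ramp_sweep(thr=-40.0, slow=5.0, fast=50.0)
        peak_time = sweep.time_ms[int(np.argmax(sweep.voltage_mv))]
        thr = ephys.voltage_threshold(sweep, peak_time)
        assert thr == pytest.approx(-40.0, abs=50.0 * sweep.dt_ms)

    def test_criterion_above_max_slope_is_undefined(self):
        sweep = _ramp_sweep(fast=50.0)
        peak_time = sweep.time_ms[int(np.argmax(sweep.voltage_mv))]
        with pytest.raises(EphysError, match="undefined"):
            ephys.voltage_threshold(sweep, peak_time, dvdt_crit=500.0)

    @pytest.mark.parametrize("dt", [0.2, 0.1, 0.05])
    def test_converges_to_generator_threshold(self, dt):
        cfg = noiseless_cell(sample_interval_ms=dt)
        rec = synth.generate_sweep_family(cfg)
        rheo = rec.ground_truth.rheobase_pa
        sweep = next(s for s in rec.sweeps if s.current_amplitude_pa == rheo)
        first = ephys.detect_spikes(sweep)[0]
        thr = ephys.voltage_threshold(sweep, first)
        # error shrinks with dt and is < 1 mV at the acquisition rate
        assert abs(thr - cfg.spike_threshold_mv) < max(1.0, 25.0 * dt)


class TestCurrentThreshold:
    def test_matches_generator_rheobase(self):
        rec = synth.generate_sweep_family(noiseless_cell())
        assert ephys.current_threshold(rec) == rec.ground_truth.rheobase_pa

    def test_always_a_protocol_amplitude(self):
        rec = synth.generate_sweep_family(SyntheticCellConfig(seed=17))
        rheo = ephys.current_threshold(rec)
        assert rheo in rec.protocol.amplitudes_pa()

    def test_silent_cell_flagged(self):
        rec = synth.generate_sweep_family(noiseless_cell(rin_mohm=50.0))
        with pytest.raises(EphysError, match="undefined"):
            ephys.current_threshold(rec)


class TestFiringCurve:
    def test_frequency_arithmetic(self):
        rec = synth.generate_sweep_family(noiseless_cell())
        counts, max_count, max_freq = ephys.firing_curve(rec)
        assert max_freq == max_count / 0.5  # 500 ms steps
        assert max_freq * 0.5 == max_count

    def test_counts_monotone_for_integrator_cell(self):
        rec = synth.generate_sweep_family(noiseless_cell())
        counts = [c for _, c in sorted(ephys.firing_curve(rec)[0].items())]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_counts_match_ground_truth(self):
        rec = synth.generate_sweep_family(SyntheticCellConfig(noise_sd_mv=0.2, seed=5))
        counts, _, _ = ephys.firing_curve(rec)
        for sweep, truth in zip(rec.sweeps, rec.ground_truth.spike_times_ms):
            assert counts[sweep.current_amplitude_pa] == truth.size

    def test_frequency_at_queried_amplitude(self):
        rec = synth.generate_sweep_family(noiseless_cell())
        counts, _, _ = ephys.firing_curve(rec)
        assert ephys.firing_frequency_at(rec, 40.0) == counts[40.0] / 0.5


class TestPassiveProperties:
    def test_noiseless_rin_recovered_within_half_mohm(self):
        # short time constant so the 200 ms steps settle completely
        cfg = noiseless_cell(rin_mohm=500.0, tau_ms=20.0)
        rec = synth.generate_sweep_family(cfg, protocol=PASSIVE_PROTOCOL)
        assert ephys.input_resistance(rec) == pytest.approx(500.0, abs=0.5)

    def test_unit_consistency_across_three_orders_of_magnitude(self):
        for rin in (5.0, 50.0, 500.0):
            cfg = noiseless_cell(rin_mohm=rin, tau_ms=10.0)
            rec = synth.generate_sweep_family(cfg, protocol=PASSIVE_PROTOCOL)
            assert ephys.input_resistance(rec) == pytest.approx(rin, rel=0.01)

    def test_flat_vi_relationship_flagged(self):
        proto = StepProtocol(-60.0, 20.0, 200.0, 5, onset_ms=50.0, tail_ms=50.0)
        t = np.arange(0, 400.0, 0.2)
        sweeps = [CurrentClampSweep(t, np.full(t.size, -60.0), a, 50.0, 250.0)
                  for a in proto.amplitudes_pa()]
        rec = CurrentClampRecording("flat", sweeps, proto)
        with pytest.raises(EphysError, match="non-physical"):
            ephys.input_resistance(rec)

    def test_noiseless_tau_recovered(self):
        cfg = noiseless_cell(tau_ms=50.0)
        rec = synth.generate_sweep_family(cfg, protocol=PASSIVE_PROTOCOL)
        assert ephys.membrane_tau(rec) == pytest.approx(50.0, abs=0.5)

    def test_capacitance_identity(self):
        cfg = SyntheticCellConfig(rin_mohm=500.0, tau_ms=50.0, noise_sd_mv=0.1, seed=3)
        rec = synth.generate_sweep_family(cfg, protocol=PASSIVE_PROTOCOL)
        props = ephys.passive_properties(rec)
        assert props.capacitance_pf == pytest.approx(
            1000.0 * props.tau_ms / props.rin_mohm, rel=1e-12)
        # true values 500 MOhm / 50 ms give 100 pF; estimates land nearby
        assert props.capacitance_pf == pytest.approx(100.0, rel=0.1)


class TestWaveformFeatures:
    def test_template_slopes_and_latency_recovered(self):
        cfg = noiseless_cell()
        rec = synth.generate_sweep_family(cfg)
        rheo = rec.ground_truth.rheobase_pa
        sweep = next(s for s in rec.sweeps if s.current_amplitude_pa == rheo)
        first = ephys.detect_spikes(sweep)[0]
        up, down, lat = ephys.ap_waveform_features(sweep, first)
        assert up == pytest.approx(rec.ground_truth.upstroke_mv_per_ms, rel=0.02)
        assert down == pytest.approx(rec.ground_truth.downstroke_mv_per_ms, rel=0.02)
        truth_lat = rec.ground_truth.spike_times_ms[
            list(rec.protocol.amplitudes_pa()).index(rheo)][0] - sweep.step_onset_ms
        assert lat == pytest.approx(truth_lat, abs=sweep.dt_ms)

    def test_upstroke_positive_downstroke_negative(self):
        rec = synth.generate_sweep_family(SyntheticCellConfig(seed=11))
        feats = ephys.extract_spike_features(rec)
        assert feats.upstroke_mv_per_ms > 0 > feats.downstroke_mv_per_ms

    def test_silent_cell_yields_none_fields(self):
        rec = synth.generate_sweep_family(noiseless_cell(rin_mohm=50.0))
        feats = ephys.extract_spike_features(rec)
        assert feats.current_threshold_pa is None
        assert feats.voltage_threshold_mv is None
        assert feats.max_spike_count == 0
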