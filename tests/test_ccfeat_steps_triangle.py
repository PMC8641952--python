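"""Step rheobase, firing classification, FI gain, triangular-ramp
hysteresis, sag analysis and single-spike waveform measures."""

import numpy as np
import pytest

from mnephys import ProtocolSpec
from mnephys import ccfeat
from mnephys.errors import (InsufficientFiringError, InvalidSweepError,
                            NotFoundError)
from mnephys.sim import make_preset, simulate_protocol, steady_state_iv
from mnephys.sweep import Sweep, CURRENT_CLAMP, triangle_peak_rate

from conftest import add_stylized_spike


def spike_train_sweep(spike_times, amp_pa, pre_ms=500.0, stim_ms=5000.0,
                      post_ms=300.0, fs=20000.0, baseline=-60.0):
    """Current step sweep carrying stylized spikes at given times (ms,
    absolute)."""
    dt = 1000.0 / fs
    n = int(round((pre_ms + stim_ms + post_ms) / dt))
    t = np.arange(n) * dt
    cmd = np.zeros(n)
    cmd[int(pre_ms / dt):int((pre_ms + stim_ms) / dt)] = amp_pa
    v = np.full(n, baseline)
    for ts in spike_times:
        add_stylized_spike(v, t, ts, peak=30.0)
    return Sweep(time=t, recorded=v, command=cmd, mode=CURRENT_CLAMP)


class TestRheobaseFromSteps:
    def test_first_step_with_three_spikes_wins(self, config):
        """Spike counts [0, 1, 3, 8] at [100, 200, 300, 400] pA → 300."""
        def times(n, start=700.0):
            return [start + 300.0 * k for k in range(n)]
        sweeps = [spike_train_sweep(times(n), amp)
                  for n, amp in ((0, 100.0), (1, 200.0), (3, 300.0),
                                 (8, 400.0))]
        assert ccfeat.rheobase_from_steps(sweeps, config) == 300.0

    def test_all_subthreshold_raises_with_payload(self, config):
        sweeps = [spike_train_sweep([], 100.0),
                  spike_train_sweep([700.0], 200.0)]
        with pytest.raises(NotFoundError) as exc:
            ccfeat.rheobase_from_steps(sweeps, config)
        assert exc.value.payload["max_spike_count"] == 1

    def test_tie_goes_to_lowest_amplitude(self, config):
        times = [700.0, 1000.0, 1300.0]
        sweeps = [spike_train_sweep(times, 400.0),
                  spike_train_sweep(times, 300.0)]
        assert ccfeat.rheobase_from_steps(sweeps, config) == 300.0


class TestClassifyFiringType:
    def test_late_accelerating_train_is_delayed(self, config):
        """Spikes from 2500 ms with shrinking ISIs → delayed."""
        times, t, isi = [], 2500.0, 400.0
        while t < 5400.0:
            times.append(t)
            t += isi
            isi = max(50.0, isi * 0.85)
        sw = spike_train_sweep(times, 200.0)
        fi = ccfeat.classify_firing_type(sw, config)
        assert fi.firing_type == "delayed"
        assert fi.onset_latency == pytest.approx(2000.0, abs=5.0)

    def test_early_steady_train_is_immediate(self, config):
        times = [530.0 + 200.0 * k for k in range(10)]
        sw = spike_train_sweep(times, 200.0)
        fi = ccfeat.classify_firing_type(sw, config)
        assert fi.firing_type == "immediate"
        assert fi.onset_latency == pytest.approx(30.0, abs=5.0)

    def test_ambiguous_combination_flagged(self, config):
        # late onset but decelerating -> neither rule applies
        times, t, isi = [], 3000.0, 200.0
        while t < 5400.0:
            times.append(t)
            t += isi
            isi *= 1.3
        sw = spike_train_sweep(times, 200.0)
        assert ccfeat.classify_firing_type(sw, config).firing_type \
            == "unclassified"

    def test_too_few_spikes_raise(self, config):
        sw = spike_train_sweep([700.0, 1500.0], 200.0)
        with pytest.raises(InsufficientFiringError):
            ccfeat.classify_firing_type(sw, config)


class TestFIAnalysis:
    def make_family(self, rates, amps):
        sweeps = []
        for rate, amp in zip(rates, amps):
            if rate == 0:
                sweeps.append(spike_train_sweep([], amp))
                continue
            isi = 1000.0 / rate
            times = list(np.arange(600.0, 5400.0, isi))
            sweeps.append(spike_train_sweep(times, amp))
        return sweeps

    def test_linear_fi_gain_exact(self, config):
        """Rates [10, 20, 30, 40] Hz at [100..400] pA → 0.1 Hz/pA."""
        sweeps = self.make_family([10, 20, 30, 40], [100, 200, 300, 400])
        fi = ccfeat.fi_analysis(sweeps, None, config)
        assert fi.subprimary_gain == pytest.approx(0.1, rel=0.02)
        assert fi.rate_at_rheobase == pytest.approx(10.0, rel=0.02)
        assert fi.rate_at_2x_rheobase == pytest.approx(20.0, rel=0.02)

    def test_flat_fi_gain_zero(self, config):
        sweeps = self.make_family([15, 15, 15, 15], [100, 200, 300, 400])
        fi = ccfeat.fi_analysis(sweeps, None, config)
        assert fi.subprimary_gain == pytest.approx(0.0, abs=1e-3)

    def test_too_few_suprathreshold_steps(self, config):
        sweeps = self.make_family([0, 0, 20], [100, 200, 300])
        with pytest.raises(InsufficientFiringError):
            ccfeat.fi_analysis(sweeps, None, config)

    def test_gain_restricted_to_initial_section(self, config):
        """A slope collapse after the 2nd point keeps the fit on the
        initial steep section."""
        sweeps = self.make_family([10, 30, 32, 33, 34],
                                  [100, 200, 300, 400, 500])
        fi = ccfeat.fi_analysis(sweeps, None, config)
        assert fi.gain_points == 2
        assert fi.subprimary_gain == pytest.approx(0.2, rel=0.05)


class TestTriangleHysteresis:
    def test_mirror_symmetric_spiking_type1(self, config):
        """Last spike at the same command as the first → ΔI = 0, linear."""
        dt = 0.05
        n = int(10800.0 / dt)
        t = np.arange(n) * dt
        cmd = np.zeros(n)
        n_pre, n_up = int(400.0 / dt), int(5000.0 / dt)
        up = np.linspace(0, 500.0, n_up)
        cmd[n_pre:n_pre + n_up] = up
        cmd[n_pre + n_up:n_pre + 2 * n_up] = up[::-1]
        v = np.full(n, -60.0)
        spike_t = [2400.0, 3400.0, 4400.0, 5400.0,
                   6400.0, 7400.0, 8400.0]  # symmetric about the apex
        for ts in spike_t:
            add_stylized_spike(v, t, ts, peak=30.0)
        sw = Sweep(time=t, recorded=v, command=cmd, mode=CURRENT_CLAMP)
        res = ccfeat.triangle_hysteresis(sw, config)
        assert res.delta_I == pytest.approx(0.0, abs=5.0)
        assert res.hysteresis_type == 1

    def test_strong_nap_gives_sustained_type3(self, config):
        p = make_preset("delayed", 2)
        prot = ProtocolSpec(mode="current", kind="ramp", holding=-60.0,
                            rate=100.0, durations=(500.0, 8000.0, 200.0))
        rheo = ccfeat.rheobase_from_ramp(
            simulate_protocol(p, prot)[0], config).rheobase_I
        tri = ProtocolSpec(mode="current", kind="triangle", holding=-60.0,
                           rate=triangle_peak_rate(2 * rheo),
                           durations=(500.0, 5000.0, 300.0))
        res = ccfeat.triangle_hysteresis(simulate_protocol(p, tri)[0], config)
        assert res.delta_I < 0
        assert res.hysteresis_type == 3

    def test_adapting_no_pic_gives_type2(self, config):
        p = make_preset("immediate", 2).replace(
            g_NaP=0.0, g_CaL=0.0, g_mAHP=300.0, tau_mAHP=400.0)
        prot = ProtocolSpec(mode="current", kind="ramp", holding=-60.0,
                            rate=100.0, durations=(500.0, 8000.0, 200.0))
        rheo = ccfeat.rheobase_from_ramp(
            simulate_protocol(p, prot)[0], config).rheobase_I
        tri = ProtocolSpec(mode="current", kind="triangle", holding=-60.0,
                           rate=triangle_peak_rate(2 * rheo),
                           durations=(500.0, 5000.0, 300.0))
        res = ccfeat.triangle_hysteresis(simulate_protocol(p, tri)[0], config)
        assert res.delta_I > 0
        assert res.hysteresis_type == 2

    def test_single_spike_raises(self, config):
        sw = spike_train_sweep([900.0], 200.0)
        with pytest.raises(InsufficientFiringError):
            ccfeat.triangle_hysteresis(sw, config)


class TestSagAnalysis:
    def step_family(self, p, targets=(-70.0, -80.0, -90.0, -100.0)):
        from mnephys.pipeline import _step_to_target
        amps = tuple(_step_to_target(p, -60.0, v) for v in targets)
        prot = ProtocolSpec(mode="current", kind="step_family", holding=-60.0,
                            amplitudes=amps, durations=(500.0, 1000.0, 300.0))
        return simulate_protocol(p, prot)

    def test_no_hcn_no_sag(self, config):
        p = make_preset("delayed", 3).replace(g_H=0.0)
        res = ccfeat.sag_analysis(self.step_family(p), config)
        assert np.all(np.abs(res.sag_amplitudes) < 1.0)
        assert abs(res.g_sag) < 1.5

    def test_gsag_formula_arithmetic(self):
        """R_init = 100 MΩ, R_ss = 80 MΩ → gSag = 2.5 nS (pure formula,
        via synthetic linear I–V traces)."""
        dt = 0.05
        sweeps = []
        for amp in (-50.0, -100.0):
            n = int(1800.0 / dt)
            t = np.arange(n) * dt
            cmd = np.zeros(n)
            on, off = int(500.0 / dt), int(1500.0 / dt)
            cmd[on:off] = amp
            v = np.full(n, -60.0)
            v_tr = -60.0 + amp * 100.0 / 1000.0
            v_ss = -60.0 + amp * 80.0 / 1000.0
            # fast drop to trough then relax to the plateau
            seg = np.arange(off - on) * dt
            v[on:off] = v_ss + (v_tr - v_ss) * np.exp(-np.maximum(
                seg - 30.0, 0.0) / 150.0)
            v[on:on + int(30.0 / dt)] = np.linspace(-60.0, v_tr,
                                                    int(30.0 / dt))
            sweeps.append(Sweep(time=t, recorded=v, command=cmd,
                                mode=CURRENT_CLAMP))
        res = ccfeat.sag_analysis(sweeps)
        assert res.g_sag == pytest.approx(1000.0 / 80.0 - 1000.0 / 100.0,
                                          rel=0.05)

    def test_single_step_flags_gsag_undefined(self, config):
        p = make_preset("delayed", 3)
        res = ccfeat.sag_analysis(self.step_family(p, (-80.0,)), config)
        assert "g_sag_undefined" in res.flags
        assert np.isnan(res.g_sag)

    def test_delayed_week3_gsag_matches_analytic_slopes(self, config):
        """gSag from simulated steps agrees with the conductance change
        computed from the analytic steady-state I–V at the same voltages
        (within 15%)."""
        p = make_preset("delayed", 3)
        sweeps = self.step_family(p)
        res = ccfeat.sag_analysis(sweeps, config)
        assert res.sag_amplitudes.max() > 2.0  # visible depolarizing sag

        # oracle: instantaneous (H frozen at rest) vs steady-state slopes
        from mnephys.sim.engine import _boltz_inv
        v_lo, v_hi = -95.0, -65.0
        iv = steady_state_iv(p, [v_lo, v_hi])
        g_ss = (iv["total"][1] - iv["total"][0]) / (v_hi - v_lo)
        r0 = float(_boltz_inv(-60.0, p.V_half_H, p.k_H))
        frozen = {}
        for v in (v_lo, v_hi):
            comp = steady_state_iv(p, v)
            frozen[v] = (comp["total"][0] - comp["H"][0]
                         + p.g_H * r0 * (v - p.E_H))
        g_init = (frozen[v_hi] - frozen[v_lo]) / (v_hi - v_lo)
        g_sag_true = g_ss - g_init
        assert res.g_sag == pytest.approx(g_sag_true, rel=0.15)


class TestSpikeAHPFeatures:
    def pulse_sweep(self, thr=-45.0, peak=35.0, rise=1.0, fall=1.0):
        dt = 0.05
        n = int(1000.0 / dt)
        t = np.arange(n) * dt
        cmd = np.zeros(n)
        cmd[int(300.0 / dt):int(310.0 / dt)] = 500.0
        v = np.full(n, -60.0)
        i0 = int(302.0 / dt)
        # linear rise from baseline to threshold over 2 ms, then the spike
        pre = int(2.0 / dt)
        v[i0 - pre:i0] = np.linspace(-60.0, thr, pre)
        n_rise, n_fall = int(rise / dt), int(fall / dt)
        up = np.linspace(thr, peak, n_rise + 1)
        down = np.linspace(peak, thr, n_fall + 1)[1:]
        seg = np.concatenate([up, down])
        v[i0:i0 + seg.size] = seg
        j = i0 + seg.size
        ts = (t[j:] - t[j])
        # monotone return to baseline, no undershoot
        v[j:] = -60.0 + (thr - (-60.0)) * np.exp(-ts / 2.0)
        return Sweep(time=t, recorded=v, command=cmd, mode=CURRENT_CLAMP)

    def test_triangular_spike_geometry(self, config):
        """Threshold −45, peak +35, symmetric 1 ms flanks → amplitude
        80 mV, half-width 1.0 ms."""
        sw = self.pulse_sweep(thr=-45.0, peak=35.0, rise=1.0, fall=1.0)
        ap = ccfeat.spike_ahp_features(sw, config)
        assert ap.amplitude == pytest.approx(80.0, rel=0.02)
        assert ap.half_width == pytest.approx(1.0, abs=0.1)
        assert ap.rise_time == pytest.approx(1.0, abs=0.15)

    def test_monotone_return_flags_mahp_absent(self, config):
        sw = self.pulse_sweep()
        ap = ccfeat.spike_ahp_features(sw, config)
        assert ap.mAHP_amplitude == 0.0
        assert "mahp_absent" in ap.flags

    def test_multiple_spikes_rejected(self, config):
        sw = spike_train_sweep([700.0, 900.0], 300.0)
        with pytest.raises(InvalidSweepError):
            ccfeat.spike_ahp_features(sw, config)

    def test_immediate_broader_spike_and_mahp_than_delayed(self, config):
        """Immediate presets produce broader spikes and longer mAHPs than
        delayed presets (brief suprathreshold pulse)."""
        from mnephys.pipeline import _pulse_threshold
        out = {}
        for subtype in ("delayed", "immediate"):
            p = make_preset(subtype, 2)
            thr = _pulse_threshold(p, 0, config)
            prot = ProtocolSpec(mode="current", kind="pulse", holding=-60.0,
                                amplitudes=(1.25 * thr,),
                                durations=(200.0, 10.0, 500.0))
            sw = simulate_protocol(p, prot)[0]
            out[subtype] = ccfeat.spike_ahp_features(sw, config)
        assert out["immediate"].half_width > out["delayed"].half_width
        assert out["immediate"].mAHP_half_width > \
            out["delayed"].mAHP_half_width
        for ap in out.values():
            assert ap.amplitude > 60.0
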