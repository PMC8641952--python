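"""Voltage-clamp analysis oracles: leak subtraction, PIC measures, Ih
steps, resting Ih and drug-sensitive difference currents."""

import numpy as np
import pytest

from mnephys import ProtocolSpec
from mnephys import vcfeat
from mnephys.errors import (InvalidArgumentError, InvalidProtocolError,
                            ProtocolMismatchError)
from mnephys.sim import (ModelParams, apply_drug, make_preset,
                         simulate_protocol, steady_state_iv)
from mnephys.sweep import Sweep, VOLTAGE_CLAMP

PIC_RAMP = ProtocolSpec(mode="voltage", kind="ramp", holding=-90.0,
                        rate=10.0, durations=(1500.0, 8000.0, 200.0))
IH_STEPS = ProtocolSpec(mode="voltage", kind="step_family", holding=-60.0,
                        amplitudes=tuple(np.arange(-60.0, -111.0, -10.0)),
                        durations=(1000.0, 1000.0, 300.0))


def nap_only_cell(g_nap=5.0, v_half=-45.0, k=5.0, g_l=10.0):
    """Leak + persistent Na only (spike machinery off)."""
    return ModelParams(C_m=150.0, g_L=g_l, E_L=-65.0, g_NaP=g_nap,
                       V_half_NaP=v_half, k_NaP=k).replace(
                           g_Na=0.0, g_K=0.0, g_mAHP=0.0)


class TestLeakSubtract:
    def test_ohmic_null(self, config):
        """A purely ohmic cell leaves < 2 pA residual over the whole ramp."""
        p = ModelParams(C_m=150.0, g_L=10.0, E_L=-65.0).passive_only()
        sw = simulate_protocol(p, PIC_RAMP)[0]
        sub = vcfeat.leak_subtract(sw, config=config)
        interior = slice(200, -200)  # filter edge transients
        assert np.abs(sub.current[interior]).max() < 2.0
        assert sub.leak_slope == pytest.approx(10.0, rel=0.01)

    def test_window_outside_ramp_rejected(self, config):
        p = ModelParams(C_m=150.0, g_L=10.0, E_L=-65.0).passive_only()
        sw = simulate_protocol(p, PIC_RAMP)[0]
        with pytest.raises(InvalidArgumentError):
            vcfeat.leak_subtract(sw, fit_window=(-120.0, -100.0),
                                 config=config)

    def test_escape_transients_suppressed(self, config):
        """Brief current transients (escape-spike surrogates) are reduced
        by > 95% in the filtered, subtracted trace."""
        p = ModelParams(C_m=150.0, g_L=10.0, E_L=-65.0).passive_only()
        sw = simulate_protocol(p, PIC_RAMP)[0]
        contaminated = sw.recorded.copy()
        rng = np.random.default_rng(0)
        spike_amp = 2000.0
        for t_ms in rng.uniform(4000.0, 8000.0, size=8):
            i0 = int(t_ms / sw.dt)
            contaminated[i0:i0 + 40] += spike_amp  # 2 ms transients
        noisy = Sweep(time=sw.time, recorded=contaminated,
                      command=sw.command, mode=VOLTAGE_CLAMP)
        sub = vcfeat.leak_subtract(noisy, config=config)
        assert np.abs(sub.current[200:-200]).max() < 0.05 * spike_amp

    def test_nap_component_matches_analytic(self, config):
        """Subtracted trace tracks the analytic NaP steady-state component
        within 5% of its peak over −70…−30 mV."""
        p = nap_only_cell()
        sw = simulate_protocol(p, PIC_RAMP)[0]
        sub = vcfeat.leak_subtract(sw, config=config)
        mask = (sub.command_V >= -70.0) & (sub.command_V <= -30.0)
        analytic = steady_state_iv(p, sub.command_V[mask])["NaP"]
        scale = np.abs(analytic).max()
        assert np.abs(sub.current[mask] - analytic).max() < 0.05 * scale


class TestPICMeasures:
    def test_ohmic_trace_flagged_absent(self, config):
        p = ModelParams(C_m=150.0, g_L=10.0, E_L=-65.0).passive_only()
        sw = simulate_protocol(p, PIC_RAMP)[0]
        pm = vcfeat.pic_measures(vcfeat.leak_subtract(sw, config=config),
                                 150.0, config=config)
        assert "pic_absent" in pm.flags
        assert pm.amplitude == 0.0

    def test_boltzmann_nap_peak_recovery(self, config):
        """Peak voltage within 2 mV and amplitude within 10% of the
        minimum of the analytic leak-subtracted steady-state I–V."""
        p = nap_only_cell(g_nap=5.0, v_half=-45.0, k=5.0)
        sw = simulate_protocol(p, PIC_RAMP)[0]
        sub = vcfeat.leak_subtract(sw, config=config)
        pm = vcfeat.pic_measures(sub, p.C_m, config=config)

        grid = np.linspace(-90.0, -10.0, 1601)
        iv = steady_state_iv(p, grid)
        leak_line = np.polyval(np.polyfit(
            grid[(grid >= -90) & (grid <= -75)],
            iv["total"][(grid >= -90) & (grid <= -75)], 1), grid)
        resid = iv["total"] - leak_line
        v_peak_true = grid[np.argmin(resid)]
        amp_true = resid.min()
        assert pm.peak_V == pytest.approx(v_peak_true, abs=2.0)
        assert pm.amplitude == pytest.approx(amp_true, rel=0.10)
        assert pm.density == pytest.approx(pm.amplitude / p.C_m, rel=1e-12)

    def test_vhalf_ordering_recovered(self, config):
        """Across a V_half grid the measured onset ordering follows the
        ground-truth ordering exactly."""
        onsets = []
        for v_half in (-50.0, -45.0, -40.0):
            p = nap_only_cell(v_half=v_half)
            sw = simulate_protocol(p, PIC_RAMP)[0]
            pm = vcfeat.pic_measures(
                vcfeat.leak_subtract(sw, config=config), p.C_m,
                config=config)
            onsets.append(pm.onset_V)
        assert onsets[0] < onsets[1] < onsets[2]

    def test_preset_onset_more_depolarized_in_delayed(self, preset_vc_ramps,
                                                      config):
        for week in (2, 3):
            res = {}
            for subtype in ("delayed", "immediate"):
                p, sw = preset_vc_ramps[(subtype, week)]
                sub = vcfeat.leak_subtract(sw, fit_window="auto",
                                           config=config)
                res[subtype] = vcfeat.pic_measures(sub, p.C_m, config=config)
            assert res["delayed"].onset_V > res["immediate"].onset_V

    def test_preset_amplitude_larger_in_delayed(self, preset_vc_ramps,
                                                config):
        for week in (2, 3):
            amp = {}
            for subtype in ("delayed", "immediate"):
                p, sw = preset_vc_ramps[(subtype, week)]
                sub = vcfeat.leak_subtract(sw, fit_window="auto",
                                           config=config)
                amp[subtype] = vcfeat.pic_measures(sub, p.C_m,
                                                   config=config).amplitude
            assert amp["delayed"] < amp["immediate"]  # more inward

    def test_onset_invariant_to_sample_rate(self, config):
        p = nap_only_cell()
        onsets = []
        for fs in (20000.0, 40000.0):
            prot = ProtocolSpec(mode="voltage", kind="ramp", holding=-90.0,
                                rate=10.0, durations=(1500.0, 8000.0, 200.0),
                                sample_rate=fs)
            sw = simulate_protocol(p, prot)[0]
            pm = vcfeat.pic_measures(
                vcfeat.leak_subtract(sw, config=config), p.C_m,
                config=config)
            onsets.append(pm.onset_V)
        assert abs(onsets[0] - onsets[1]) <= 1.0


class TestIhFromSteps:
    def hcn_cell(self, g_h=20.0, tau=200.0):
        return ModelParams(C_m=200.0, g_L=10.0, E_L=-65.0, g_H=g_h,
                           V_half_H=-80.0, k_H=8.0, tau_H=tau,
                           E_H=-35.0).replace(g_Na=0.0, g_K=0.0, g_mAHP=0.0)

    def test_no_hcn_no_amplitude(self, config):
        p = ModelParams(C_m=200.0, g_L=10.0, E_L=-65.0).passive_only()
        sws = simulate_protocol(p, IH_STEPS)
        ih = vcfeat.ih_from_steps(sws, p.C_m, config)
        assert np.nanmax(np.abs(ih.amplitude)) < 2.0

    def test_two_thirds_time_is_tau_ln3(self, config):
        """Constant-τ HCN: time to 2/3 of peak Ih ≈ τ·ln 3 within 10%."""
        p = self.hcn_cell(tau=200.0)
        sws = simulate_protocol(p, IH_STEPS)
        ih = vcfeat.ih_from_steps(sws, p.C_m, config)
        deepest = np.argmin(ih.command_V)
        assert ih.tau[deepest] == pytest.approx(200.0 * np.log(3.0),
                                                rel=0.10)

    def test_amplitude_matches_analytic(self, config):
        """Amplitude at −110 mV within 10% of g_H·Δr∞·(V−E_H)."""
        p = self.hcn_cell()
        sws = simulate_protocol(p, IH_STEPS)
        ih = vcfeat.ih_from_steps(sws, p.C_m, config)
        from mnephys.sim.engine import _boltz_inv
        dr = (_boltz_inv(-110.0, -80.0, 8.0)
              - _boltz_inv(-60.0, -80.0, 8.0))
        expected = 20.0 * float(dr) * (-110.0 + 35.0)
        deepest = np.argmin(ih.command_V)
        assert ih.amplitude[deepest] == pytest.approx(expected, rel=0.10)

    def test_amplitudes_monotone_with_depth(self, config):
        p = make_preset("delayed", 3)
        sws = simulate_protocol(p, IH_STEPS)
        ih = vcfeat.ih_from_steps(sws, p.C_m, config)
        order = np.argsort(-ih.command_V)  # −60 first
        assert np.all(np.diff(ih.amplitude[order]) < 1.0)


class TestRestingIh:
    def test_rmp_above_holding_rejected(self, config):
        p = make_preset("delayed", 3)
        prot = ProtocolSpec(mode="voltage", kind="step", holding=-50.0,
                            amplitudes=(-67.0,),
                            durations=(500.0, 1000.0, 200.0))
        sw = simulate_protocol(p, prot)[0]
        with pytest.raises(InvalidProtocolError):
            vcfeat.resting_ih(sw, p.C_m, rmp=-45.0, config=config)

    def test_no_hcn_variant_near_zero(self, config):
        p = make_preset("delayed", 3).replace(g_H=0.0)
        prot = ProtocolSpec(mode="voltage", kind="step", holding=-50.0,
                            amplitudes=(-66.8,),
                            durations=(1000.0, 1000.0, 300.0))
        sw = simulate_protocol(p, prot)[0]
        res = vcfeat.resting_ih(sw, p.C_m, rmp=-66.8, config=config)
        assert abs(res.resting_Ih) < 10.0


class TestDrugSensitiveCurrent:
    def test_identical_sweeps_zero_difference(self, config):
        p = make_preset("delayed", 3)
        sws = simulate_protocol(p, IH_STEPS)
        diff = vcfeat.drug_sensitive_current(sws, sws, config)
        assert np.abs(diff["delta_pA"]).max() < 1e-9

    def test_full_hcn_block_difference_matches_component(self, config):
        """ZD-like full block: difference at −110 mV equals the simulated
        H component within 5%."""
        p = make_preset("delayed", 3)
        before = simulate_protocol(p, IH_STEPS)
        after = simulate_protocol(apply_drug(p, "zd7288", 1.0), IH_STEPS)
        diff = vcfeat.drug_sensitive_current(before, after, config)
        h_110 = float(steady_state_iv(p, -110.0)["H"][0])
        assert diff["at_-110"] == pytest.approx(-h_110, rel=0.05)

    def test_half_block_half_difference(self, config):
        p = make_preset("delayed", 3)
        before = simulate_protocol(p, IH_STEPS)
        full = vcfeat.drug_sensitive_current(
            before, simulate_protocol(apply_drug(p, "zd7288", 1.0),
                                      IH_STEPS), config)
        half = vcfeat.drug_sensitive_current(
            before, simulate_protocol(apply_drug(p, "zd7288", 0.5),
                                      IH_STEPS), config)
        assert half["at_-110"] == pytest.approx(0.5 * full["at_-110"],
                                                rel=0.10)

    def test_mismatched_protocols_rejected(self, config):
        p = make_preset("delayed", 3)
        a = simulate_protocol(p, IH_STEPS)
        other = ProtocolSpec(mode="voltage", kind="step_family",
                             holding=-60.0,
                             amplitudes=tuple(np.arange(-60.0, -101.0,
                                                        -10.0)),
                             durations=(1000.0, 1000.0, 300.0))
        b = simulate_protocol(p, other)
        with pytest.raises(ProtocolMismatchError):
            vcfeat.drug_sensitive_current(a, b, config)
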