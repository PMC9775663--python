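"""Gate dynamics, exponential conductance, asymmetric I-V, packet output."""

import math

import numpy as np
import pytest

from shuntsyn.oscillator import GateFrequencyMap
from shuntsyn.synapse import (
    SynapseConfig,
    SynapseState,
    apply_input_pulse,
    conductance,
    oscillatory_current,
    peak_gate,
    phi_iv,
    step_gate,
    synaptic_current,
)

CFG = SynapseConfig()


def run_gate(state, cfg, t_end, dt=1e-5):
    """Integrate the gate and return (times, gate trace)."""
    n = int(round(t_end / dt))
    trace = np.empty(n + 1)
    trace[0] = state.V_gate
    for k in range(n):
        state = step_gate(state, k * dt, dt, cfg)
        trace[k + 1] = state.V_gate
    return np.arange(n + 1) * dt, trace, state


class TestGateDynamics:
    def test_zero_efficacy_pulse_leaves_gate_unchanged(self):
        st = apply_input_pulse(SynapseState(w=0), 0.0, CFG)
        _, trace, _ = run_gate(st, CFG, 0.005)
        assert np.all(trace == 0.0)

    def test_binary_weighting_exact(self):
        """Efficacy 8 produces exactly twice the increment of efficacy 4."""
        incr = {}
        for w in (4, 8):
            st = apply_input_pulse(SynapseState(w=w), 0.0, CFG)
            st = step_gate(st, 0.0, CFG.pulse_width, CFG)
            incr[w] = st.V_gate
        assert incr[8] == pytest.approx(2.0 * incr[4], rel=1e-12)

    def test_peak_at_pulse_end(self):
        st = apply_input_pulse(SynapseState(w=8), 0.001, CFG)
        t, trace, _ = run_gate(st, CFG, 0.01)
        assert t[np.argmax(trace)] == pytest.approx(0.001 + CFG.pulse_width, abs=2e-5)

    def test_linear_discharge_arithmetic(self):
        cfg = SynapseConfig(discharge_rate=40.0, charge_rate=10.0)
        st = SynapseState(V_gate=0.2, w=8)
        st = step_gate(st, 0.0, 1e-3, cfg)
        assert st.V_gate == pytest.approx(0.16)

    def test_resting_gate_stays_at_zero(self):
        st = step_gate(SynapseState(V_gate=0.0), 0.0, 0.01, CFG)
        assert st.V_gate == 0.0

    def test_time_to_floor_closed_form(self):
        peak = peak_gate(CFG, 8)
        st = apply_input_pulse(SynapseState(w=8), 0.0, CFG)
        st = step_gate(st, 0.0, CFG.pulse_width, CFG)
        assert st.V_gate == pytest.approx(peak, rel=1e-9)
        t_floor = (peak - CFG.gate_floor) / CFG.discharge_rate
        st = step_gate(st, CFG.pulse_width, t_floor, CFG)
        assert st.V_gate == pytest.approx(CFG.gate_floor, abs=1e-12)

    def test_overlapping_pulses_extend_not_stack(self):
        st = apply_input_pulse(SynapseState(w=8), 0.0, CFG)
        st = apply_input_pulse(st, 0.001, CFG)
        assert st.pulse_start_time == 0.0
        assert st.pulse_end_time == pytest.approx(0.001 + CFG.pulse_width)
        st = step_gate(st, 0.0, 0.003, CFG)
        # charged for the full extended interval at single-pulse rate
        assert st.V_gate == pytest.approx(CFG.charge_rate * 8 * 0.003)

    def test_gate_saturates_at_integrator_ceiling(self):
        st = apply_input_pulse(SynapseState(V_gate=CFG.gate_max - 1e-4, w=15), 0.0, CFG)
        st = step_gate(st, 0.0, CFG.pulse_width, CFG)
        assert st.V_gate == pytest.approx(CFG.gate_max)


class TestConductance:
    def test_zero_at_rest(self):
        assert conductance(SynapseState(V_gate=0.0), CFG) == 0.0

    def test_exponential_decay_time_constant(self):
        """ln g is affine in time; fitted tau matches U_T_eff/discharge_rate."""
        st = apply_input_pulse(SynapseState(w=15), 0.0, CFG)
        st = step_gate(st, 0.0, CFG.pulse_width, CFG)
        dt = 1e-5
        ts, gs = [], []
        t = CFG.pulse_width
        for _ in range(400):
            st = step_gate(st, t, dt, CFG)
            t += dt
            g = conductance(st, CFG)
            if st.V_gate > CFG.gate_floor:
                ts.append(t)
                gs.append(g)
        slope, _ = np.polyfit(ts, np.log(gs), 1)
        tau_fit = -1.0 / slope
        assert tau_fit == pytest.approx(CFG.tau_syn, rel=0.05)

    def test_default_decay_constant_in_hardware_band(self):
        assert 3e-3 <= CFG.tau_syn <= 5e-3

    def test_peak_conductance_monotone_in_efficacy(self):
        peaks = []
        for w in range(16):
            st = apply_input_pulse(SynapseState(w=w), 0.0, CFG)
            st = step_gate(st, 0.0, CFG.pulse_width, CFG)
            peaks.append(conductance(st, CFG))
        assert np.all(np.diff(peaks) >= 0)


class TestSynapticCurrent:
    def test_zero_at_reversal_potential(self):
        st = SynapseState(V_gate=0.05, w=15)
        cfg = SynapseConfig(E_syn=33.0)
        assert synaptic_current(st, cfg, V_mem=33.0) == 0.0

    def test_sign_flips_across_reversal(self):
        st = SynapseState(V_gate=0.05, w=15)
        cfg = SynapseConfig(E_syn=0.0)
        assert synaptic_current(st, cfg, V_mem=-10.0) > 0
        assert synaptic_current(st, cfg, V_mem=+10.0) < 0

    def test_asymmetry_ratio_above_5(self):
        """|I| at E_syn 100 mV above V_mem >> |I| at 100 mV below."""
        st = SynapseState(V_gate=0.05, w=15)
        above = synaptic_current(st, SynapseConfig(E_syn=100.0), V_mem=0.0)
        below = synaptic_current(st, SynapseConfig(E_syn=-100.0), V_mem=0.0)
        assert above > 0 > below
        assert above / abs(below) > 5.0

    def test_current_modes_ignore_membrane_potential(self):
        st = SynapseState(V_gate=0.05, w=15)
        exc = SynapseConfig(mode="excitatory_current")
        vals = {synaptic_current(st, exc, v) for v in (-50.0, 0.0, 80.0)}
        assert len(vals) == 1
        assert vals.pop() > 0  # depolarizing
        inh = SynapseConfig(mode="inhibitory_current")
        assert synaptic_current(st, inh, 0.0) < 0

    def test_phi_continuous_with_unit_slope_at_origin(self):
        assert phi_iv(0.0, 35.0, 700.0) == 0.0
        eps = 1e-6
        assert phi_iv(eps, 35.0, 700.0) / eps == pytest.approx(1.0, rel=1e-4)
        assert phi_iv(-eps, 35.0, 700.0) / -eps == pytest.approx(1.0, rel=1e-4)


class TestOscillatoryOutput:
    def test_silent_oscillator_delivers_nothing(self):
        st = SynapseState(V_gate=0.05, w=15)
        i, ph = oscillatory_current(st, CFG, 0.0, f_inst=0.0, phase=0.3, dt=1e-4)
        assert i == 0.0 and ph == 0.3

    def _event_traces(self, dt):
        """Smooth and packet currents over one full synaptic event."""
        cfg = CFG
        cal = GateFrequencyMap()
        st = apply_input_pulse(SynapseState(w=15), 0.0, cfg)
        t, phase = 0.0, 0.0
        smooth, packets, times = [], [], []
        while t < 0.030:
            i_s = synaptic_current(st, cfg, 0.0)
            f = cal(st.V_gate)
            i_p, phase = oscillatory_current(st, cfg, 0.0, f, phase, dt) if f > 0 else (0.0, phase)
            smooth.append(i_s if st.V_gate > cal.gate_floor else 0.0)
            packets.append(i_p)
            times.append(t)
            st = step_gate(st, t, dt, cfg)
            t += dt
        return np.asarray(times), np.asarray(smooth), np.asarray(packets)

    def test_moving_average_matches_smooth_model(self):
        """5 ms moving average of the packet train tracks the smooth current."""
        t, smooth, packets = self._event_traces(dt=2e-6)
        w = int(round(5e-3 / 2e-6))
        kern = np.ones(w) / w
        ma_p = np.convolve(packets, kern, mode="valid")
        ma_s = np.convolve(smooth, kern, mode="valid")
        mask = ma_s > 0.2 * ma_s.max()
        rel = np.abs(ma_p[mask] - ma_s[mask]) / ma_s[mask]
        assert np.max(rel) < 0.10

    def test_charge_conservation_within_2pct(self):
        t, smooth, packets = self._event_traces(dt=2e-6)
        q_s = np.trapezoid(smooth, t)
        q_p = np.trapezoid(packets, t)
        assert q_p == pytest.approx(q_s, rel=0.02)


class TestValidation:
    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SynapseConfig(mode="bogus")
        with pytest.raises(ValueError):
            SynapseConfig(V_alpha=100.0, V_beta=50.0)
        with pytest.raises(ValueError):
            SynapseConfig(pulse_width=0.0)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            SynapseState(V_gate=-0.1)
        with pytest.raises(ValueError):
            SynapseState(w=16)
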