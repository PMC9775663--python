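"""Subthreshold inverter timing: closed forms, ODE oracle, ring frequency."""

import math

import numpy as np
import pytest

from shuntsyn.oscillator import (
    FrequencyTransient,
    GateFrequencyMap,
    InverterParams,
    OscillatorDrive,
    OscillatorDomainError,
    charge_time,
    discharge_time,
    fit_frequency_transient,
    frequency_transient_from_gate,
    ode_transition_oracle,
    propagation_time,
    ring_frequency,
)
from shuntsyn.synapse import SynapseConfig, peak_gate

PARAMS = InverterParams()
UT = PARAMS.U_T


def random_fall_case(rng):
    vdd = rng.uniform(0.4, 0.8)
    vin = rng.uniform(0.0, vdd - 5 * UT)
    p = InverterParams(
        I0_n=10 ** rng.uniform(-13, -11),
        I0_p=10 ** rng.uniform(-13, -11),
        kappa_n=rng.uniform(0.5, 0.9),
        kappa_p=rng.uniform(0.5, 0.9),
        C_out=rng.uniform(1e-15, 2e-14),
    )
    d = OscillatorDrive(vdd, vin, rng.uniform(vin + 0.05, vdd), rng.uniform(vin + 0.02, vdd))
    return p, d


class TestClosedFormsAgainstOracle:
    def test_discharge_matches_oracle_on_random_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            p, d = random_fall_case(rng)
            t_closed = discharge_time(p, d)
            t_oracle = ode_transition_oracle(p, d, "fall")
            assert t_closed == pytest.approx(t_oracle, rel=1e-2)

    def test_charge_matches_oracle_on_random_grid(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            vdd = rng.uniform(0.4, 0.8)
            vin = rng.uniform(0.0, vdd - 5 * UT)
            p = InverterParams(I0_p=10 ** rng.uniform(-13, -11), kappa_p=rng.uniform(0.5, 0.9))
            d = OscillatorDrive(vdd, vin, rng.uniform(vin, vdd - 0.05), rng.uniform(vin, vdd - 0.02))
            assert charge_time(p, d) == pytest.approx(
                ode_transition_oracle(p, d, "rise"), rel=1e-2
            )

    def test_oracle_tolerance_convergence(self):
        d = OscillatorDrive(0.6, 0.05, 0.6, 0.6)
        t1 = ode_transition_oracle(PARAMS, d, "fall", rtol=1e-8)
        t2 = ode_transition_oracle(PARAMS, d, "fall", rtol=5e-9)
        assert abs(t1 - t2) / t2 < 1e-4

    def test_oracle_rejects_device_off(self):
        d = OscillatorDrive(0.6, 0.05, Vg=0.05, V_initial=0.6)  # Vg at lower rail
        with pytest.raises(OscillatorDomainError):
            ode_transition_oracle(PARAMS, d, "fall")


class TestScalingLaws:
    def test_gate_drive_ratio_e(self):
        """+U_T/kappa_n of gate drive shortens the discharge by a factor e."""
        d1 = OscillatorDrive(0.7, 0.05, 0.55, 0.6)
        d2 = OscillatorDrive(0.7, 0.05, 0.55 + UT / PARAMS.kappa_n, 0.6)
        assert discharge_time(PARAMS, d1) / discharge_time(PARAMS, d2) == pytest.approx(
            math.e, rel=1e-12
        )

    def test_time_linear_in_output_capacitance(self):
        d = OscillatorDrive(0.6, 0.05, 0.6, 0.6)
        p10 = InverterParams(C_out=PARAMS.C_out * 10)
        assert discharge_time(p10, d) == pytest.approx(10 * discharge_time(PARAMS, d))

    def test_time_inverse_in_current_scale(self):
        d = OscillatorDrive(0.6, 0.05, 0.05, 0.05)
        p10 = InverterParams(I0_p=PARAMS.I0_p * 10)
        assert charge_time(p10, d) == pytest.approx(charge_time(PARAMS, d) / 10)

    def test_mirror_symmetry_of_charge_and_discharge(self):
        """Symmetric devices + mirror-symmetric drive give equal times.

        Exact when voltages are referenced to the lower rail (Vin_osc = 0);
        a nonzero lower rail enters the pull-down exponent unscaled and
        breaks the mirror symmetry.
        """
        vdd, vin = 0.6, 0.0
        mid = (vdd + vin) / 2
        vg, vini = 0.55, 0.5
        fall = OscillatorDrive(vdd, vin, vg, vini)
        rise = OscillatorDrive(vdd, vin, 2 * mid - vg, 2 * mid - vini)
        assert discharge_time(PARAMS, fall) == pytest.approx(
            charge_time(PARAMS, rise), rel=1e-12
        )


class TestPropagationTime:
    def test_matches_mean_of_transition_times_within_15pct(self):
        for h in np.linspace(5 * UT, 25 * UT, 40):
            vin = 0.05
            vdd = vin + h
            t_fall = discharge_time(PARAMS, OscillatorDrive(vdd, vin, vdd, vdd))
            t_rise = charge_time(PARAMS, OscillatorDrive(vdd, vin, vin, vin))
            t_p = propagation_time(PARAMS, OscillatorDrive(vdd, vin, vdd, vdd))
            assert abs(t_p - 0.5 * (t_fall + t_rise)) / (0.5 * (t_fall + t_rise)) < 0.15

    def test_monotone_in_lower_rail_and_capacitance(self):
        drives = [OscillatorDrive(0.6, v, 0.6, 0.6) for v in np.linspace(0.1, 0.4, 8)]
        times = [propagation_time(PARAMS, d) for d in drives]
        assert np.all(np.diff(times) > 0)
        p2 = InverterParams(C_out=2 * PARAMS.C_out)
        assert propagation_time(p2, drives[0]) > times[0]

    def test_regime_violation_raises(self):
        with pytest.raises(OscillatorDomainError):
            propagation_time(PARAMS, OscillatorDrive(0.6, 0.6 - 3 * UT, 0.6, 0.6))

    def test_prefactor_linear_under_thermal_rescaling(self):
        """Doubling U_T with the exponent argument held fixed doubles t_P."""
        d = OscillatorDrive(0.6, 0.1, 0.6, 0.6)
        p2 = InverterParams(U_T=2 * UT)
        d2 = OscillatorDrive(1.2, 0.2, 1.2, 1.2)  # voltages scaled with U_T
        assert propagation_time(p2, d2) == pytest.approx(2 * propagation_time(PARAMS, d))


class TestRingFrequency:
    def test_defining_relation(self):
        # t_P = 33.3 us over 3 stages -> f ~ 5 kHz
        t_p = 33.3e-6
        assert 1.0 / (2 * 3 * t_p) == pytest.approx(5.0e3, rel=0.01)

    def test_log_frequency_affine_in_lower_rail(self):
        vins = np.linspace(0.25, 0.45, 20)
        fs = [ring_frequency(PARAMS, OscillatorDrive(0.6, v, 0.6, 0.6)) for v in vins]
        slope, _ = np.polyfit(vins, np.log(fs), 1)
        r = np.corrcoef(vins, np.log(fs))[0, 1]
        assert r**2 > 0.999
        assert slope < 0

    def test_default_calibration_reaches_operating_band(self):
        """Some drive settings must produce 2-25 kHz oscillation."""
        fs = [
            ring_frequency(PARAMS, OscillatorDrive(0.6, v, 0.6, 0.6))
            for v in np.linspace(0.30, 0.40, 41)
        ]
        assert min(fs) < 2e3 < 25e3 < max(fs) or (
            any(f <= 2.5e3 for f in fs) and any(f >= 20e3 for f in fs)
        )


class TestFrequencyTransient:
    def test_silent_gate_gives_zero_frequency(self):
        t = np.linspace(0, 0.05, 100)
        f = frequency_transient_from_gate(t, np.zeros_like(t), GateFrequencyMap())
        assert np.all(f == 0.0)

    def test_linear_discharge_gives_exponential_decay(self):
        cal = GateFrequencyMap()
        t = np.linspace(0, 0.004, 200)
        gate = 0.084 - 13.333 * t  # linear discharge from the full-efficacy peak
        f = frequency_transient_from_gate(t, np.maximum(gate, 0.0), cal)
        active = f > 0
        fit = np.polyfit(t[active], np.log(f[active]), 1)
        resid = np.log(f[active]) - np.polyval(fit, t[active])
        assert np.max(np.abs(resid)) < 1e-9  # exactly affine while above floor
        tr = fit_frequency_transient(t, f)
        assert tr.decay_rate == pytest.approx(13.333 / cal.V_f, rel=1e-6)

    def test_efficacy_anchor_frequencies(self):
        """Peak frequency 2.4 kHz at efficacy 1 and 17.7 kHz at efficacy 15."""
        cal = GateFrequencyMap()
        syn = SynapseConfig()
        assert cal(peak_gate(syn, 1)) == pytest.approx(2.4e3, rel=0.01)
        assert cal(peak_gate(syn, 15)) == pytest.approx(17.7e3, rel=0.01)

    def test_negative_gate_rejected(self):
        with pytest.raises(ValueError):
            frequency_transient_from_gate(
                np.array([0.0, 1.0]), np.array([0.1, -0.1]), GateFrequencyMap()
            )


class TestValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            InverterParams(kappa_n=1.2)
        with pytest.raises(ValueError):
            InverterParams(I0_n=0.0)
        with pytest.raises(ValueError):
            OscillatorDrive(Vdd_osc=0.1, Vin_osc=0.2)
        with pytest.raises(ValueError):
            OscillatorDrive(n_stages=4)
        with pytest.raises(ValueError):
            FrequencyTransient(f_max=-1.0, decay_rate=1.0)
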