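"""Subthreshold inverter timing and the ring-oscillator frequency model.

The transconductance stage of the conductance-based synapse is driven by a
ring oscillator built from current-starved subthreshold inverters.  The time
an inverter takes to charge/discharge its output node through a MOS device in
weak inversion has a closed form; the average of the two transition times is
the per-stage propagation delay, which fixes the oscillation frequency.  This
module provides those closed forms, an independent ODE oracle that integrates
the underlying device equation numerically, and the behavioral map from the
synapse gate variable to the oscillator's instantaneous frequency (the
frequency decays exponentially during a synaptic event because the gate
discharges linearly).

Device model (weak inversion, body effect ignored): the pull-down NMOS with
source at the lower rail ``Vin_osc`` sinks

    I = I0_n * exp((kappa_n*Vg - Vin_osc)/U_T) * (1 - exp(-(Vout - Vin_osc)/U_T))

and the pull-up PMOS with source at ``Vdd_osc`` sources the mirror-image
current.  Transition times are measured to the halfway point between the
starting voltage and the destination rail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InverterParams",
    "OscillatorDrive",
    "FrequencyTransient",
    "GateFrequencyMap",
    "OscillatorDomainError",
    "OscillatorConvergenceError",
    "discharge_time",
    "charge_time",
    "propagation_time",
    "ode_transition_oracle",
    "ring_frequency",
    "frequency_transient_from_gate",
]

U_T_300K = 0.0258  # thermal voltage at ~300 K, volts


class OscillatorDomainError(ValueError):
    """A drive/parameter combination outside the validity of the closed forms."""


class OscillatorConvergenceError(RuntimeError):
    """The numerical transition oracle failed to reach the halfway point."""


@dataclass(frozen=True)
class InverterParams:
    """Weak-inversion device constants of one inverter stage.

    Attributes
    ----------
    I0_n, I0_p:
        Current scaling factors of the pull-down / pull-up device (A).
    kappa_n, kappa_p:
        Capacitive coupling ratios (gate efficiency), dimensionless in (0, 1].
    C_out:
        Output node capacitance (F).
    U_T:
        Thermal voltage (V).
    """

    I0_n: float = 1e-12
    I0_p: float = 1e-12
    kappa_n: float = 0.7
    kappa_p: float = 0.7
    C_out: float = 5e-15
    U_T: float = U_T_300K

    def __post_init__(self) -> None:
        for name in ("I0_n", "I0_p", "kappa_n", "kappa_p", "C_out", "U_T"):
            if not getattr(self, name) > 0:
                raise ValueError(f"InverterParams.{name} must be strictly positive")
        if self.kappa_n > 1 or self.kappa_p > 1:
            raise ValueError("capacitive coupling ratios must be <= 1")


@dataclass(frozen=True)
class OscillatorDrive:
    """Supply/input voltages of the ring during one transition.

    ``Vdd_osc`` is the upper rail, ``Vin_osc`` the (floating, behaviorally
    imposed) lower rail, ``Vg`` the input gate voltage of the switching
    inverter and ``V_initial`` its output voltage when the transition starts.
    ``n_stages`` is the (odd) number of inverters in the ring.
    """

    Vdd_osc: float = 0.6
    Vin_osc: float = 0.05
    Vg: float = 0.6
    V_initial: float = 0.6
    n_stages: int = 3

    def __post_init__(self) -> None:
        if not self.Vdd_osc > self.Vin_osc:
            raise ValueError("Vdd_osc must exceed Vin_osc")
        if self.n_stages < 3 or self.n_stages % 2 == 0:
            raise ValueError("n_stages must be odd and >= 3")


@dataclass(frozen=True)
class FrequencyTransient:
    """Descriptor of the exponential frequency decay in one synaptic event."""

    f_max: float
    decay_rate: float
    t_on: float = 0.0
    t_floor: float = 0.0

    def __post_init__(self) -> None:
        if not self.f_max > 0 or not self.decay_rate > 0:
            raise ValueError("f_max and decay_rate must be positive")
        if self.t_floor < self.t_on:
            raise ValueError("t_floor must be >= t_on")


@dataclass(frozen=True)
class GateFrequencyMap:
    """Behavioral calibration from the synapse gate variable to frequency.

    While the gate exceeds ``gate_floor`` (the analogue of the "4 U_T"
    saturation condition of the integrator's discharge transistor) the
    instantaneous frequency is ``f_scale * exp(V_gate / V_f)``; below the
    floor there is insufficient headroom and the oscillator is off (0 Hz).
    A linearly discharging gate therefore yields an exponentially decaying
    frequency, as observed in the hardware transient.
    """

    f_scale: float = 2080.84  # Hz
    V_f: float = 0.0392400  # V per e-fold of frequency
    gate_floor: float = 2e-3  # V

    def __call__(self, v_gate: np.ndarray | float) -> np.ndarray | float:
        v = np.asarray(v_gate, dtype=float)
        f = np.where(v > self.gate_floor, self.f_scale * np.exp(v / self.V_f), 0.0)
        if np.ndim(v_gate) == 0:
            return float(f)
        return f


def _log_term(headroom: float, U_T: float) -> float:
    """ln{(1 - e^-h/UT) / (e^-h/2UT - e^-h/UT)} evaluated stably.

    Equals h/(2 U_T) + ln(1 - e^-h/UT) - ln(1 - e^-h/2UT); for h >> U_T it
    approaches h/(2 U_T).
    """
    eta = headroom / U_T
    if eta <= 0:
        raise OscillatorDomainError(
            "transition start voltage must lie strictly between the rails "
            f"(headroom {headroom:.4g} V <= 0)"
        )
    return eta / 2.0 + math.log(-math.expm1(-eta)) - math.log(-math.expm1(-eta / 2.0))


def discharge_time(params: InverterParams, drive: OscillatorDrive) -> float:
    """Time t_PHL for the NMOS to pull the output to (V_initial + Vin_osc)/2.

    Strictly positive; exponentially decreasing in the gate voltage ``Vg``
    (one thermal voltage of extra gate drive divided by kappa_n shortens the
    transition by a factor e).
    """
    if not drive.Vg > drive.Vin_osc:
        raise OscillatorDomainError("discharge requires Vg > Vin_osc (pull-down device on)")
    headroom = drive.V_initial - drive.Vin_osc
    if headroom <= 0:
        raise OscillatorDomainError("discharge requires V_initial > Vin_osc")
    drive_exp = math.exp((params.kappa_n * drive.Vg - drive.Vin_osc) / params.U_T)
    prefactor = params.C_out * params.U_T / (params.I0_n * drive_exp)
    return prefactor * _log_term(headroom, params.U_T)


def charge_time(params: InverterParams, drive: OscillatorDrive) -> float:
    """Time t_PLH for the PMOS to pull the output to (V_initial + Vdd_osc)/2."""
    if not drive.Vg < drive.Vdd_osc:
        raise OscillatorDomainError("charge requires Vg < Vdd_osc (pull-up device on)")
    headroom = drive.Vdd_osc - drive.V_initial
    if headroom <= 0:
        raise OscillatorDomainError("charge requires V_initial < Vdd_osc")
    drive_exp = math.exp(params.kappa_p * (drive.Vdd_osc - drive.Vg) / params.U_T)
    prefactor = params.C_out * params.U_T / (params.I0_p * drive_exp)
    return prefactor * _log_term(headroom, params.U_T)


def propagation_time(params: InverterParams, drive: OscillatorDrive) -> float:
    """Per-stage propagation delay: large-headroom mean of t_PHL and t_PLH.

    Valid for rail separation above 4 U_T.  Uses the symmetric-device
    simplification; when the devices differ, the geometric mean of I0 and the
    arithmetic mean of kappa are used.  The log factor of the exact forms is
    replaced by its large-headroom limit (Vdd_osc - Vin_osc)/(2 U_T), keeping
    both branch exponentials, so the result tracks the mean of the exact
    transition times to within a few percent in its regime.
    """
    h = drive.Vdd_osc - drive.Vin_osc
    if h <= 4.0 * params.U_T:
        raise OscillatorDomainError(
            "propagation-time regime violated: rail separation must exceed 4 U_T"
        )
    I0 = math.sqrt(params.I0_n * params.I0_p)
    kappa = 0.5 * (params.kappa_n + params.kappa_p)
    fall = math.exp(-(kappa * drive.Vdd_osc - drive.Vin_osc) / params.U_T)
    rise = math.exp(-kappa * h / params.U_T)
    return params.C_out * h / (4.0 * I0) * (fall + rise)


def ode_transition_oracle(
    params: InverterParams,
    drive: OscillatorDrive,
    direction: str,
    rtol: float = 1e-8,
) -> float:
    """Halfway-crossing time by direct numerical integration of the device ODE.

    This is the independent ground truth for :func:`discharge_time` and
    :func:`charge_time`: it integrates

        C_out dVout/dt = -I_NMOS(Vout)   (fall)
        C_out dVout/dt = +I_PMOS(Vout)   (rise)

    with an adaptive stiff-capable integrator until the output crosses the
    halfway point between ``V_initial`` and the destination rail.

    Raises
    ------
    OscillatorDomainError
        If the driving device is off (no current to move the node).
    OscillatorConvergenceError
        If the crossing is not reached within the integration horizon.
    """
    if direction not in ("fall", "rise"):
        raise ValueError("direction must be 'fall' or 'rise'")
    U = params.U_T
    if direction == "fall":
        if not drive.Vg > drive.Vin_osc:
            raise OscillatorDomainError(
                "fall oracle: pull-down device is off for Vg <= Vin_osc"
            )
        if not drive.V_initial > drive.Vin_osc:
            raise OscillatorDomainError("fall oracle requires V_initial > Vin_osc")
        amp = (params.I0_n / params.C_out) * math.exp(
            (params.kappa_n * drive.Vg - drive.Vin_osc) / U
        )
        target = 0.5 * (drive.V_initial + drive.Vin_osc)

        def rhs(t, y):
            return [-amp * -math.expm1(-(y[0] - drive.Vin_osc) / U)]

    else:
        if not drive.Vg < drive.Vdd_osc:
            raise OscillatorDomainError(
                "rise oracle: pull-up device is off for Vg >= Vdd_osc"
            )
        if not drive.V_initial < drive.Vdd_osc:
            raise OscillatorDomainError("rise oracle requires V_initial < Vdd_osc")
        amp = (params.I0_p / params.C_out) * math.exp(
            params.kappa_p * (drive.Vdd_osc - drive.Vg) / U
        )
        target = 0.5 * (drive.V_initial + drive.Vdd_osc)

        def rhs(t, y):
            return [amp * -math.expm1(-(drive.Vdd_osc - y[0]) / U)]

    def crossing(t, y):
        return y[0] - target

    crossing.terminal = True
    crossing.direction = -1.0 if direction == "fall" else 1.0

    # Horizon found by doubling from a scale set only by the drive current
    # magnitude (independent of the closed forms under test).
    t_span = max(params.C_out * U / (amp * params.C_out), 1e-15)
    for _ in range(80):
        sol = solve_ivp(
            rhs,
            (0.0, t_span),
            [drive.V_initial],
            method="LSODA",
            events=crossing,
            rtol=rtol,
            atol=1e-14,
        )
        if sol.t_events[0].size:
            return float(sol.t_events[0][0])
        if not sol.success:
            raise OscillatorConvergenceError(
                f"integration failed before halfway crossing: {sol.message}"
            )
        t_span *= 2.0
    raise OscillatorConvergenceError(
        "halfway crossing not reached within integration horizon "
        f"(t_span={t_span:.3g} s); drive current may be effectively zero"
    )


def ring_frequency(params: InverterParams, drive: OscillatorDrive) -> float:
    """Oscillation frequency f = 1 / (2 * n_stages * t_P) of the ring.

    The output toggles once per propagation delay and a full period needs two
    traversals of the (odd) chain, hence the standard relation.  Because t_P
    is exponential in the rail separation, ln(f) is affine in Vin_osc.
    """
    t_p = propagation_time(params, drive)
    return 1.0 / (2.0 * drive.n_stages * t_p)


def frequency_transient_from_gate(
    times: np.ndarray,
    gate_trace: np.ndarray,
    calibration: GateFrequencyMap,
) -> np.ndarray:
    """Instantaneous oscillator frequency for a synapse gate trace.

    Total on valid traces: wherever the gate is at or below the calibration
    floor the oscillator lacks headroom and the frequency is exactly 0.
    """
    times = np.asarray(times, dtype=float)
    gate = np.asarray(gate_trace, dtype=float)
    if gate.shape != times.shape:
        raise ValueError("times and gate_trace must have the same shape")
    if np.any(gate < 0):
        raise ValueError("gate trace must be non-negative")
    return np.asarray(calibration(gate), dtype=float)


def fit_frequency_transient(
    times: np.ndarray, freq: np.ndarray, t_on: float = 0.0
) -> FrequencyTransient:
    """Fit f(t) = f_max * exp(-decay_rate (t - t_on)) to the active samples."""
    times = np.asarray(times, dtype=float)
    freq = np.asarray(freq, dtype=float)
    active = freq > 0
    if active.sum() < 2:
        raise ValueError("need at least two active samples to fit a transient")
    t = times[active]
    lf = np.log(freq[active])
    slope, intercept = np.polyfit(t, lf, 1)
    if slope >= 0:
        raise ValueError("frequency trace is not decaying")
    return FrequencyTransient(
        f_max=float(math.exp(intercept + slope * t_on)),
        decay_rate=float(-slope),
        t_on=float(t_on),
        t_floor=float(t.max()),
    )
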