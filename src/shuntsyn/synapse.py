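"""Behavioral model of one 4-bit conductance-based synapse.

The circuit being modeled has three stages: a binary-weighted DAC that, for
the ~2 ms duration of an input pulse, charges a gate node at a rate
proportional to the 4-bit efficacy; an integrator that discharges the gate
linearly at a constant rate; and an output stage that converts the linear
gate voltage into an exponential conductance.  Because the gate decays
linearly, the conductance (and hence the synaptic current) decays
exponentially, with time constant ``U_T_eff / discharge_rate``.

Three output modes are provided:

``excitatory_current`` / ``inhibitory_current``
    Current-based operation: a stereotyped current independent of the
    postsynaptic potential (positive current depolarizes).
``conductance``
    The current is ``g * Phi(E_syn - V_mem)`` where ``Phi`` is a continuous,
    asymmetric current–voltage curve: sign-preserving, zero at the reversal
    potential, unit slope there, and exponentially larger in magnitude on the
    ``E_syn > V_mem`` side — the emulated resistance is exponentially larger
    when the membrane sits above the reversal potential.

The conductance mode additionally supports an oscillatory charge-packet
output that mimics the switched-capacitor stage clocked by the ring
oscillator: current is delivered in rectangular packets at the oscillator
frequency whose time average equals the smooth conductance-mode current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SynapseConfig",
    "SynapseState",
    "phi_iv",
    "apply_input_pulse",
    "step_gate",
    "conductance",
    "synaptic_current",
    "oscillatory_current",
    "peak_gate",
]

_MODES = ("excitatory_current", "inhibitory_current", "conductance")

W_MAX = 15  # four-bit efficacy


@dataclass(frozen=True)
class SynapseConfig:
    """Behavioral parameters of a synapse circuit.

    Attributes
    ----------
    mode:
        Output stage configuration; one of ``excitatory_current``,
        ``inhibitory_current``, ``conductance``.
    E_syn:
        Synaptic reversal potential (mV), conductance mode only.
    charge_rate:
        Gate charge rate per unit efficacy during an input pulse (V/s per
        efficacy step; behavioral stand-in for the DAC bias).
    discharge_rate:
        Constant gate discharge rate (V/s; stand-in for the integrator's
        discharge bias and capacitance).
    gate_floor:
        Gate voltage below which the oscillator lacks headroom and the
        linear-discharge description ends (V).
    pulse_width:
        Input pulse duration (s).
    g_unit:
        Conductance scale (nS): the conductance at ``V_gate == V_ref``.
    U_T_eff:
        Effective thermal voltage of the gate-to-conductance conversion (V);
        the synaptic decay time constant is ``U_T_eff / discharge_rate``.
    V_ref:
        Gate reference voltage of the conversion (V); defaults to the peak
        gate voltage reached by a single maximal-efficacy pulse, so that
        ``g_unit`` is the peak conductance at efficacy 15.
    V_alpha, V_beta:
        Exponential scales (mV) of the asymmetric I–V curve for the
        ``E_syn > V_mem`` and ``E_syn < V_mem`` sides; ``V_beta >> V_alpha``.
    s_exc, s_inh:
        Current-mode scale factors (mV-equivalent: current is ``g * s``).
    osc_duty:
        Duty fraction of the oscillatory charge packets.
    """

    mode: str = "conductance"
    E_syn: float = 120.0
    charge_rate: float = 2.8
    discharge_rate: float = 40.0 / 3.0
    gate_floor: float = 2e-3
    pulse_width: float = 2e-3
    g_unit: float = 0.00808
    U_T_eff: float = 0.04
    V_ref: Optional[float] = None
    V_alpha: float = 35.0
    V_beta: float = 700.0
    s_exc: float = 500.0
    s_inh: float = 500.0
    osc_duty: float = 0.5
    gate_max: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        for name in ("charge_rate", "discharge_rate", "gate_floor", "pulse_width",
                     "g_unit", "U_T_eff", "V_alpha", "V_beta", "s_exc", "s_inh"):
            if not getattr(self, name) > 0:
                raise ValueError(f"SynapseConfig.{name} must be strictly positive")
        if not self.V_beta > self.V_alpha:
            raise ValueError("V_beta must exceed V_alpha (asymmetric I-V)")
        if not 0.0 < self.osc_duty < 1.0:
            raise ValueError("osc_duty must lie in (0, 1)")
        if self.V_ref is None:
            object.__setattr__(self, "V_ref", peak_gate(self, W_MAX))
        if self.gate_max is None:
            # integrator linear range: one maximal-efficacy pulse from rest;
            # closely spaced pulses saturate instead of stacking further
            object.__setattr__(self, "gate_max", peak_gate(self, W_MAX))
        if self.gate_max <= 0:
            raise ValueError("gate_max must be positive")

    @property
    def tau_syn(self) -> float:
        """Decay time constant of the synaptic conductance (s)."""
        return self.U_T_eff / self.discharge_rate


def peak_gate(cfg: SynapseConfig, w: int) -> float:
    """Gate voltage at the end of a single input pulse from rest, efficacy w.

    Exactly linear in the efficacy: during the pulse the DAC current
    dominates and the discharge path is inactive, so the increment is
    ``charge_rate * w * pulse_width``.
    """
    return cfg.charge_rate * w * cfg.pulse_width


@dataclass
class SynapseState:
    """Mutable state of one synapse: gate voltage, efficacy, pulse interval."""

    V_gate: float = 0.0
    w: int = 8
    pulse_start_time: Optional[float] = None
    pulse_end_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.V_gate < 0:
            raise ValueError("V_gate must be non-negative")
        if not 0 <= self.w <= W_MAX:
            raise ValueError(f"efficacy must lie in [0, {W_MAX}]")


def apply_input_pulse(state: SynapseState, t: float, cfg: SynapseConfig) -> SynapseState:
    """Register an input pulse on ``[t, t + pulse_width]``.

    The DAC charges the gate at ``charge_rate * w`` while a pulse is active;
    a pulse overlapping an already-active one extends the active interval
    rather than stacking (a single input transistor drives the DAC).
    """
    if t < 0:
        raise ValueError("pulse time must be non-negative")
    end = t + cfg.pulse_width
    if state.pulse_end_time is not None and state.pulse_end_time >= t:
        return replace(
            state,
            pulse_start_time=min(state.pulse_start_time, t),
            pulse_end_time=max(state.pulse_end_time, end),
        )
    return replace(state, pulse_start_time=t, pulse_end_time=end)


def step_gate(state: SynapseState, t: float, dt: float, cfg: SynapseConfig) -> SynapseState:
    """Advance the gate from ``t`` to ``t + dt`` (piecewise-linear dynamics).

    While a pulse is active the gate charges at ``charge_rate * w`` (the DAC
    current dominates and the discharge path is off, so the per-pulse
    increment is exactly binary-weighted); otherwise it discharges at
    ``discharge_rate``, clamped at zero.  The step is split exactly at pulse
    edges falling inside it.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    v = state.V_gate
    start, end = state.pulse_start_time, state.pulse_end_time
    t_remaining = dt
    now = t
    while t_remaining > 1e-15:
        if start is not None and now < start:
            seg = min(t_remaining, start - now)
            v -= cfg.discharge_rate * seg
        elif end is not None and now < end:
            seg = min(t_remaining, end - now)
            v = min(v + cfg.charge_rate * state.w * seg, cfg.gate_max)
        else:
            seg = t_remaining
            v -= cfg.discharge_rate * seg
        v = max(v, 0.0)
        now += seg
        t_remaining -= seg
    if end is not None and end <= now:
        start, end = None, None
    return replace(state, V_gate=v, pulse_start_time=start, pulse_end_time=end)


def conductance(state: SynapseState, cfg: SynapseConfig) -> float:
    """Instantaneous synaptic conductance (nS).

    Exponential conversion of the linear gate: ``g_unit * exp((V_gate -
    V_ref)/U_T_eff)`` for a positive gate, exactly 0 at rest (the ~fA static
    leakage of the physical circuit is not modeled).
    """
    if state.V_gate <= 0.0:
        return 0.0
    return cfg.g_unit * math.exp((state.V_gate - cfg.V_ref) / cfg.U_T_eff)


def phi_iv(x: np.ndarray | float, V_alpha: float, V_beta: float) -> np.ndarray | float:
    """Asymmetric driving-force curve Phi(E_syn - V_mem) in mV.

    Continuous, Phi(0) = 0, slope 1 at the origin; exponential growth with
    scale ``V_alpha`` for positive arguments, saturating (scale ``V_beta``,
    with ``V_beta >> V_alpha``) for negative ones, so the emulated resistance
    is exponentially larger on the ``E_syn < V_mem`` side.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0.0,
        V_alpha * np.expm1(np.minimum(x, 60.0 * V_alpha) / V_alpha),
        -V_beta * (-np.expm1(np.maximum(x, -60.0 * V_beta) / V_beta)),
    )
    if out.ndim == 0:
        return float(out)
    return out


def synaptic_current(state: SynapseState, cfg: SynapseConfig, V_mem: float) -> float:
    """Synaptic current (pA) into the postsynaptic node; positive depolarizes.

    Current modes ignore ``V_mem`` entirely; conductance mode implements the
    phenomenological law I = g * Phi(E_syn - V_mem), which vanishes exactly at
    the reversal potential and changes sign across it.
    """
    g = conductance(state, cfg)
    if cfg.mode == "excitatory_current":
        return g * cfg.s_exc
    if cfg.mode == "inhibitory_current":
        return -g * cfg.s_inh
    return g * phi_iv(cfg.E_syn - V_mem, cfg.V_alpha, cfg.V_beta)


def oscillatory_current(
    state: SynapseState,
    cfg: SynapseConfig,
    V_mem: float,
    f_inst: float,
    phase: float,
    dt: float,
) -> tuple[float, float]:
    """Charge-packet output of the switched-capacitor stage.

    Within each oscillator period ``1/f_inst`` the packet occupies a fixed
    duty fraction of the period and carries the charge the smooth model would
    deliver, so the moving average of the packet train reproduces the smooth
    current and the total delivered charge matches the smooth model's
    integral.  The returned value is the packet current averaged over the
    step ``[t, t + dt]`` (the exact on-phase measure of the interval is used,
    so charge is conserved even when the oscillator period is shorter than
    the step).  Returns ``(current_pA, new_phase)``; ``phase`` is the
    oscillator phase in cycles.  A silent oscillator (``f_inst == 0``)
    delivers nothing.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    if f_inst < 0:
        raise ValueError("f_inst must be non-negative")
    if f_inst == 0.0:
        return 0.0, phase
    i_smooth = synaptic_current(state, cfg, V_mem)
    duty = cfg.osc_duty
    ph1 = phase + f_inst * dt

    def on_measure(x: float) -> float:
        fl = math.floor(x)
        return duty * fl + min(x - fl, duty)

    on_frac = (on_measure(ph1) - on_measure(phase)) / (ph1 - phase)
    return i_smooth * on_frac / duty, ph1 - math.floor(phase)
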