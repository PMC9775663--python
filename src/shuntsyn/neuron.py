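"""Soma stand-in and the two neuron wiring configurations.

The spiking soma is a leaky integrate-and-fire unit with a refractory period
(Class 1: its f–I curve rises continuously from 0 Hz, with no
spike-frequency adaptation), standing in for the qualitative silicon soma.

Two wirings are supported:

``single_compartment``
    A current conveyor clamps the shared postsynaptic node at
    ``V_post_clamp``, so conductance-mode synapses see a constant membrane
    potential and their currents are independent of the soma trajectory; the
    conveyor replicates the summed current into the soma with either
    polarity.

``two_compartment_unidirectional``
    Synapses drive a dendritic RC node (capacitor plus a leak implemented by
    one synapse circuit held in its conductance configuration) and the
    dendrite couples one-way into the soma through a resistor: current
    ``(V_den - V_mem)/R_c`` flows into the soma only, with exactly zero
    back-action on the dendrite.

Positive synaptic current depolarizes (conventional polarity throughout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .synapse import SynapseConfig, phi_iv

__all__ = [
    "SomaParams",
    "DendriteParams",
    "NetworkConfig",
    "SomaState",
    "step_soma",
    "step_dendrite",
    "coupling_current",
    "conveyor_sum",
]


@dataclass(frozen=True)
class SomaParams:
    """Leaky integrate-and-fire constants.

    C_mem (pF), g_leak (nS), potentials (mV), refractory period t_refr (s).
    """

    C_mem: float = 1.5
    g_leak: float = 1.0
    V_rest: float = 0.0
    V_thresh: float = 162.0
    V_reset: float = 0.0
    t_refr: float = 8e-3

    def __post_init__(self) -> None:
        if not (self.C_mem > 0 and self.g_leak > 0 and self.t_refr > 0):
            raise ValueError("C_mem, g_leak, t_refr must be strictly positive")
        if self.V_thresh == self.V_rest:
            raise ValueError("V_thresh must differ from V_rest")

    @property
    def tau_mem(self) -> float:
        """Membrane time constant (s)."""
        return 1e-3 * self.C_mem / self.g_leak


@dataclass(frozen=True)
class DendriteParams:
    """Dendritic compartment: capacitor, one-way coupling, synaptic leak.

    ``leak_synapse`` is a conductance-mode synapse configuration acting as
    the leak resistor toward its reversal potential; its gate is frozen at
    ``leak_gate`` volts (the circuit used as a resistor with a fixed gate).
    """

    C_den: float = 8.5
    R_c: float = 1000.0
    leak_synapse: SynapseConfig = field(
        default_factory=lambda: SynapseConfig(mode="conductance", E_syn=0.0, g_unit=1.0)
    )
    leak_gate: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.C_den > 0 and self.R_c > 0):
            raise ValueError("C_den and R_c must be strictly positive")
        if self.leak_synapse.mode != "conductance":
            raise ValueError("leak synapse must be in conductance mode")
        if self.leak_gate is None:
            object.__setattr__(self, "leak_gate", self.leak_synapse.V_ref)

    @property
    def g_leak_den(self) -> float:
        """Small-signal leak conductance at the frozen gate (nS)."""
        cfg = self.leak_synapse
        return cfg.g_unit * math.exp((self.leak_gate - cfg.V_ref) / cfg.U_T_eff)

    def leak_current(self, V_den: float) -> float:
        """Current (pA) through the frozen-gate leak synapse at ``V_den``."""
        cfg = self.leak_synapse
        return self.g_leak_den * phi_iv(cfg.E_syn - V_den, cfg.V_alpha, cfg.V_beta)


@dataclass(frozen=True)
class NetworkConfig:
    """Wiring of the synapse population onto the neuron."""

    configuration: str = "single_compartment"
    V_post_clamp: float = 0.0
    conveyor_polarity: str = "same"
    synapse_assignment: Sequence[tuple] = ()

    def __post_init__(self) -> None:
        if self.configuration not in (
            "single_compartment",
            "two_compartment_unidirectional",
        ):
            raise ValueError("unknown neuron configuration")
        if self.conveyor_polarity not in ("same", "reversed"):
            raise ValueError("conveyor polarity must be 'same' or 'reversed'")


@dataclass
class SomaState:
    """Membrane potential plus refractory bookkeeping."""

    V: float = 0.0
    refr_until: float = float("-inf")


def step_soma(
    state: SomaState,
    I_in: float,
    t: float,
    dt: float,
    params: SomaParams,
) -> tuple[SomaState, Optional[float]]:
    """One integrate-and-fire step; returns (state, spike time or None).

    Forward-Euler update of C dV/dt = -g_leak (V - V_rest) + I_in, with the
    threshold crossing located by linear interpolation inside the step and
    the membrane held at ``V_reset`` through the refractory period.
    """
    if not 0 < dt <= 5e-4:
        raise ValueError("dt must be positive and at most 0.5 ms")
    if t < state.refr_until:
        state.V = params.V_reset
        return state, None
    v_old = state.V
    dv = dt * 1e3 * (-(params.g_leak) * (v_old - params.V_rest) + I_in) / params.C_mem
    v_new = v_old + dv
    rising = params.V_thresh > params.V_rest
    crossed = v_new >= params.V_thresh if rising else v_new <= params.V_thresh
    if crossed:
        frac = (params.V_thresh - v_old) / (v_new - v_old) if v_new != v_old else 1.0
        t_spike = t + frac * dt
        state.V = params.V_reset
        state.refr_until = t_spike + params.t_refr
        return state, t_spike
    state.V = v_new
    return state, None


def step_dendrite(
    V_den: float,
    synapse_currents: Iterable[float],
    params: DendriteParams,
    dt: float,
) -> float:
    """Advance the dendritic potential by one step.

    C_den dV/dt = sum(I_syn) + I_leak(V_den); the unidirectional coupling
    resistor carries no current into or out of this compartment, so the
    trajectory is bit-identical no matter what the soma does.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    i_total = float(sum(synapse_currents)) + params.leak_current(V_den)
    return V_den + dt * 1e3 * i_total / params.C_den


def coupling_current(V_den: float, V_mem: float, R_c: float) -> float:
    """Current (pA) delivered to the soma by the one-way resistor.

    I = (V_den - V_mem)/R_c with R_c in megaohms; both signs are permitted at
    the soma and the dendrite never sees this current.
    """
    if not R_c > 0:
        raise ValueError("R_c must be positive")
    return 1e3 * (V_den - V_mem) / R_c


def conveyor_sum(synapse_currents: Iterable[float], polarity: str = "same") -> float:
    """Summed synapse current replicated by the current conveyor (pA).

    The conveyor's two output branches deliver the sum with the same or the
    reversed polarity.  All conductance-mode synapses feeding it were
    evaluated at the clamped node voltage, so the result does not depend on
    the soma potential.
    """
    total = float(sum(synapse_currents))
    if polarity == "same":
        return total
    if polarity == "reversed":
        return -total
    raise ValueError("polarity must be 'same' or 'reversed'")
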