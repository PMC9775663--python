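"""Shunting-inhibition demonstration on the two-compartment neuron.

Protocol (mirroring the hardware demonstration): all synapses at maximal
efficacy, learning off.

1. One excitatory (current-based) synapse is pulsed alone: the dendrite shows
   a clear EPSP.
2. The shunting synapse (conductance mode, reversal just above rest) is
   pulsed alone: the dendrite barely moves — shunting inhibition raises the
   local conductance without hyperpolarizing.
3. Both together: the EPSP is attenuated by the conductance divider.

Then synchronous volleys: the minimal number of excitatory synapses that
spikes the soma (four under the default calibration), the same volley plus
the shunting synapse (spike blocked), and five excitatory plus the shunting
synapse (inhibition overpowered).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .neuron import DendriteParams, SomaParams, SomaState, coupling_current, step_dendrite, step_soma
from .synapse import SynapseConfig, SynapseState, apply_input_pulse, step_gate, synaptic_current

__all__ = ["ShuntingConfig", "ShuntingResult", "run_shunting_protocol"]


@dataclass(frozen=True)
class ShuntingConfig:
    """Calibrated defaults of the shunting demonstration."""

    exc_synapse: SynapseConfig = field(
        default_factory=lambda: SynapseConfig(mode="excitatory_current", g_unit=0.06, s_exc=500.0)
    )
    shunt_synapse: SynapseConfig = field(
        default_factory=lambda: SynapseConfig(mode="conductance", E_syn=1.0, g_unit=3.0)
    )
    dendrite: DendriteParams = field(default_factory=DendriteParams)
    soma: SomaParams = field(
        default_factory=lambda: SomaParams(
            C_mem=5.0, g_leak=1.0, V_rest=0.0, V_thresh=10.6, V_reset=0.0, t_refr=5e-3
        )
    )
    dt: float = 5e-5
    t_pulse: float = 0.02
    t_total: float = 0.15


@dataclass
class ShuntingResult:
    """Traces and summary numbers of the full protocol."""

    times: np.ndarray
    v_den_exc: np.ndarray
    v_den_shunt: np.ndarray
    v_den_both: np.ndarray
    epsp_exc: float
    deflection_shunt: float
    epsp_both: float
    attenuation_pct: float
    spikes_exc_only: int
    spikes_exc_shunt: int
    spikes_overpower: int
    n_exc_volley: int

    def summary(self) -> str:
        lines = [
            f"run 1  EPSP peak (1 excitatory)            {self.epsp_exc:8.3f} mV",
            f"run 2  deflection (shunting alone)         {self.deflection_shunt:8.3f} mV"
            f"  ({100 * self.deflection_shunt / self.epsp_exc:.1f}% of EPSP)",
            f"run 3  EPSP peak (excitatory + shunting)   {self.epsp_both:8.3f} mV"
            f"  (attenuation {self.attenuation_pct:.1f}%)",
            f"volley {self.n_exc_volley} excitatory              -> {self.spikes_exc_only} soma spike(s)",
            f"volley {self.n_exc_volley} excitatory + shunting   -> {self.spikes_exc_shunt} soma spike(s)",
            f"volley {self.n_exc_volley + 1} excitatory + shunting   -> {self.spikes_overpower} soma spike(s)",
        ]
        return "\n".join(lines)


def _simulate(
    cfg: ShuntingConfig,
    n_exc: int,
    with_shunt: bool,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One run: returns (times, dendritic trace, soma spike count)."""
    dt = cfg.dt
    n_steps = int(round(cfg.t_total / dt))
    exc = SynapseState(V_gate=0.0, w=15)
    shunt = SynapseState(V_gate=0.0, w=15)
    if n_exc > 0:
        exc = apply_input_pulse(exc, cfg.t_pulse, cfg.exc_synapse)
    if with_shunt:
        shunt = apply_input_pulse(shunt, cfg.t_pulse, cfg.shunt_synapse)
    v_den = cfg.dendrite.leak_synapse.E_syn  # dendrite rests at the leak reversal
    soma = SomaState(V=cfg.soma.V_rest)
    trace = np.empty(n_steps + 1)
    trace[0] = v_den
    times = np.arange(n_steps + 1) * dt
    spikes = 0
    for k in range(n_steps):
        t = k * dt
        currents: List[float] = []
        if n_exc > 0:
            currents.append(n_exc * synaptic_current(exc, cfg.exc_synapse, v_den))
        if with_shunt:
            currents.append(synaptic_current(shunt, cfg.shunt_synapse, v_den))
        v_den_next = step_dendrite(v_den, currents, cfg.dendrite, dt)
        i_c = coupling_current(v_den, soma.V, cfg.dendrite.R_c)
        soma, t_spk = step_soma(soma, i_c, t, dt, cfg.soma)
        if t_spk is not None:
            spikes += 1
        if n_exc > 0:
            exc = step_gate(exc, t, dt, cfg.exc_synapse)
        if with_shunt:
            shunt = step_gate(shunt, t, dt, cfg.shunt_synapse)
        v_den = v_den_next
        trace[k + 1] = v_den
    return times, trace, spikes


def run_shunting_protocol(
    cfg: Optional[ShuntingConfig] = None, n_exc_volley: int = 4
) -> ShuntingResult:
    """Run the three single-synapse runs plus the synchronous volleys."""
    if cfg is None:
        cfg = ShuntingConfig()
    baseline = cfg.dendrite.leak_synapse.E_syn
    times, tr_exc, _ = _simulate(cfg, n_exc=1, with_shunt=False)
    _, tr_shunt, _ = _simulate(cfg, n_exc=0, with_shunt=True)
    _, tr_both, _ = _simulate(cfg, n_exc=1, with_shunt=True)
    epsp_exc = float(np.max(tr_exc - baseline))
    deflection = float(np.max(np.abs(tr_shunt - baseline)))
    epsp_both = float(np.max(tr_both - baseline))
    attenuation = 100.0 * (1.0 - epsp_both / epsp_exc)
    _, _, n_spk_exc = _simulate(cfg, n_exc=n_exc_volley, with_shunt=False)
    _, _, n_spk_blocked = _simulate(cfg, n_exc=n_exc_volley, with_shunt=True)
    _, _, n_spk_over = _simulate(cfg, n_exc=n_exc_volley + 1, with_shunt=True)
    return ShuntingResult(
        times=times,
        v_den_exc=tr_exc,
        v_den_shunt=tr_shunt,
        v_den_both=tr_both,
        epsp_exc=epsp_exc,
        deflection_shunt=deflection,
        epsp_both=epsp_both,
        attenuation_pct=attenuation,
        spikes_exc_only=n_spk_exc,
        spikes_exc_shunt=n_spk_blocked,
        spikes_overpower=n_spk_over,
        n_exc_volley=n_exc_volley,
    )
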