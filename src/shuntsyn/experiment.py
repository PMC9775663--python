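"""End-to-end spike-pattern detection experiment.

All afferents drive one neuron in the single-compartment configuration: the
current conveyor clamps the shared postsynaptic node, every synapse runs in
the conductance-based configuration (smooth or oscillatory charge-packet
output), and the adaptive STDP rule updates the 4-bit efficacies from the
pre/post spike streams.  After the run, occurrences of the embedded pattern
in the final scoring window are checked for output spikes: a *hit* is an
occurrence containing at least one soma spike, a *false alarm* a soma spike
outside every occurrence.  A run succeeds when the hit rate exceeds 98% with
zero false alarms in the last 75 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from ._engine import run_kernel
from .neuron import NetworkConfig, SomaParams
from .oscillator import GateFrequencyMap
from .plasticity import LearningParams, t_post_at
from .synapse import SynapseConfig, phi_iv
from .taskgen import SpikeTrainSet, TaskConfig, generate

__all__ = [
    "DetectionNetwork",
    "ExperimentResult",
    "BatchResult",
    "run_detection",
    "score",
    "success",
    "batch",
    "default_detection_network",
    "default_learning",
]

SCORE_WINDOW = 75.0  # scoring window at the end of a run (s)
HIT_RATE_CRITERION = 98.0  # strict lower bound on the hit rate (%)


@dataclass(frozen=True)
class DetectionNetwork:
    """Neuron + synapse configuration of the detection experiment."""

    synapse: SynapseConfig = field(
        default_factory=lambda: SynapseConfig(mode="conductance", E_syn=120.0)
    )
    soma: SomaParams = field(default_factory=SomaParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    frequency_map: GateFrequencyMap = field(default_factory=GateFrequencyMap)
    output_stage: str = "smooth"  # "smooth" | "oscillatory"
    dt: float = 1e-4
    w_init: int = 8

    def __post_init__(self) -> None:
        if self.output_stage not in ("smooth", "oscillatory"):
            raise ValueError("output_stage must be 'smooth' or 'oscillatory'")
        if self.synapse.mode != "conductance":
            raise ValueError("the detection experiment uses conductance-mode synapses")
        if self.network.configuration != "single_compartment":
            raise ValueError("the detection experiment runs single-compartment")


@dataclass
class ExperimentResult:
    """Output of one detection run."""

    post_spike_times: np.ndarray
    final_weights: np.ndarray
    weight_trace: np.ndarray  # snapshots (n_snapshots, n_aff)
    t_post_trace: np.ndarray  # (n_snapshots,) LTD window at each snapshot (s)
    snapshot_times: np.ndarray
    hits: int = 0
    false_alarms: int = 0
    n_occurrences_scored: int = 0
    hit_rate: float = float("nan")
    success: bool = False
    initial_rate: float = float("nan")  # output rate in the first 5 s (Hz)
    seed: Optional[int] = None


def default_detection_network(output_stage: str = "smooth") -> DetectionNetwork:
    """The study conditions of the detection experiment."""
    return DetectionNetwork(output_stage=output_stage)


def default_learning() -> LearningParams:
    """Adaptive STDP defaults used by the detection experiment."""
    return LearningParams()


def run_detection(
    ts: SpikeTrainSet,
    network: Optional[DetectionNetwork] = None,
    learning: Optional[LearningParams] = None,
    seed: Optional[int] = None,
    learn: bool = True,
    snapshot_dt: float = 5.0,
) -> ExperimentResult:
    """Simulate the full train set and score the final window.

    Each afferent spike triggers the DAC pulse of its synapse and the LTD
    branch of the rule; each soma spike triggers the LTP branch on every
    synapse.  Identical inputs give bit-identical results.
    """
    if network is None:
        network = default_detection_network()
    if learning is None:
        learning = default_learning()
    if learning.t_post_schedule is not None:
        raise ValueError(
            "the vectorized experiment supports the built-in linear schedule only"
        )
    cfg = ts.config
    n_aff = ts.n_aff
    ev_t = np.concatenate(ts.spikes) if n_aff else np.empty(0)
    ev_aff = np.concatenate(
        [np.full(s.size, i, dtype=np.int64) for i, s in enumerate(ts.spikes)]
    )
    order = np.argsort(ev_t, kind="stable")
    ev_t = np.ascontiguousarray(ev_t[order])
    ev_aff = np.ascontiguousarray(ev_aff[order])

    syn = network.synapse
    phi_const = phi_iv(syn.E_syn - network.network.V_post_clamp, syn.V_alpha, syn.V_beta)
    fm = network.frequency_map
    post, w_final, snaps = run_kernel(
        ev_t,
        ev_aff,
        n_aff,
        cfg.duration,
        network.dt,
        syn.charge_rate,
        syn.discharge_rate,
        syn.U_T_eff,
        syn.V_ref,
        syn.g_unit,
        syn.pulse_width,
        fm.gate_floor,
        syn.gate_max,
        float(phi_const),
        network.output_stage == "oscillatory",
        fm.f_scale,
        fm.V_f,
        syn.osc_duty,
        network.soma.C_mem,
        network.soma.g_leak,
        network.soma.V_rest,
        network.soma.V_thresh,
        network.soma.V_reset,
        network.soma.t_refr,
        learn,
        learning.t_pre,
        learning.t_post_initial,
        learning.t_post_final,
        learning.t_post_ramp,
        -1.0 if learning.t_post_late is None else learning.t_post_late,
        learning.t_post_ramp_late,
        network.w_init,
        snapshot_dt,
    )
    snap_times = np.arange(snaps.shape[0]) * snapshot_dt
    result = ExperimentResult(
        post_spike_times=post,
        final_weights=w_final,
        weight_trace=snaps,
        t_post_trace=np.array([t_post_at(t, learning) for t in snap_times]),
        snapshot_times=snap_times,
        seed=seed,
    )
    result.initial_rate = float((post < 5.0).sum() / min(5.0, cfg.duration))
    hit_rate, fa, n_occ = score(
        post,
        ts.occurrences,
        cfg.section,
        cfg.duration,
        window=min(SCORE_WINDOW, cfg.duration),
    )
    result.hits = int(round(hit_rate * n_occ / 100.0)) if n_occ else 0
    result.false_alarms = fa
    result.n_occurrences_scored = n_occ
    result.hit_rate = hit_rate
    result.success = success(result)
    return result


def score(
    post_spikes: np.ndarray,
    occurrences: np.ndarray,
    section: float,
    duration: float,
    window: float = SCORE_WINDOW,
    extension: float = 0.0,
) -> tuple[float, int, int]:
    """Hit rate (%) and false-alarm count in the final ``window`` seconds.

    Only occurrences lying entirely inside the window are scored; an
    occurrence counts as hit when ``[start, start + section + extension]``
    contains a soma spike.  Soma spikes in the window that fall outside every
    occurrence interval (truncated ones included) are false alarms.  With no
    scorable occurrence the hit rate is NaN rather than a division by zero.
    """
    if window > duration:
        raise ValueError("scoring window exceeds the simulated duration")
    t_lo = duration - window
    post = np.asarray(post_spikes, dtype=float)
    occ = np.asarray(occurrences, dtype=float)
    post_w = post[(post >= t_lo) & (post <= duration)]
    scorable = occ[(occ >= t_lo) & (occ + section <= duration)]
    hits = 0
    for start in scorable:
        if np.any((post_w >= start) & (post_w <= start + section + extension)):
            hits += 1
    # spikes inside any occurrence interval (even truncated ones) are not FAs
    in_any = np.zeros(post_w.size, dtype=bool)
    for start in occ:
        in_any |= (post_w >= start) & (post_w <= start + section + extension)
    false_alarms = int((~in_any).sum())
    n_occ = int(scorable.size)
    hit_rate = 100.0 * hits / n_occ if n_occ else float("nan")
    return hit_rate, false_alarms, n_occ


def success(result: ExperimentResult) -> bool:
    """Strict criterion: hit rate above 98% and zero false alarms."""
    if result.n_occurrences_scored == 0:
        return False
    return result.hit_rate > HIT_RATE_CRITERION and result.false_alarms == 0


@dataclass
class BatchResult:
    """Success statistics over independent detection runs."""

    results: List[ExperimentResult]
    success_rate: float  # %

    @property
    def n_success(self) -> int:
        return sum(r.success for r in self.results)


def batch(
    task: Optional[TaskConfig] = None,
    network: Optional[DetectionNetwork] = None,
    learning: Optional[LearningParams] = None,
    n_runs: int = 50,
    seed_base: int = 0,
) -> BatchResult:
    """Independent trains and runs per seed; returns the success rate (%)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if task is None:
        task = TaskConfig()
    results = []
    for k in range(n_runs):
        seed = int(seed_base + k) % (2**31 - 1)
        ts = generate(replace(task, seed=seed))
        results.append(run_detection(ts, network, learning, seed=seed))
    rate = 100.0 * sum(r.success for r in results) / n_runs
    return BatchResult(results=results, success_rate=rate)
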