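"""Adaptive rectangular STDP on 4-bit synaptic efficacies.

The learning rule is rectangular spike-timing-dependent plasticity with
single-bit updates on a 4-bit up/down counter per synapse:

* LTP: on a postsynaptic spike at ``t_i``, every synapse whose most recent
  presynaptic spike ``t_j`` satisfies ``t_j <= t_i`` and ``t_i - t_j < t_pre``
  is incremented by one bit (saturating at ``w_max``).
* LTD: on a presynaptic spike at ``t_j``, the synapse is decremented by one
  bit (saturating at ``w_min``) if the most recent postsynaptic spike ``t_i``
  satisfies ``t_j > t_i`` and ``t_j - t_i < t_post``.

Simultaneous pre/post spikes fall in the LTP branch (``t_j <= t_i``).

The adaptive element: ``t_pre`` is fixed while the depression window
``t_post`` follows a non-decreasing schedule of elapsed learning time.  A
small ``t_post`` early in a run lets the output rate settle; ramping it up
makes depression progressively dominant for synapses whose spikes are not
consistently predictive of output spikes, which drives the efficacy
distribution bimodal and the neuron selective.

Only the most recent pre/post spike is remembered per synapse
(nearest-spike semantics), matching the single-capacitor timing memory of
the hardware learning circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "LearningParams",
    "LearningState",
    "t_post_at",
    "on_pre_spike",
    "on_post_spike",
    "EventOrderError",
]

W_MIN = 0
W_MAX = 15


class EventOrderError(ValueError):
    """A spike event was submitted out of temporal order."""


@dataclass(frozen=True)
class LearningParams:
    """Windows and bounds of the adaptive rectangular STDP rule.

    ``t_post_schedule`` maps elapsed learning time (s) to the LTD window (s)
    and must be non-decreasing; the built-in schedule is linear from
    ``t_post_initial`` to ``t_post_final`` over ``t_post_ramp`` seconds, then
    constant.  A constant schedule (``t_post_final == t_post_initial``)
    recovers classical rectangular STDP.
    """

    t_pre: float = 0.004
    t_post_initial: float = 0.0036
    t_post_final: float = 0.008
    t_post_ramp: float = 125.0
    t_post_late: Optional[float] = 0.0135
    t_post_ramp_late: float = 150.0
    w_min: int = W_MIN
    w_max: int = W_MAX
    t_post_schedule: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if not self.t_pre > 0:
            raise ValueError("t_pre must be positive")
        if self.t_post_schedule is None:
            if self.t_post_final < self.t_post_initial:
                raise ValueError("t_post schedule must be non-decreasing")
            if not self.t_post_initial > 0 or not self.t_post_ramp >= 0:
                raise ValueError("t_post_initial > 0 and t_post_ramp >= 0 required")
            if self.t_post_late is not None:
                if self.t_post_late < self.t_post_final:
                    raise ValueError("t_post schedule must be non-decreasing")
                if self.t_post_ramp_late <= self.t_post_ramp:
                    raise ValueError("late ramp must end after the first ramp")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be below w_max")


def t_post_at(t_elapsed: float, params: LearningParams) -> float:
    """LTD window (s) in effect after ``t_elapsed`` seconds of learning."""
    if t_elapsed < 0:
        raise ValueError("t_elapsed must be non-negative")
    if params.t_post_schedule is not None:
        return params.t_post_schedule(t_elapsed)
    if params.t_post_ramp > 0 and t_elapsed < params.t_post_ramp:
        frac = t_elapsed / params.t_post_ramp
        return params.t_post_initial + frac * (params.t_post_final - params.t_post_initial)
    if params.t_post_late is None:
        return params.t_post_final
    if t_elapsed >= params.t_post_ramp_late:
        return params.t_post_late
    frac = (t_elapsed - params.t_post_ramp) / (params.t_post_ramp_late - params.t_post_ramp)
    return params.t_post_final + frac * (params.t_post_late - params.t_post_final)


@dataclass
class LearningState:
    """Per-synapse spike-timing memory and efficacies for one neuron.

    ``last_pre[i]`` / ``last_post`` hold the most recent spike times (NaN when
    none has occurred); ``w`` holds the integer efficacies.
    """

    n_synapses: int = 1
    w_init: int = 8
    last_pre: np.ndarray = field(init=False)
    last_post: float = field(init=False, default=float("nan"))
    w: np.ndarray = field(init=False)
    _t_latest: float = field(init=False, default=float("-inf"))

    def __post_init__(self) -> None:
        if not W_MIN <= self.w_init <= W_MAX:
            raise ValueError("initial efficacy out of range")
        self.last_pre = np.full(self.n_synapses, np.nan)
        self.w = np.full(self.n_synapses, self.w_init, dtype=np.int64)

    def _check_order(self, t: float) -> None:
        if t < self._t_latest:
            raise EventOrderError(
                f"event at t={t} precedes already-processed event at t={self._t_latest}"
            )
        self._t_latest = t


def on_pre_spike(
    state: LearningState,
    synapse: int,
    t_j: float,
    params: LearningParams,
    t_elapsed: Optional[float] = None,
) -> LearningState:
    """Process a presynaptic spike on one synapse (LTD branch).

    Decrements the efficacy by one bit if the most recent postsynaptic spike
    occurred strictly before ``t_j`` and within the current LTD window; the
    presynaptic memory is then updated.  ``t_elapsed`` defaults to ``t_j``
    (learning time measured from the start of the run).
    """
    state._check_order(t_j)
    window = t_post_at(t_j if t_elapsed is None else t_elapsed, params)
    t_i = state.last_post
    if (
        not np.isnan(t_i)
        and t_j > t_i
        and t_j - t_i < window
        and state.w[synapse] > params.w_min
    ):
        state.w[synapse] -= 1
    state.last_pre[synapse] = t_j
    return state


def on_post_spike(state: LearningState, t_i: float, params: LearningParams) -> LearningState:
    """Process a postsynaptic spike (LTP branch, applied to every synapse).

    Each synapse whose remembered presynaptic spike lies within ``t_pre``
    before (or exactly at) ``t_i`` gains one bit, at most once per
    postsynaptic spike; the postsynaptic memory is then updated.
    """
    state._check_order(t_i)
    dt = t_i - state.last_pre
    eligible = (dt >= 0.0) & (dt < params.t_pre) & (state.w < params.w_max)
    state.w[eligible] += 1
    state.last_post = t_i
    return state
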