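"""Synthetic stimulus for the spike-pattern detection task.

A population of independent afferents fires as inhomogeneous Poisson
processes whose instantaneous rates follow a slew-limited random walk between
0 and 90 Hz (the rate can change by at most 90 Hz per 50 ms).  Every afferent
is guaranteed at least one spike per disjoint 50 ms window, fixing 20 Hz as
its minimum windowed rate.  A randomly chosen 50 ms segment of the generated
train — the target pattern — is then copied over a randomly chosen set of
50 ms sections (a quarter or a tenth of them, never two adjacent), so that
the pattern is hidden in the trains and distinguishable only by the precise
spike times, not by any rate signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

__all__ = [
    "TaskConfig",
    "SpikeTrainSet",
    "gen_rate_profiles",
    "gen_poisson_spikes",
    "enforce_min_activity",
    "embed_pattern",
    "population_rate_stats",
    "generate",
]

RATE_DT = 1e-3  # resolution of the rate random walk (s)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the stimulus generator.

    Defaults are the task's study conditions: 256 afferents, 225 s trains,
    50 ms sections, rates in [0, 90] Hz with full-range slew taking at least
    50 ms, at least one spike per afferent per 50 ms, and a quarter of the
    sections replaced by the pattern.
    """

    n_aff: int = 256
    duration: float = 225.0
    section: float = 0.05
    repeat_fraction: float = 0.25
    rate_min: float = 0.0
    rate_max: float = 90.0
    slew_max: float = 1800.0
    min_activity_window: float = 0.05
    seed: int = 0
    count_source_section: bool = True

    def __post_init__(self) -> None:
        if self.n_aff < 1:
            raise ValueError("n_aff must be >= 1")
        n_sections = self.duration / self.section
        if abs(n_sections - round(n_sections)) > 1e-9:
            raise ValueError("duration must be an integer multiple of section")
        if not 0.0 <= self.repeat_fraction <= 0.5:
            raise ValueError(
                "repeat_fraction must lie in [0, 0.5] (non-adjacent placement "
                "is infeasible beyond one half)"
            )
        if not self.rate_max > self.rate_min >= 0:
            raise ValueError("need rate_max > rate_min >= 0")
        if not self.slew_max > 0:
            raise ValueError("slew_max must be positive")

    @property
    def n_sections(self) -> int:
        return int(round(self.duration / self.section))

    @property
    def n_occurrences(self) -> int:
        return int(round(self.repeat_fraction * self.n_sections))


@dataclass
class SpikeTrainSet:
    """Per-afferent spike times plus the embedded-pattern record.

    ``spikes[i]`` is the sorted spike-time array of afferent ``i`` (s);
    ``pattern_spikes[i]`` holds the pattern's offsets in [0, section) for
    afferent ``i``; ``occurrences`` holds the sorted start times of the
    pattern instances (multiples of the section length, never adjacent).
    """

    spikes: List[np.ndarray]
    config: TaskConfig
    pattern_spikes: Optional[List[np.ndarray]] = None
    occurrences: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_aff(self) -> int:
        return len(self.spikes)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        cfg = self.config
        for i, s in enumerate(self.spikes):
            if s.size and (np.any(np.diff(s) <= 0)):
                raise ValueError(f"afferent {i}: spike times not strictly increasing")
            if s.size and (s[0] < 0 or s[-1] > cfg.duration):
                raise ValueError(f"afferent {i}: spike outside [0, duration]")
        occ = np.asarray(self.occurrences, dtype=float)
        if occ.size:
            ratios = occ / cfg.section
            if np.any(np.abs(ratios - np.round(ratios)) > 1e-9):
                raise ValueError("occurrence starts must be multiples of the section")
            idx = np.round(ratios).astype(int)
            if np.any(np.diff(np.sort(idx)) < 2):
                raise ValueError("adjacent pattern occurrences are not allowed")


def gen_rate_profiles(cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Slew-limited rate random walk for each afferent.

    Piecewise-linear at 1 ms resolution; increments are uniform in
    ``[-slew_max*dt, +slew_max*dt]`` and the walk is reflected at the rate
    bounds, whose stationary distribution is uniform on [rate_min, rate_max].
    Returns an array of shape ``(n_aff, n_samples)`` in Hz (float32).
    """
    n_samples = int(round(cfg.duration / RATE_DT)) + 1
    lo, hi = cfg.rate_min, cfg.rate_max
    step = np.float32(cfg.slew_max * RATE_DT)
    span = np.float32(hi - lo)
    walk = rng.random((cfg.n_aff, n_samples), dtype=np.float32)
    walk *= 2.0 * step
    walk -= step
    walk[:, 0] = rng.random(cfg.n_aff, dtype=np.float32) * span
    np.cumsum(walk, axis=1, out=walk)
    # reflect into [lo, hi]: fold the unbounded walk with period 2*(hi-lo)
    np.remainder(walk, 2.0 * span, out=walk)
    walk -= span
    np.abs(walk, out=walk)
    return (span - walk) + np.float32(lo)


def gen_poisson_spikes(
    rates: np.ndarray, cfg: TaskConfig, rng: np.random.Generator
) -> List[np.ndarray]:
    """Sample inhomogeneous Poisson trains by thinning.

    Homogeneous candidates at the rate ceiling are kept with probability
    ``r(t)/rate_max``, with ``r(t)`` linearly interpolated between the 1 ms
    samples of the rate profile.  Afferents are independent.
    """
    rates = np.asarray(rates)
    trains: List[np.ndarray] = []
    t_grid_scale = 1.0 / RATE_DT
    for i in range(rates.shape[0]):
        n_cand = rng.poisson(cfg.rate_max * cfg.duration)
        cand = np.sort(rng.uniform(0.0, cfg.duration, size=n_cand))
        pos = cand * t_grid_scale
        idx = np.minimum(pos.astype(np.int64), rates.shape[1] - 2)
        frac = pos - idx
        r = rates[i, idx] * (1.0 - frac) + rates[i, idx + 1] * frac
        keep = rng.uniform(0.0, cfg.rate_max, size=n_cand) < r
        trains.append(cand[keep])
    return trains


def enforce_min_activity(
    trains: List[np.ndarray], cfg: TaskConfig, rng: np.random.Generator
) -> List[np.ndarray]:
    """Guarantee at least one spike per disjoint activity window per afferent.

    Every empty 50 ms window receives exactly one spike at a uniform random
    position inside it; already-active windows are untouched.
    """
    win = cfg.min_activity_window
    n_win = int(round(cfg.duration / win))
    out: List[np.ndarray] = []
    for s in trains:
        occupied = np.zeros(n_win, dtype=bool)
        if s.size:
            occupied[np.minimum((s / win).astype(np.int64), n_win - 1)] = True
        missing = np.nonzero(~occupied)[0]
        if missing.size == 0:
            out.append(s)
            continue
        extra = (missing + rng.uniform(0.0, 1.0, size=missing.size)) * win
        out.append(np.sort(np.concatenate([s, extra])))
    return out


def _sample_nonadjacent(
    n_sections: int, k: int, forced: Optional[int], rng: np.random.Generator
) -> np.ndarray:
    """Uniformly shuffled greedy draw of k section indices, no two adjacent."""
    if k > (n_sections + 1) // 2:
        raise ValueError("cannot place that many non-adjacent sections")
    chosen: List[int] = []
    taken = np.zeros(n_sections + 2, dtype=bool)  # padded adjacency mask

    def free(ix: int) -> bool:
        return not (taken[ix] or taken[ix + 1] or taken[ix + 2])

    def take(ix: int) -> None:
        chosen.append(ix)
        taken[ix + 1] = True

    if forced is not None:
        take(forced)
    order = rng.permutation(n_sections)
    for ix in order:
        if len(chosen) >= k:
            break
        if free(int(ix)):
            take(int(ix))
    if len(chosen) < k:
        # extremely dense request: restart with fresh permutations
        for _ in range(1000):
            chosen.clear()
            taken[:] = False
            if forced is not None:
                take(forced)
            for ix in rng.permutation(n_sections):
                if len(chosen) >= k:
                    break
                if free(int(ix)):
                    take(int(ix))
            if len(chosen) >= k:
                break
        else:
            raise RuntimeError("failed to place non-adjacent pattern sections")
    return np.sort(np.asarray(chosen, dtype=np.int64))


def embed_pattern(
    trains: List[np.ndarray], cfg: TaskConfig, rng: np.random.Generator
) -> SpikeTrainSet:
    """Copy one random section over a non-adjacent random set of sections.

    The copied segment's own section already equals the pattern, is counted
    as an occurrence (when ``count_source_section``), and anchors the
    non-adjacency constraint.  With ``repeat_fraction == 0`` the trains are
    returned untouched with an empty occurrence list.
    """
    n_sections = cfg.n_sections
    k = cfg.n_occurrences
    if k == 0:
        return SpikeTrainSet(spikes=[np.array(s) for s in trains], config=cfg)
    source = int(rng.integers(n_sections))
    forced = source if cfg.count_source_section else None
    idx = _sample_nonadjacent(n_sections, k, forced, rng)
    sec = cfg.section
    t0 = source * sec
    pattern = [s[(s >= t0) & (s < t0 + sec)] - t0 for s in trains]
    occurrences = idx * sec
    out: List[np.ndarray] = []
    starts = occurrences
    for s, pat in zip(trains, pattern):
        sec_idx = np.minimum((s / sec).astype(np.int64), n_sections - 1)
        keep = ~np.isin(sec_idx, idx)
        pasted = (starts[:, None] + pat[None, :]).ravel()
        out.append(np.sort(np.concatenate([s[keep], pasted])))
    ts = SpikeTrainSet(
        spikes=out, config=cfg, pattern_spikes=pattern, occurrences=occurrences.astype(float)
    )
    return ts


def population_rate_stats(
    ts: SpikeTrainSet, bin_width: float = 0.01
) -> tuple[Optional[float], float]:
    """Mean per-afferent rate (Hz) in fixed bins, inside vs outside patterns.

    A bin counts as *inside* when it lies entirely within a pattern
    occurrence.  With no occurrences the inside rate is undefined and
    returned as ``None`` (never silently zero).
    """
    cfg = ts.config
    n_bins = int(round(cfg.duration / bin_width))
    counts = np.zeros(n_bins)
    for s in ts.spikes:
        if s.size:
            counts += np.bincount(
                np.minimum((s / bin_width).astype(np.int64), n_bins - 1), minlength=n_bins
            )
    rate = counts / (ts.n_aff * bin_width)
    inside = np.zeros(n_bins, dtype=bool)
    occ = np.asarray(ts.occurrences, dtype=float)
    edges = np.arange(n_bins) * bin_width
    for start in occ:
        inside |= (edges >= start - 1e-12) & (edges + bin_width <= start + cfg.section + 1e-12)
    rate_outside = float(rate[~inside].mean())
    rate_inside = float(rate[inside].mean()) if inside.any() else None
    return rate_inside, rate_outside


def generate(cfg: TaskConfig, rng: Optional[np.random.Generator] = None) -> SpikeTrainSet:
    """Full pipeline: rate walk -> Poisson thinning -> activity floor -> pattern."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rates = gen_rate_profiles(cfg, rng)
    trains = gen_poisson_spikes(rates, cfg, rng)
    trains = enforce_min_activity(trains, cfg, rng)
    return embed_pattern(trains, cfg, rng)
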