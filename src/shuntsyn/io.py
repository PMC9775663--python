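"""Plain-text spike-train files, YAML run configuration, provenance hashes.

Spike events live in a tab-separated text file with a single header line::

    # shuntsyn-spikes v1 n_aff=<N> duration=<T>
    <afferent_id>\t<time_seconds>

sorted by time, afferent ids in ``[0, n_aff)``, times quantized to 1 µs on
disk (round trips are lossless at that resolution).  Pattern occurrence
start times use a one-number-per-line text file with the same header prefix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Dict, List

import numpy as np
import yaml

from .neuron import DendriteParams, NetworkConfig, SomaParams
from .oscillator import GateFrequencyMap, InverterParams, OscillatorDrive
from .plasticity import LearningParams
from .synapse import SynapseConfig
from .taskgen import SpikeTrainSet, TaskConfig

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "read_occurrences",
    "write_occurrences",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
]

_HEADER_PREFIX = "# shuntsyn-spikes v1"
_TIME_QUANTUM = 1e-6


class SpikeFileError(ValueError):
    """Malformed spike-train file."""


def write_spike_trains(ts: SpikeTrainSet, path: str | Path) -> None:
    """Write one event per line, sorted by time."""
    path = Path(path)
    n_aff = ts.n_aff
    ev_t = np.concatenate(ts.spikes) if n_aff else np.empty(0)
    ev_aff = np.concatenate(
        [np.full(s.size, i, dtype=np.int64) for i, s in enumerate(ts.spikes)]
    )
    order = np.argsort(ev_t, kind="stable")
    with path.open("w") as fh:
        fh.write(f"{_HEADER_PREFIX} n_aff={n_aff} duration={ts.config.duration:g}\n")
        for k in order:
            fh.write(f"{ev_aff[k]}\t{ev_t[k]:.6f}\n")


def read_spike_trains(path: str | Path) -> SpikeTrainSet:
    """Read a v1 spike file; returns a train set without occurrence record."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_HEADER_PREFIX):
            raise SpikeFileError(f"{path}: missing '{_HEADER_PREFIX}' header")
        fields = dict(tok.split("=", 1) for tok in header[len(_HEADER_PREFIX):].split())
        try:
            n_aff = int(fields["n_aff"])
            duration = float(fields["duration"])
        except (KeyError, ValueError) as exc:
            raise SpikeFileError(f"{path}: malformed header '{header}'") from exc
        spikes: List[List[float]] = [[] for _ in range(n_aff)]
        last_t = -np.inf
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SpikeFileError(f"{path}:{lineno}: expected 'id<TAB>time'")
            try:
                aff = int(parts[0])
                t = float(parts[1])
            except ValueError as exc:
                raise SpikeFileError(f"{path}:{lineno}: unparsable event") from exc
            if not 0 <= aff < n_aff:
                raise SpikeFileError(
                    f"{path}:{lineno}: afferent id {aff} outside [0, {n_aff})"
                )
            if t < last_t:
                raise SpikeFileError(f"{path}:{lineno}: events not sorted by time")
            last_t = t
            spikes[aff].append(round(t / _TIME_QUANTUM) * _TIME_QUANTUM)
    cfg = TaskConfig(n_aff=n_aff, duration=duration, repeat_fraction=0.0)
    arrays = []
    for s in spikes:
        a = np.asarray(s, dtype=float)
        arrays.append(np.unique(a))  # drop exact quantization ties
    return SpikeTrainSet(spikes=arrays, config=cfg)


def write_occurrences(occurrences: np.ndarray, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"{_HEADER_PREFIX} occurrences\n")
        for t in np.asarray(occurrences, dtype=float):
            fh.write(f"{t:.6f}\n")


def read_occurrences(path: str | Path) -> np.ndarray:
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith(_HEADER_PREFIX):
            raise SpikeFileError(f"{path}: missing '{_HEADER_PREFIX}' header")
        vals = [float(line) for line in fh if line.strip()]
    return np.asarray(vals, dtype=float)


# --------------------------------------------------------------------------
# run configuration

_BLOCKS = {
    "oscillator": InverterParams,
    "oscillator_drive": OscillatorDrive,
    "frequency_map": GateFrequencyMap,
    "synapse": SynapseConfig,
    "soma": SomaParams,
    "dendrite": DendriteParams,
    "network": NetworkConfig,
    "learning": LearningParams,
    "task": TaskConfig,
}

_TOP_LEVEL = {"seed", "out_dir", "log_level", "output_stage", "dt"}


@dataclasses.dataclass
class RunConfig:
    """Validated, fully-materialized configuration of one run."""

    oscillator: InverterParams = dataclasses.field(default_factory=InverterParams)
    oscillator_drive: OscillatorDrive = dataclasses.field(default_factory=OscillatorDrive)
    frequency_map: GateFrequencyMap = dataclasses.field(default_factory=GateFrequencyMap)
    synapse: SynapseConfig = dataclasses.field(default_factory=SynapseConfig)
    soma: SomaParams = dataclasses.field(default_factory=SomaParams)
    dendrite: DendriteParams = dataclasses.field(default_factory=DendriteParams)
    network: NetworkConfig = dataclasses.field(default_factory=NetworkConfig)
    learning: LearningParams = dataclasses.field(default_factory=LearningParams)
    task: TaskConfig = dataclasses.field(default_factory=TaskConfig)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "info"
    output_stage: str = "smooth"
    dt: float = 1e-4


def _build_block(cls, block_name: str, data: Dict[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block '{block_name}' "
            f"(valid: {sorted(valid)})"
        )
    defaults = cls()
    kwargs = {}
    for key, value in data.items():
        current = getattr(defaults, key, None)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            value = _build_block(type(current), f"{block_name}.{key}", value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults are filled in."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_BLOCKS) - _TOP_LEVEL
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs: Dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        block = raw.get(name, {})
        if not isinstance(block, dict):
            raise ValueError(f"{path}: block '{name}' must be a mapping")
        kwargs[name] = _build_block(cls, name, block)
    for key in _TOP_LEVEL:
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _as_dict(cfg: RunConfig) -> Dict[str, Any]:
    out: Dict[str, Any] = {}
    for name in _BLOCKS:
        block = getattr(cfg, name)
        out[name] = {
            f.name: getattr(block, f.name)
            for f in dataclasses.fields(block)
            if f.init and not dataclasses.is_dataclass(getattr(block, f.name))
            and not callable(getattr(block, f.name))
        }
    for key in sorted(_TOP_LEVEL):
        out[key] = getattr(cfg, key)
    return out


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective (defaults-materialized) configuration."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(_as_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short provenance hash of the effective configuration."""
    blob = json.dumps(_as_dict(cfg), sort_keys=True, default=repr).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
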