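"""On-disk session format and run configuration.

A session is a set of three tab-separated tables in one directory:

* ``trials.tsv``  — session_id, trial_index, task, d_small, d_large,
  large_on_right, instructed_target, latent_bias, choice_side,
  choice_reward, valid, t_go
* ``spikes.tsv``  — neuron_id, trial_index, spike_time_s (seconds
  relative to cue onset; sorted within neuron x trial)
* ``neurons.tsv`` — neuron_id, region, hemisphere, bias_type,
  preferred_label

Plain delimited text keeps the data diff-able and portable; adapters to
standard neurophysiology containers (NWB etc.) would slot in here.
All times are seconds with cue onset at 0; analysis windows are
half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import NeuronSession

__all__ = ["SessionFileSet", "RunConfig", "read_session", "write_session",
           "load_config"]

TRIAL_COLUMNS = ["session_id", "trial_index", "task", "d_small", "d_large",
                 "large_on_right", "instructed_target", "latent_bias",
                 "choice_side", "choice_reward", "valid", "t_go"]
SPIKE_COLUMNS = ["neuron_id", "trial_index", "spike_time_s"]
NEURON_COLUMNS = ["neuron_id", "region", "hemisphere", "bias_type",
                  "preferred_label"]


@dataclass
class SessionFileSet:
    trials: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame

    def neuron_sessions(self):
        """Reassemble per-neuron spike-train containers."""
        out = []
        for row in self.neurons.itertuples(index=False):
            sub = self.spikes[self.spikes.neuron_id == row.neuron_id]
            spk = {int(t): np.sort(g.spike_time_s.to_numpy())
                   for t, g in sub.groupby("trial_index")}
            for t in self.trials.trial_index:
                spk.setdefault(int(t), np.empty(0))
            out.append(NeuronSession(row.neuron_id, row.region,
                                     row.hemisphere, row.bias_type,
                                     row.preferred_label, spk))
        return out


def _check_columns(df, cols, name):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table missing columns: {missing}")


def validate_session(fs: SessionFileSet):
    _check_columns(fs.trials, TRIAL_COLUMNS, "trials")
    _check_columns(fs.spikes, SPIKE_COLUMNS, "spikes")
    _check_columns(fs.neurons, NEURON_COLUMNS, "neurons")
    known = set(fs.trials.trial_index)
    orphans = fs.spikes[~fs.spikes.trial_index.isin(known)]
    if len(orphans):
        raise ValueError(
            "spikes reference nonexistent trials, first offending rows:\n"
            f"{orphans.head()}")
    unknown_neurons = fs.spikes[~fs.spikes.neuron_id.isin(
        set(fs.neurons.neuron_id))]
    if len(unknown_neurons):
        raise ValueError(
            "spikes reference neurons absent from the neurons table:\n"
            f"{unknown_neurons.head()}")
    for (nid, t), g in fs.spikes.groupby(["neuron_id", "trial_index"]):
        ts = g.spike_time_s.to_numpy()
        if np.any(np.diff(ts) < 0):
            raise ValueError(
                f"unsorted spike times for neuron {nid} trial {t}")
    return fs


def write_session(fs: SessionFileSet, path) -> Path:
    """Write the three tables (validated first) under ``path``."""
    validate_session(fs)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    fs.trials.to_csv(path / "trials.tsv", sep="\t", index=False,
                     float_format="%.17g")
    fs.spikes.to_csv(path / "spikes.tsv", sep="\t", index=False,
                     float_format="%.17g")
    fs.neurons.to_csv(path / "neurons.tsv", sep="\t", index=False)
    return path


def read_session(path) -> SessionFileSet:
    """Read and validate a session directory written by `write_session`."""
    path = Path(path)
    for fname in ("trials.tsv", "spikes.tsv", "neurons.tsv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"missing {fname} under {path}")
    trials = pd.read_csv(path / "trials.tsv", sep="\t",
                         dtype={"session_id": str})
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t",
                         dtype={"neuron_id": str})
    if len(spikes) == 0:
        spikes = pd.DataFrame(columns=SPIKE_COLUMNS).astype(
            {"trial_index": int, "spike_time_s": float})
    neurons = pd.read_csv(path / "neurons.tsv", sep="\t",
                          dtype={"neuron_id": str})
    trials["large_on_right"] = trials.large_on_right.astype(bool)
    trials["valid"] = trials.valid.astype(bool)
    return validate_session(SessionFileSet(trials, spikes, neurons))


@dataclass
class RunConfig:
    """Analysis constants; the defaults are the full-procedure values."""

    pre_cue_window: tuple = (-1.5, 0.0)
    cue_window: tuple = (0.0, 1.0)
    go_duration: float = 0.5
    burst_threshold: float = 0.010
    sdf_kernel_sd: float = 0.100
    min_rate: float = 0.5
    min_side_fraction: float = 0.25
    undet_band: tuple = (0.35, 0.65)
    wdet_band: tuple = (0.25, 0.75)
    n_shuffles: int = 10_000
    call_alpha: float = 0.05
    fn_reps: int = 1_000
    seed: int = 0
    generator: dict = field(default_factory=dict)
    circuit: dict = field(default_factory=dict)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a flat key-value (YAML) config file, applying overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("pre_cue_window", "cue_window", "undet_band", "wdet_band"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(cfg).items()}, fh)
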