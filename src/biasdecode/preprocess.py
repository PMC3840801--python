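"""Spike-train and trial-table preprocessing.

Conventions: time 0 = cue onset; all analysis windows are half-open
[start, end).  The pre-cue window [-1.5, 0) spans the last 0.5 s of the
inter-trial interval plus the 1 s fore period; the cue window is [0, 1);
the go window is the first 0.5 s after the go signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisWindows",
    "TrialTypePartition",
    "consolidate_bursts",
    "count_spikes",
    "spike_density",
    "partition_trials",
    "inclusion_filter",
    "pre_cue_counts",
    "window_counts",
]

TRIAL_TYPES = ("UNDET", "WDET", "SDET", "NC")


@dataclass(frozen=True)
class AnalysisWindows:
    pre_cue: tuple = (-1.5, 0.0)
    cue: tuple = (0.0, 1.0)
    go_duration: float = 0.5

    def go(self, t_go: float) -> tuple:
        return (t_go, t_go + self.go_duration)


def consolidate_bursts(spike_times, threshold: float = 0.010) -> np.ndarray:
    """Merge bursts into single spikes.

    Any run of spikes whose successive inter-spike intervals are all below
    ``threshold`` (default 10 ms) collapses to the run's first spike.
    Idempotent: after one pass every surviving ISI is >= threshold.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return t.copy()
    isi = np.diff(t)
    if np.any(isi < 0):
        raise ValueError("spike times must be sorted ascending")
    # a run = maximal stretch of successive ISIs below threshold; keep the
    # first spike of each run
    keep = np.concatenate([[True], isi >= threshold])
    return t[keep]


def count_spikes(spike_times, window) -> int:
    """Number of spikes in the half-open window [start, end)."""
    start, end = window
    if end < start:
        raise ValueError("window end before start")
    t = np.asarray(spike_times, dtype=float)
    return int(np.count_nonzero((t >= start) & (t < end)))


def spike_density(spike_times, sample_grid, kernel_sd: float = 0.100
                  ) -> np.ndarray:
    """Spike density function: sum of unit-area Gaussians (SD ``kernel_sd``,
    default 100 ms) centered on each spike, sampled at ``sample_grid``.
    Integrates to the spike count over the real line.  For plotting only.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    grid = np.asarray(sample_grid, dtype=float)
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return np.zeros_like(grid)
    z = (grid[:, None] - t[None, :]) / kernel_sd
    return np.exp(-0.5 * z * z).sum(axis=1) / (kernel_sd * np.sqrt(2 * np.pi))


@dataclass
class TrialTypePartition:
    """Per-delay-pair small-reward choice ratios and trial-type labels."""

    pair_ratio: dict            # (d_small, d_large) -> r, fraction small chosen
    pair_label: dict            # (d_small, d_large) -> UNDET/WDET/SDET
    trial_label: pd.Series      # trial_index -> label (NC for control)

    def trials_of_type(self, trial_type: str) -> np.ndarray:
        return self.trial_label.index[self.trial_label == trial_type].to_numpy()

    @property
    def has_undet(self) -> bool:
        return any(v == "UNDET" for v in self.pair_label.values())


def _label_from_ratio(r: float) -> str:
    # Boundary values go to the less-determined neighbor, so each valid
    # choice trial receives exactly one label.
    if 0.35 <= r <= 0.65:
        return "UNDET"
    if 0.25 <= r < 0.35 or 0.65 < r <= 0.75:
        return "WDET"
    return "SDET"


def partition_trials(trials: pd.DataFrame) -> TrialTypePartition:
    """Partition a session's trials into UNDET / WDET / SDET / NC.

    For each delay pair, r = fraction of valid choice trials on which the
    small reward was chosen; pairs with r in [0.35, 0.65] are undetermined
    (UNDET), in [0.25, 0.35) or (0.65, 0.75] weakly determined (WDET),
    otherwise strongly determined (SDET).  Control trials are NC.
    """
    choice = trials[(trials.task == "choice") & trials.valid]
    pair_ratio, pair_label = {}, {}
    labels = pd.Series("NC", index=trials.trial_index.to_numpy(), dtype=object)
    labels[trials.set_index("trial_index").valid.eq(False)] = "invalid"
    for (ds, dl), grp in choice.groupby(["d_small", "d_large"]):
        if len(grp) == 0:
            continue
        r = float((grp.choice_reward == "small").mean())
        pair_ratio[(ds, dl)] = r
        pair_label[(ds, dl)] = _label_from_ratio(r)
        labels[grp.trial_index.to_numpy()] = pair_label[(ds, dl)]
    all_pairs = set(map(tuple, trials.loc[trials.task == "choice",
                                          ["d_small", "d_large"]].values))
    missing = all_pairs - set(pair_ratio)
    if missing:
        warnings.warn(f"delay pairs with zero valid trials excluded: {missing}")
    return TrialTypePartition(pair_ratio, pair_label, labels)


def pre_cue_counts(neuron, trials: pd.DataFrame,
                   windows: AnalysisWindows = AnalysisWindows(),
                   burst_threshold: float | None = 0.010) -> pd.Series:
    """Per-trial pre-cue spike counts (after burst consolidation)."""
    return window_counts(neuron, trials, "pre_cue", windows, burst_threshold)


def window_counts(neuron, trials: pd.DataFrame, window: str,
                  windows: AnalysisWindows = AnalysisWindows(),
                  burst_threshold: float | None = 0.010) -> pd.Series:
    """Per-trial spike counts for one analysis window.

    ``window`` is one of ``pre_cue``, ``cue``, ``go``; the go window starts
    at each trial's recorded go-signal time.
    """
    counts = {}
    t_go = trials.set_index("trial_index").t_go
    for idx, spk in neuron.spikes.items():
        if burst_threshold is not None:
            spk = consolidate_bursts(spk, burst_threshold)
        if window == "go":
            win = windows.go(float(t_go.loc[idx]))
        else:
            win = getattr(windows, window)
        counts[idx] = count_spikes(spk, win)
    return pd.Series(counts, dtype=int).sort_index()


def inclusion_filter(neuron, trials: pd.DataFrame,
                     analysis: str = "spatial",
                     partition: TrialTypePartition | None = None,
                     windows: AnalysisWindows = AnalysisWindows(),
                     min_rate: float = 0.5,
                     min_side_fraction: float = 0.25):
    """Decide whether a neuron enters the bias analysis.

    Criteria: (1) the session contains at least one undetermined delay
    pair; (2) mean pre-cue firing rate >= ``min_rate`` spikes/s; (3) for
    the spatial analysis only, each side was chosen on at least
    ``min_side_fraction`` of valid choice trials.  Trials flagged invalid
    (e.g. following a post-cue fixation break) are dropped beforehand.

    Returns ``(included, reasons)`` with ``reasons`` the list of failed
    criteria (empty when included).
    """
    if analysis not in ("spatial", "reward"):
        raise ValueError(f"unknown analysis {analysis!r}")
    if partition is None:
        partition = partition_trials(trials)
    reasons = []
    if not partition.has_undet:
        reasons.append("no_undet_pair")
    counts = pre_cue_counts(neuron, trials, windows)
    valid_idx = trials.loc[trials.valid, "trial_index"]
    counts = counts.loc[counts.index.intersection(valid_idx)]
    pre_dur = windows.pre_cue[1] - windows.pre_cue[0]
    if len(counts) == 0 or counts.mean() / pre_dur < min_rate:
        reasons.append("rate")
    if analysis == "spatial":
        choice = trials[(trials.task == "choice") & trials.valid]
        if len(choice):
            frac_right = (choice.choice_side == "R").mean()
            if min(frac_right, 1 - frac_right) < min_side_fraction:
                reasons.append("side_preference")
    return (len(reasons) == 0), reasons
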