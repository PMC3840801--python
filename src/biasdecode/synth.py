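"""Synthetic intertemporal-choice sessions and Poisson spike trains.

The generator emulates the statistical structure of a delayed-reward
choice task in monkeys: on each trial a small reward (default 0.26 ml)
at delay 0 or 2 s competes with a large reward (default 0.4 ml) at delay
0-8 s, targets counterbalanced left/right, with interleaved forced-choice
("control") blocks in which the fixation color instructs the target.

Choice behavior follows a softmax on the difference of temporally
discounted values, nudged by a per-trial latent bias ``b_t`` drawn from
N(0, sigma_b).  The same latent bias modulates the pre-cue firing rate of
simulated bias neurons, so that a decoder reading pre-cue spike counts
gains predictive power exactly where the discounted values are similar
(undetermined trials) and loses it where the stimulus dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorConfig",
    "NeuronSpec",
    "NeuronSession",
    "discounted_value",
    "generate_session",
    "generate_spikes",
    "generate_cohort",
    "dlpfc_config",
    "striatum_config",
    "DLPFC_DELAY_PAIRS",
    "STRIATUM_DELAY_PAIRS",
]

#: legal delays (s) for the small- and large-reward targets
SMALL_DELAYS = (0.0, 2.0)
LARGE_DELAYS = (0.0, 2.0, 4.0, 6.0, 8.0)

#: all 10 delay pairs (striatum sessions); prefrontal sessions drop (2, 0)
STRIATUM_DELAY_PAIRS = tuple(
    (ds, dl) for ds in SMALL_DELAYS for dl in LARGE_DELAYS
)
DLPFC_DELAY_PAIRS = tuple(
    p for p in STRIATUM_DELAY_PAIRS if p != (2.0, 0.0)
)


def discounted_value(magnitude, delay, k, form="hyperbolic"):
    """Temporally discounted value of a reward.

    Parameters
    ----------
    magnitude : float
        Reward magnitude (ml); must be >= 0.
    delay : float
        Delay to delivery (s); must be >= 0.
    k : float
        Discount rate (1/s); must be >= 0.
    form : {"hyperbolic", "exponential"}
        ``hyperbolic`` returns ``magnitude / (1 + k*delay)``,
        ``exponential`` returns ``magnitude * exp(-k*delay)``.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    delay = np.asarray(delay, dtype=float)
    if np.any(magnitude < 0):
        raise ValueError("reward magnitude must be non-negative")
    if np.any(delay < 0):
        raise ValueError("delay must be non-negative")
    if k < 0:
        raise ValueError("discount rate k must be non-negative")
    if form == "hyperbolic":
        out = magnitude / (1.0 + k * delay)
    elif form == "exponential":
        out = magnitude * np.exp(-k * delay)
    else:
        raise ValueError(f"unknown discounting form: {form!r}")
    return out if out.ndim else float(out)


@dataclass
class GeneratorConfig:
    """Parameters of the behavioral session generator.

    ``n_reps_per_pair`` trials of every delay pair per choice block, target
    sides counterbalanced (must be even).  With the 9 prefrontal pairs and
    2 repeats a block holds 18 trials; with all 10 pairs and 4 repeats, 40.
    """

    delay_pairs: tuple = DLPFC_DELAY_PAIRS
    n_reps_per_pair: int = 2
    n_blocks: int = 10
    include_control_blocks: bool = True
    reward_small: float = 0.26
    reward_large: float = 0.4
    discount_rate: float = 0.2          # k, 1/s
    discount_form: str = "hyperbolic"
    inverse_temperature: float = 20.0   # gamma, softmax slope on DV difference
    bias_sd: float = 1.0                # sigma_b of the latent per-trial bias
    bias_choice_weight: float = 0.5     # w, bias -> choice coupling
    bias_mode: str = "spatial"          # {"spatial", "reward"}
    control_error_rate: float = 0.0     # instructed-trial disobedience rate
    t_go: float = 1.0                   # go signal = cue onset + 1 s cue period
    session_id: str = "synthetic"
    seed: int | None = None

    @property
    def n_trials_per_block(self) -> int:
        return len(self.delay_pairs) * self.n_reps_per_pair

    def validate(self):
        if not self.delay_pairs:
            raise ValueError("delay_pairs must be non-empty")
        for ds, dl in self.delay_pairs:
            if ds not in SMALL_DELAYS or dl not in LARGE_DELAYS:
                raise ValueError(f"illegal delay pair ({ds}, {dl})")
        if self.n_reps_per_pair < 2 or self.n_reps_per_pair % 2:
            raise ValueError("n_reps_per_pair must be even and >= 2 for "
                             "left/right counterbalancing")
        if self.bias_sd < 0:
            raise ValueError("bias_sd must be >= 0")
        if min(self.reward_small, self.reward_large) < 0:
            raise ValueError("rewards must be >= 0")
        if self.bias_mode not in ("spatial", "reward"):
            raise ValueError(f"unknown bias_mode {self.bias_mode!r}")
        return self


def dlpfc_config(**kw) -> GeneratorConfig:
    """Prefrontal preset: 9 delay pairs, 2 repeats -> 18 trials/block."""
    return replace(GeneratorConfig(), delay_pairs=DLPFC_DELAY_PAIRS,
                   n_reps_per_pair=2, **kw)


def striatum_config(**kw) -> GeneratorConfig:
    """Striatal preset: all 10 delay pairs, 4 repeats -> 40 trials/block."""
    return replace(GeneratorConfig(), delay_pairs=STRIATUM_DELAY_PAIRS,
                   n_reps_per_pair=4, **kw)


from scipy.special import expit as _logistic


def generate_session(config: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one behavioral session as a trials table.

    Returns a DataFrame with one row per trial, columns
    ``session_id, trial_index, task, d_small, d_large, large_on_right,
    instructed_target, latent_bias, choice_side, choice_reward, valid, t_go``.
    Choice blocks alternate with forced-choice control blocks when
    ``include_control_blocks`` is set; every (delay pair, side) cell appears
    ``n_reps_per_pair / 2`` times per choice block.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    dv_small = discounted_value(
        config.reward_small,
        np.array([p[0] for p in config.delay_pairs]),
        config.discount_rate, config.discount_form)
    dv_large = discounted_value(
        config.reward_large,
        np.array([p[1] for p in config.delay_pairs]),
        config.discount_rate, config.discount_form)
    ddv = dict(zip(config.delay_pairs, np.atleast_1d(dv_large - dv_small)))

    rows = []
    n_per_block = config.n_trials_per_block
    for block in range(config.n_blocks):
        # --- choice block: counterbalanced (pair, side) cells, shuffled ---
        cells = [(p, side) for p in config.delay_pairs
                 for side in (True, False)
                 for _ in range(config.n_reps_per_pair // 2)]
        order = rng.permutation(len(cells))
        for j in order:
            (ds, dl), large_right = cells[j]
            b_t = rng.normal(0.0, config.bias_sd)
            drive = config.inverse_temperature * ddv[(ds, dl)]
            if config.bias_mode == "spatial":
                side_sign = 1.0 if large_right else -1.0
            else:
                side_sign = 1.0
            p_large = _logistic(drive + config.bias_choice_weight * b_t * side_sign)
            chose_large = rng.random() < p_large
            rows.append(dict(
                task="choice", d_small=ds, d_large=dl,
                large_on_right=large_right, instructed_target="none",
                latent_bias=b_t,
                choice_reward="large" if chose_large else "small",
                choice_side=_side(chose_large, large_right),
                valid=True))
        # --- control block: fixation color instructs the target ---
        if config.include_control_blocks:
            ctl = [(side, tgt) for side in (True, False)
                   for tgt in ("small", "large")]
            reps = int(np.ceil(n_per_block / len(ctl)))
            cells = (ctl * reps)[:n_per_block]
            order = rng.permutation(len(cells))
            for j in order:
                large_right, tgt = cells[j]
                b_t = rng.normal(0.0, config.bias_sd)
                follow = rng.random() >= config.control_error_rate
                chosen = tgt if follow else ("small" if tgt == "large" else "large")
                rows.append(dict(
                    task="control", d_small=0.0, d_large=0.0,
                    large_on_right=large_right, instructed_target=tgt,
                    latent_bias=b_t,
                    choice_reward=chosen,
                    choice_side=_side(chosen == "large", large_right),
                    valid=True))

    trials = pd.DataFrame(rows)
    trials.insert(0, "trial_index", np.arange(len(trials)))
    trials.insert(0, "session_id", config.session_id)
    trials["t_go"] = config.t_go
    return trials


def _side(chose_large: bool, large_right: bool) -> str:
    return "R" if chose_large == large_right else "L"


@dataclass
class NeuronSpec:
    """What kind of neuron to simulate."""

    neuron_id: str = "n0"
    region: str = "DLPFC"            # {"DLPFC", "VS", "CD"}
    hemisphere: str = "L"
    bias_type: str = "spatial"       # {"spatial", "reward", "none"}
    preferred_label: str = "R"       # {"L", "R", "small", "large", "none"}
    baseline_rate: float = 8.0       # spikes/s
    bias_gain: float = 3.0           # g, spikes/s per latent-bias unit
    choice_gain: float = 0.0         # cue-locked rate step for choice neurons
    burst_prob: float = 0.0          # P(spike spawns a <10 ms doublet)
    window: tuple = (-1.5, 2.5)      # spike window around cue onset (s)


@dataclass
class NeuronSession:
    """One simulated neuron's spike trains across a session."""

    neuron_id: str
    region: str
    hemisphere: str
    bias_type: str
    preferred_label: str
    spikes: dict = field(repr=False, default_factory=dict)  # trial_index -> sorted array

    def spikes_frame(self) -> pd.DataFrame:
        idx = np.concatenate([np.full(len(s), t)
                              for t, s in self.spikes.items()]) \
            if self.spikes else np.array([], dtype=int)
        ts = np.concatenate(list(self.spikes.values())) \
            if self.spikes else np.array([])
        return pd.DataFrame({"neuron_id": self.neuron_id,
                             "trial_index": idx.astype(int),
                             "spike_time_s": ts})


def _pref_sign(spec: NeuronSpec) -> float:
    # positive latent bias pushes rightward (spatial) / toward large (reward)
    if spec.bias_type == "spatial":
        return {"R": 1.0, "L": -1.0}.get(spec.preferred_label, 0.0)
    if spec.bias_type == "reward":
        return {"large": 1.0, "small": -1.0}.get(spec.preferred_label, 0.0)
    return 0.0


def _poisson_times(rng, rate, t0, t1):
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, n))


def generate_spikes(trials: pd.DataFrame, spec: NeuronSpec,
                    rng: np.random.Generator | int | None = None
                    ) -> NeuronSession:
    """Simulate one neuron's spike trains for every trial of a session.

    Pre-cue spiking ([-1.5, 0) s) is homogeneous Poisson at
    ``baseline + g * b_t * pref_sign`` (floored at 0); post-cue spiking is
    Poisson at baseline plus, for choice neurons (``choice_gain > 0``), a
    rate step when the chosen target matches the preferred label.  Burst
    injection optionally doubles spikes at sub-10-ms lags to exercise the
    burst-consolidation step.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sgn = _pref_sign(spec)
    t0, t1 = spec.window
    spikes = {}
    n_floored = 0
    for row in trials.itertuples(index=False):
        pre_rate = spec.baseline_rate + spec.bias_gain * row.latent_bias * sgn
        if pre_rate <= 0:
            n_floored += 1
            pre_rate = 0.0
        post_rate = spec.baseline_rate
        if spec.choice_gain > 0:
            chosen = (row.choice_side if spec.bias_type != "reward"
                      else row.choice_reward)
            if chosen == spec.preferred_label:
                post_rate += spec.choice_gain
        tr = np.concatenate([
            _poisson_times(rng, pre_rate, t0, 0.0),
            _poisson_times(rng, post_rate, 0.0, t1),
        ])
        if spec.burst_prob > 0 and len(tr):
            dup = rng.random(len(tr)) < spec.burst_prob
            if dup.any():
                extra = tr[dup] + rng.uniform(0.001, 0.009, dup.sum())
                tr = np.sort(np.concatenate([tr, extra]))
        spikes[int(row.trial_index)] = tr
    if n_floored == len(trials) and len(trials):
        warnings.warn(f"neuron {spec.neuron_id}: rate floored to 0 on every "
                      "trial; it will fail the inclusion filter")
    return NeuronSession(spec.neuron_id, spec.region, spec.hemisphere,
                         spec.bias_type, spec.preferred_label, spikes)


def generate_cohort(config: GeneratorConfig, n_neurons: int,
                    bias_fraction: float = 0.3,
                    rng: np.random.Generator | int | None = None,
                    spec_template: NeuronSpec | None = None):
    """Generate ``n_neurons`` (session, neuron) pairs, a ``bias_fraction``
    of them true bias neurons (nonzero gain and choice coupling), the rest
    null (``g = 0`` and ``w = 0`` behavior is *not* forced: null neurons
    simply carry no bias signal in their spikes).

    Each neuron gets its own session draw, mirroring single-electrode
    recording where every neuron comes with its own trials.  Returns a list
    of ``(trials, NeuronSession)`` tuples plus the boolean ground truth.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    template = spec_template or NeuronSpec()
    out, truth = [], []
    for i in range(n_neurons):
        is_bias = i < round(bias_fraction * n_neurons)
        cfg = replace(config, session_id=f"sess{i:03d}", seed=None)
        trials = generate_session(cfg, rng)
        pref = ("R" if rng.random() < 0.5 else "L") \
            if template.bias_type == "spatial" else \
            ("large" if rng.random() < 0.5 else "small")
        spec = replace(template, neuron_id=f"n{i:03d}", preferred_label=pref,
                       bias_gain=template.bias_gain if is_bias else 0.0)
        out.append((trials, generate_spikes(trials, spec, rng)))
        truth.append(is_bias)
    return out, np.array(truth)
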