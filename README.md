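# biasdecode

Tools for studying **pre-deliberation choice biases** in value-based
decision making: does neural activity recorded *before* the decision
alternatives are revealed predict the upcoming choice, and how could such
bias activity be wired into a decision circuit?

The package targets the intertemporal-choice setting used in monkey
electrophysiology: on each trial the animal chooses between a small
reward (0.26 ml) at delay 0 or 2 s and a large reward (0.4 ml) at delay
0–8 s, with interleaved forced-choice control blocks. It provides

* a **synthetic-data generator** producing trial tables and Poisson spike
  trains with the statistical structure this analysis assumes — softmax
  choices on temporally discounted values, nudged by a latent per-trial
  bias that also modulates pre-cue firing;
* the **single-neuron bias decoder**: binomial logistic regression of the
  binary choice on one pre-cue spike count, evaluated by leave-one-out
  cross-validation (LOOCV) against a per-neuron label-shuffle null;
* **population statistics**: binomial/Wilcoxon enrichment tests,
  trial-type trends, bias-vs-choice-population overlap, a
  false-negative (sensitivity) correction by Poisson resimulation,
  error-trial and behavioral-control analyses;
* a **biased winner-take-all (WTA) circuit model** (5-unit reduced and
  11-unit reward-gated versions) with closed-form steady states and
  phase-space/separatrix scans.

## The statistic at the core

For neuron *i*, spikes in the 1.5 s before cue onset (bursts with
inter-spike intervals < 10 ms consolidated) give one count per trial.
LOOCV logistic regression predicts the choice (right/left saccade or
large/small reward; predicted probability ≥ 0.5 ⇒ class 1) with accuracy
*aᵢ*. Shuffling the labels *B* = 10,000 times and repeating the LOOCV
yields a chance distribution whose mean *cᵢ* reflects the animal's side
preference. Predictive power above chance is the **proportion
explained**

> PEᵢ = (aᵢ − cᵢ) / (1 − cᵢ),

e.g. a = 0.75 against c = 0.65 gives PE = 0.29. Neurons whose accuracy
on *undetermined* trials (small-reward choice ratio within [0.35, 0.65])
ranks in the top 5% of their own null are **bias neurons**. Predictive
power should fall off as the discounted values diverge:
UNDET > WDET > SDET ≈ NC.

In the circuit model, choice units x_L, x_R (inputs I_L, I_R = discounted
values) compete via a shared inhibitory unit; a pointer unit p_i
bidirectionally coupled (δ = 0.1) to each choice unit converts a bias
input b_i > T into extra gain, so a transient pre-cue bias can decide the
winner. The winner's steady activity with an active bias is
(I_w + δ(b_w − T) + T(β₁ − 1)) / (1 − α + β₁β₂ − δ²).

## Worked example

```python
import numpy as np
import biasdecode as bd

rng = np.random.default_rng(3)
cfg = bd.dlpfc_config()                  # 9 delay pairs, 18 trials/block
trials = bd.generate_session(cfg, rng)
neuron = bd.generate_spikes(
    trials, bd.NeuronSpec(neuron_id="ex", preferred_label="R"), rng)

part = bd.partition_trials(trials)
undet = part.trials_of_type("UNDET")
counts = bd.decode.window_counts(neuron, trials, "pre_cue")
x = counts.loc[undet].to_numpy()
y = bd.choice_labels(trials, "spatial").loc[undet].to_numpy()

dec = bd.BiasDecoder(n_shuffles=2000, random_state=1).fit(x, y)
print(f"LOOCV accuracy     a = {dec.accuracy_:.3f}")
print(f"chance level       c = {dec.chance_:.3f}")
print(f"proportion explained = {dec.proportion_explained_:.3f}")
print(f"null percentile      = {dec.percentile_:.1f}")
print(f"call                 = {dec.call_}")
```

prints

```
LOOCV accuracy     a = 0.775
chance level       c = 0.633
proportion explained = 0.387
null percentile      = 99.9
call                 = bias
```

On this neuron's 40 undetermined trials the pre-cue count predicts the
upcoming saccade on 77.5% of held-out trials, while label shuffles
average 63.3% (the session is side-imbalanced, so chance is well above
0.5); the count explains 39% of the residual predictability, ranks above
99.9% of the null, and the neuron is called a spatial-bias neuron.

`BiasDecoder` and `SingleNeuronLogistic` follow scikit-learn estimator
conventions (`fit`, `predict`, `get_params`, fitted `*_` attributes) and
compose with sklearn tooling; `decode_cohort` / `period_profile` run the
procedure over cohorts and over the pre-cue/cue/go × UNDET/WDET/SDET/NC
grid. A `biasdecode` command line exposes `simulate`, `partition`,
`decode`, `population`, `wta-sim` and `wta-phase` over tab-separated
session files.

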