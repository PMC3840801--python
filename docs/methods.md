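# Methods

## Behavioral generative model

A session consists of alternating choice and control blocks. Within a
choice block every legal delay pair (small reward at 0 or 2 s, large at
0/2/4/6/8 s; the prefrontal preset drops the (2, 0) pair, the striatal
preset keeps all 10) appears a fixed, even number of times with the
large-reward side counterbalanced — 9 × 2 = 18 trials per prefrontal
block, 10 × 4 = 40 per striatal block. Control blocks match the choice
blocks in length; the fixation color instructs the target and the
generator follows the instruction (an error rate can be injected).

Choice follows a softmax on temporally discounted values with a latent
trial bias:

P(large) = σ( γ·(DV_large − DV_small) + w·b_t·s ),

where DV(m, d) = m / (1 + k·d) (hyperbolic by default; exponential
m·e^{−k d} available — companion work on this task family fits
hyperbolic discounting, and at the delays used the two are nearly
indistinguishable), b_t ~ N(0, σ_b) is drawn fresh each trial, and s
maps the bias onto the side carrying the large reward (spatial mode) or
onto reward identity (reward mode). Control trials draw b_t too, but the
instruction — not b_t — fixes the choice, which is what makes no-choice
trials a negative control for the decoder.

Defaults: k = 0.2 s⁻¹ (monkeys discount steeply; this puts two to four
delay pairs per session in the undetermined band, matching the task's
design intent), γ = 20 (strongly determined pairs are chosen ≳ 95%
toward the higher value, as observed for immediate–immediate pairs),
σ_b = 1 (the bias scale is absorbed into the gains, so unit SD is a
normalization, not a claim), w = 0.5, bias gain g = 3 spikes/s per bias
unit, baseline 8 spikes/s. With these values a true bias neuron's
undetermined-trial decoding accuracy lands around 0.55–0.75 and the
cohort-mean proportion explained is ≈ 0.10 on UNDET, ≈ 0.05 on WDET and
≈ 0 on SDET/NC — the qualitative gradient the analysis is designed to
detect, at a realistic effect size. Per-trial spiking is piecewise
homogeneous Poisson: rate baseline + g·b_t·(preference sign) in the
pre-cue window (floored at 0), baseline afterwards, plus an optional
choice-locked rate step in the cue window for simulating choice neurons
and an optional sub-10-ms doublet ("burst") injection to exercise burst
consolidation.

What the generator does **not** emulate: non-Poisson count dispersion,
slow nonstationarity (drift, satiety), reaction times, fixation breaks
(the `valid` flag exists so the exclusion rule is still exercised by
fixture injection), eye movements, and any correlation structure across
simultaneously recorded neurons. Passing tests therefore demonstrate
that the pipeline is correct and calibrated under its stated
assumptions, not that real cortex satisfies them.

## Preprocessing conventions

Time 0 = cue onset; every window is half-open [start, end). Pre-cue =
[−1.5, 0) (last 0.5 s of the inter-trial interval plus the 1 s fore
period), cue = [0, 1), go = [t_go, t_go + 0.5). Bursts — runs of spikes
whose successive inter-spike intervals are all < 10 ms — collapse to the
run's first spike (run-based, not distance-from-last-kept; the operation
is idempotent). The spike-density function (unit-area Gaussian kernel,
SD 100 ms) is provided for display only and enters no statistic.

Trial types per delay pair from the small-reward choice ratio r over
valid choice trials: UNDET for r ∈ [0.35, 0.65], WDET for
[0.25, 0.35) ∪ (0.65, 0.75], SDET otherwise; control trials are NC.
Boundary values go to the less-determined neighbor so no trial is
dropped on a measure-zero technicality. Inclusion requires ≥ 1 UNDET
pair, mean pre-cue rate ≥ 0.5 spikes/s, and (spatial analysis only) each
side chosen on ≥ 25% of trials; trials flagged invalid (following a
post-cue fixation break) are dropped first.

## Decoder

The fit is maximum-likelihood logistic regression of the binary choice
on a single spike count, computed on count-aggregated binomial cells by
a 2-parameter Newton solver batched over all (shuffle × LOOCV-fold)
problems — this is what makes 10,000-shuffle nulls per neuron feasible.
Predicted probability ≥ 0.5 maps to class 1 (the tie goes to class 1).
Degenerate training sets use explicit rules instead of divergent
coefficients: single-class → always that class; a single unique count →
intercept-only majority (note the LOOCV flip: balanced labels with
uninformative counts score 0, which the shuffle null absorbs); complete
separation → a step at the midpoint of the gap between the class count
ranges (midpoint probability 0.5 → class 1); quasi-complete separation
(classes share exactly one count) → a step at the shared count with that
cell's majority vote. The engine is validated fold by fold against a
brute-force grid-search likelihood maximizer on small instances, and the
single fit against scikit-learn's (effectively unpenalized) logistic
regression — neither is used in the pipeline itself.

The null permutes labels across trials (class counts preserved); the
chance level is the null mean, which tracks the animal's side
preference. The percentile of the observed accuracy uses mid-ranks over
ties; "bias" means percentile ≥ 95, "anti-bias" ≤ 5. Count discreteness
makes the rule slightly conservative: the measured false-positive rate
on null neurons is ≈ 5% (pooled over seeds) and never exceeded
5% + 2 binomial SE in our runs. Bias calls are made only on the
pre-cue × UNDET cell; all other window × trial-type cells are
evaluation-only, and cells under a configurable minimum of trials
(default 5) are reported missing, mirroring sessions that lack
weakly-determined pairs.

## Population statistics

Enrichment: exact binomial tail P(X ≥ n_bias) at p₀ = 0.05 (k = 0
reported as p = 1); one-sample Wilcoxon of percentiles vs 50
(one-sided); binomial test of the top-50-percentile count vs 0.5.
Per-trial-type one-tailed t-tests of proportion explained vs 0 stand in
for pairing accuracy with chance per neuron (PE is exactly that pairing,
rescaled). The trend regression codes NC = 0, SDET = 1, WDET = 2,
UNDET = 3 and tests for a positive slope, so "more predictive where less
determined" is a one-sided alternative. Overlap of neuron sets uses a
2×2 Pearson χ² (1 df), falling back to Fisher's exact test when an
expected cell is below 1. The choice-neuron screen is a deliberately
simplified stand-in for the companion value-regression models: OLS of
cue-period rate on a chosen-side indicator plus both targets' discounted
values; a neuron is a choice neuron when the choice coefficient is
significant at 0.05 (the DV covariates absorb pure value coding).

False-negative correction: for each detected bias neuron, its measured
preferred/non-preferred mean pre-cue rates and trial counts seed Poisson
resimulations (1.5 s windows) that are pushed through the full
identification; sensitivity s = re-detection fraction, and the corrected
cohort size is round(n_detected / s) — 12 detected at s = 0.7 corrects
to 17. For parameter-recovery checks the package also inverts the full
detection-rate model d = f·s + (1 − f)·α, which additionally accounts
for false positives; this matters at small cohort sizes where α·n is
comparable to the detected count.

Error trials are immediate–immediate pairs on which the small reward was
chosen (~3–5% of such trials under the defaults). Per-neuron z-scored
pre-cue counts on error trials whose small-reward side matches the
neuron's preferred direction are compared to all other trials by a
one-tailed Welch t-test. Serial dependence of undetermined choices uses
the φ coefficient at lags 1–10 with a permutation null and Bonferroni
correction across lags (the statistic is unspecified in the source
analyses; φ + permutation is the assumption-free choice). The
preferred-direction split uses the one-sided exact binomial tail of the
majority direction (17 of 29 → p ≈ 0.23 under this convention).

## Circuit model

Reduced circuit: units x_L, x_R, h, p_L, p_R; f(z) = max(0, z);
τ = 0.01 s, G = 1, T = 1, α = 1.5, β₁ = 3, β₂ = 0.4, δ = 0.1 (stability:
1 − α + β₁β₂ − δ² = 0.69 > 0). Winner steady states:
(I_w + δ(b_w − T) + T(β₁ − 1)) / 0.69 with an active bias unit,
(I_w + T(β₁ − 1)) / 0.7 without (the two differ by the additive bias
term and the δ² gain increase). The full model adds reward-bias units
q_lo/q_hi (inputs c_lo/c_hi) and four gate units d with threshold
T_d = 8, coupled q→d at 5 and d↔x at 0.1; a cue-time gating input
(amplitude 4 by default, chosen so that an active q at input c = 2 plus
the gate crosses T_d while either alone stays below it) routes the
reward bias to the side carrying that reward only after cue onset.

Integration is forward Euler, u ← u + (Δ/τ)(f(drive − T) − G·u). **The
default step is Δ = 1 ms, not Δ = τ = 10 ms.** At Δ = τ the update
degenerates to the direct map u ← f(drive − T), whose linearization
around the WTA fixed point has complex eigenvalues of modulus
√(β₁β₂) ≈ 1.1 > 1: trajectories enter a limit cycle and no convergence
tolerance is ever met, although the continuous-time system is stable
(real part (0.75 − 1)/τ < 0). Δ = 1 ms is well inside the Euler
stability region; simulated steady states then match the closed forms to
< 10⁻⁶ and halving Δ again changes nothing at that tolerance (both are
test assertions). Δ remains configurable, and the direct-map behavior at
Δ = τ is itself under test as a documented non-convergent regime.

Convergence is declared when the maximum per-unit change over 10 steps
falls below 10⁻⁹, checked only after the last scheduled input
transition (a pre-input zero plateau must not count). The winner is the
choice unit with positive steady activity while the other is ≤ 10⁻⁶; on
the exact symmetric manifold the model reports *no winner* rather than
randomizing — the deterministic model should expose its knife-edge, not
hide it. Phase-space scans integrate the whole (b_L, ΔI) grid
vectorized and decide winners from the mean activity over the final 20%
of the horizon, which is robust in both the convergent and the
direct-map regimes. The separatrix is, per b_L, the smallest ΔI at
which x_L wins; its kink is the first b_L whose critical ΔI departs from
the low-b_L level by more than half a ΔI grid step (half a step
separates real movement from floating-point noise on a flat level; the
detectable departure lags the true kink by about one ΔI step divided by
the separatrix slope, which the scan resolution keeps within one b_L
step).

## Problem sizes and seeds

The full procedure uses B = 10,000 shuffles and 1,000 resimulation
repetitions. The test suite and the scripted reproduction scale these to
B = 150–2,000 and 25–40 repetitions, and use cohorts of 20–200 neurons
with 4–10 blocks per session; the specificity study uses 200 null
neurons at B = 500 with ~30 undetermined trials each. Every stochastic
routine takes a seed or `numpy.random.Generator`; the CLI derives one
stream per subcommand from the master seed by fixed offsets so adding a
stage never perturbs another stage's draws. Parameter-recovery and
enrichment tests raise the generator's coupling (g = 5, w = 1.5) so that
per-neuron detection sensitivity is well above the false-positive rate —
at the default effect size those cohort sizes would measure mostly
Monte-Carlo noise; the gradient and calibration tests run at the
defaults.

## Known limitations

* The decoder is univariate by design; no population decoding.
* The choice-neuron screen is a simplified surrogate, not the companion
  models' full value regression.
* The false-negative resimulation inherits the Poisson assumption; real
  overdispersion would lower true sensitivity.
* The circuit model is deterministic and noise-free; the generator and
  the model share only the conceptual bias-input structure, not
  parameters.
* Recovery of a cohort's bias fraction is only informative when
  sensitivity clearly exceeds the selection rule's false-positive rate.
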