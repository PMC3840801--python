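"""Population-level inference over per-neuron decoding results.

Covers the cohort questions: are there more bias neurons than the 5%
the tail rule alone would flag; do accuracy percentiles exceed 50 on
average; does predictive power decay from undetermined toward strongly
determined and control trials; do bias and choice populations overlap
beyond independence; how many true bias neurons were missed (Poisson
resimulation sensitivity); and the behavioral controls (serial
dependence of choices, preferred-direction split, hemisphere by
direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decode import chance_distribution, classify_bias, loocv_accuracy
from .preprocess import AnalysisWindows, partition_trials, window_counts

__all__ = [
    "PopulationSummary",
    "FalseNegativeReport",
    "population_tests",
    "overlap_test",
    "choice_neuron_test",
    "estimate_bias_spec",
    "false_negative_rate",
    "error_trial_analysis",
    "serial_dependence",
    "behavioral_controls",
    "binomial_tail_p",
    "corrected_count",
    "estimated_bias_fraction",
    "zscore_counts",
]

#: ordinal coding of trial types for the predictive-power trend: higher
#: codes mean less stimulus-determined choices, so the expected trend is a
#: positive slope of proportion explained on the code.
TREND_CODE = {"NC": 0, "SDET": 1, "WDET": 2, "UNDET": 3}


def corrected_count(n_detected: int, sensitivity: float) -> int:
    """Detection-sensitivity-corrected neuron count: round(n / s).

    With 12 detected neurons and a resimulation sensitivity of 0.7 the
    corrected cohort size is 12 / 0.7 ~= 17.
    """
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must be in (0, 1]")
    return int(round(n_detected / sensitivity))


def estimated_bias_fraction(n_detected: int, n_neurons: int,
                            sensitivity: float,
                            alpha: float = 0.05) -> float:
    """Estimate the true bias-neuron fraction of a cohort.

    Inverts the expected detection rate d = f*s + (1 - f)*alpha, where s
    is the resimulation sensitivity and alpha the false-positive rate of
    the selection rule, giving f = (d - alpha) / (s - alpha), clipped to
    [0, 1].
    """
    if n_neurons <= 0:
        raise ValueError("empty cohort")
    if sensitivity <= alpha:
        raise ValueError("sensitivity must exceed the false-positive rate")
    d = n_detected / n_neurons
    return float(np.clip((d - alpha) / (sensitivity - alpha), 0.0, 1.0))


def binomial_tail_p(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial P(X >= k); k = 0 reported as 1."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


@dataclass
class PopulationSummary:
    n_neurons: int
    n_bias: int
    n_anti_bias: int
    binomial_p: float
    mean_percentile: float
    wilcoxon_p: float | None
    n_top50: int
    top50_binomial_p: float
    per_type: pd.DataFrame = field(repr=False)
    trend_slope: float = np.nan
    trend_p: float = np.nan
    notes: list = field(default_factory=list)


def population_tests(results: pd.DataFrame,
                     profile: pd.DataFrame | None = None,
                     alpha: float = 0.05) -> PopulationSummary:
    """Cohort-level tests over a per-neuron results table.

    ``results`` must hold one pre-cue UNDET row per included neuron with
    columns ``call``, ``percentile``, ``accuracy``, ``chance``.  If
    ``profile`` (the full window x trial-type table) is given, per-type
    one-tailed t-tests of proportion explained vs. 0 and the trend
    regression across trial types are added.

    Tests: exact binomial tail on the bias-neuron count vs. the nominal
    5%; one-sample Wilcoxon of percentiles vs. 50; binomial test of the
    top-50-percentile count vs. 0.5; per-type t-tests and a one-sided
    OLS slope of proportion explained on the ordinal trial-type code.
    """
    inc = results[results.get("included", True) == True]  # noqa: E712
    n = len(inc)
    if n < 2:
        raise ValueError("need at least 2 included neurons")
    n_bias = int((inc.call == "bias").sum())
    n_anti = int((inc.call == "anti_bias").sum())
    notes = []
    pct = inc.percentile.to_numpy(dtype=float)
    if np.allclose(pct, 50.0):
        wil_p = None
        notes.append("wilcoxon_degenerate_all_percentiles_50")
    else:
        d = pct - 50.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wil_p = float(stats.wilcoxon(d[d != 0],
                                         alternative="greater").pvalue)
    n_top = int((pct > 50.0).sum())

    per_type_rows = []
    slope = p_slope = np.nan
    if profile is not None:
        prof = profile[(profile.window == "pre_cue")
                       & profile.proportion_explained.notna()]
        xs, ys = [], []
        for ttype, grp in prof.groupby("trial_type"):
            pe = grp.proportion_explained.to_numpy(dtype=float)
            if len(pe) >= 2 and pe.std() > 0:
                t_p = float(stats.ttest_1samp(
                    pe, 0.0, alternative="greater").pvalue)
            else:
                t_p = np.nan
            per_type_rows.append(dict(
                trial_type=ttype, n=len(pe), mean_pe=float(pe.mean()),
                sem_pe=float(pe.std(ddof=1) / np.sqrt(len(pe)))
                if len(pe) > 1 else np.nan,
                t_p=t_p))
            xs.append(np.full(len(pe), TREND_CODE[ttype], dtype=float))
            ys.append(pe)
        if len(per_type_rows) >= 2:
            x = np.concatenate(xs)
            y = np.concatenate(ys)
            lr = stats.linregress(x, y, alternative="greater")
            slope, p_slope = float(lr.slope), float(lr.pvalue)
    per_type = pd.DataFrame(per_type_rows)

    return PopulationSummary(
        n_neurons=n, n_bias=n_bias, n_anti_bias=n_anti,
        binomial_p=binomial_tail_p(n_bias, n, alpha),
        mean_percentile=float(pct.mean()), wilcoxon_p=wil_p,
        n_top50=n_top,
        top50_binomial_p=binomial_tail_p(n_top, n, 0.5),
        per_type=per_type, trend_slope=slope, trend_p=p_slope,
        notes=notes)


def overlap_test(set_a, set_b, universe):
    """Is membership of two neuron sets associated beyond independence?

    2x2 Pearson chi-square (1 df) on joint membership over ``universe``;
    falls back to Fisher's exact test when an expected cell drops below
    1.  Returns ``(p, method)``.
    """
    universe = list(universe)
    sa, sb = set(set_a), set(set_b)
    if not sa <= set(universe) or not sb <= set(universe):
        raise ValueError("sets must be subsets of the universe")
    in_a = np.array([u in sa for u in universe])
    in_b = np.array([u in sb for u in universe])
    table = np.array([[(in_a & in_b).sum(), (in_a & ~in_b).sum()],
                      [(~in_a & in_b).sum(), (~in_a & ~in_b).sum()]])
    expected = stats.contingency.expected_freq(table)
    if (expected < 1).any():
        return float(stats.fisher_exact(table).pvalue), "fisher"
    chi2 = stats.chi2_contingency(table, correction=False)
    return float(chi2.pvalue), "chi2"


def choice_neuron_test(neuron, trials: pd.DataFrame,
                       windows: AnalysisWindows = AnalysisWindows(),
                       discount=None, alpha: float = 0.05):
    """Simplified choice-neuron screen on cue-period activity.

    Linear regression of the cue-period firing rate on a chosen-target
    indicator with both targets' discounted values as covariates; the
    neuron is a choice neuron when the choice coefficient is significant
    at ``alpha``.  (A deliberately reduced stand-in for the richer
    value-regression models used to define choice neurons; it captures
    the defining property — choice coding over and above value coding.)

    ``discount`` maps ``(magnitude, delay) -> value``; defaults to
    hyperbolic discounting with k = 0.2 /s and the standard reward sizes.
    """
    from .synth import discounted_value
    if discount is None:
        def discount(mag, delay):
            return discounted_value(mag, delay, 0.2)
    choice = trials[(trials.task == "choice") & trials.valid]
    counts = window_counts(neuron, trials, "cue", windows)
    idx = counts.index.intersection(choice.trial_index)
    choice = choice.set_index("trial_index").loc[idx]
    dur = windows.cue[1] - windows.cue[0]
    rate = counts.loc[idx].to_numpy() / dur
    chose_right = (choice.choice_side == "R").astype(float).to_numpy()
    dv_l = np.where(choice.large_on_right, discount(0.26, choice.d_small),
                    discount(0.4, choice.d_large))
    dv_r = np.where(choice.large_on_right, discount(0.4, choice.d_large),
                    discount(0.26, choice.d_small))
    X = np.column_stack([np.ones_like(rate), chose_right, dv_l, dv_r])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return None, np.nan  # rank-deficient design, neuron skipped
    import statsmodels.api as sm
    fit = sm.OLS(rate, X).fit()
    p = float(fit.pvalues[1])
    return bool(p < alpha), p


def estimate_bias_spec(trials, neuron, analysis: str = "spatial",
                       windows: AnalysisWindows = AnalysisWindows()) -> dict:
    """Measured tuning of a detected bias neuron, as input to the
    false-negative resimulation: mean pre-cue firing rate and trial count
    for the preferred and non-preferred choice over UNDET trials."""
    from .decode import choice_labels
    part = partition_trials(trials)
    idx = np.intersect1d(part.trials_of_type("UNDET"),
                         trials.loc[trials.valid, "trial_index"].to_numpy())
    counts = window_counts(neuron, trials, "pre_cue", windows).loc[idx]
    y = choice_labels(trials, analysis).loc[idx].to_numpy()
    dur = windows.pre_cue[1] - windows.pre_cue[0]
    r1 = counts.to_numpy()[y == 1].mean() / dur if (y == 1).any() else 0.0
    r0 = counts.to_numpy()[y == 0].mean() / dur if (y == 0).any() else 0.0
    if r1 >= r0:
        return dict(neuron_id=neuron.neuron_id, rate_pref=r1,
                    rate_nonpref=r0, n_pref=int((y == 1).sum()),
                    n_nonpref=int((y == 0).sum()))
    return dict(neuron_id=neuron.neuron_id, rate_pref=r0, rate_nonpref=r1,
                n_pref=int((y == 0).sum()), n_nonpref=int((y == 1).sum()))


@dataclass
class FalseNegativeReport:
    per_neuron: pd.DataFrame      # neuron_id, sensitivity
    mean_sensitivity: float
    n_detected: int
    corrected_count: int | None


def false_negative_rate(bias_specs, n_reps: int = 1000,
                        n_shuffles: int = 1000, alpha: float = 0.05,
                        duration: float = 1.5, rng=None
                        ) -> FalseNegativeReport:
    """Sensitivity of the bias-identification procedure by resimulation.

    ``bias_specs`` is a list of dicts, one per detected bias neuron,
    with keys ``neuron_id``, ``rate_pref``, ``rate_nonpref`` (mean
    pre-cue firing rates, spikes/s) and ``n_pref``, ``n_nonpref`` (trial
    counts).  Each rep draws Poisson counts over ``duration`` seconds
    with those rates and trial counts, runs the full identification
    (LOOCV accuracy vs. shuffle null, top-``alpha`` call), and records
    whether the simulated neuron is re-detected.  The corrected cohort
    size is ``round(n_detected / mean sensitivity)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for spec in bias_specs:
        n_p, n_np = int(spec["n_pref"]), int(spec["n_nonpref"])
        lam_p = spec["rate_pref"] * duration
        lam_np = spec["rate_nonpref"] * duration
        labels = np.concatenate([np.ones(n_p), np.zeros(n_np)])
        hits = 0
        for _ in range(n_reps):
            counts = np.concatenate([rng.poisson(lam_p, n_p),
                                     rng.poisson(lam_np, n_np)])
            a = loocv_accuracy(counts, labels)
            null, _ = chance_distribution(counts, labels, n_shuffles, rng)
            _, call = classify_bias(a, null, alpha)
            hits += call == "bias"
        rows.append(dict(neuron_id=spec["neuron_id"],
                         sensitivity=hits / n_reps))
    per = pd.DataFrame(rows)
    s = float(per.sensitivity.mean())
    n_det = len(bias_specs)
    corrected = corrected_count(n_det, s) if s > 0 else None
    return FalseNegativeReport(per, s, n_det, corrected)


def zscore_counts(counts: np.ndarray) -> np.ndarray:
    """Standardize one neuron's per-trial counts (mean 0, SD 1)."""
    counts = np.asarray(counts, dtype=float)
    sd = counts.std(ddof=0)
    if sd == 0:
        return np.zeros_like(counts)
    return (counts - counts.mean()) / sd


def error_trial_analysis(bias_pairs, windows=AnalysisWindows()):
    """Bias-neuron firing on error trials (both delays 0, small chosen).

    ``bias_pairs``: list of ``(trials, neuron)`` for spatial-bias neurons
    whose spiking should be elevated when their preferred side carries
    the *smaller* discounted value.  Pre-cue counts are z-scored per
    neuron over all its trials; z on aligned error trials (preferred
    side = side of the small target) is compared with z elsewhere by a
    one-tailed two-sample t-test.  Skipped with a message when no error
    trials exist.
    """
    z_err, z_rest = [], []
    for trials, neuron in bias_pairs:
        counts = window_counts(neuron, trials, "pre_cue", windows)
        idx = counts.index.to_numpy()
        z = pd.Series(zscore_counts(counts.to_numpy()), index=idx)
        t = trials.set_index("trial_index").loc[idx]
        is_err = ((t.task == "choice") & (t.d_small == 0) & (t.d_large == 0)
                  & (t.choice_reward == "small")).to_numpy()
        small_side = np.where(t.large_on_right, "L", "R")
        aligned = small_side == neuron.preferred_label
        sel = is_err & aligned
        z_err.extend(z[sel])
        z_rest.extend(z[~sel])
    if len(z_err) == 0:
        return dict(skipped=True,
                    message="no aligned error trials in this cohort")
    z_err, z_rest = np.asarray(z_err), np.asarray(z_rest)
    t_p = float(stats.ttest_ind(z_err, z_rest, equal_var=False,
                                alternative="greater").pvalue)
    return dict(skipped=False,
                n_error=len(z_err),
                mean_z_error=float(z_err.mean()),
                sem_z_error=float(z_err.std(ddof=1) / np.sqrt(len(z_err)))
                if len(z_err) > 1 else np.nan,
                mean_z_rest=float(z_rest.mean()),
                sem_z_rest=float(z_rest.std(ddof=1) / np.sqrt(len(z_rest))),
                t_p=t_p)


def _phi_coefficient(x, y):
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def serial_dependence(trials: pd.DataFrame, max_lag: int = 10,
                      n_perm: int = 10_000, rng=None) -> pd.DataFrame:
    """Association between the current UNDET choice and earlier choices.

    For each lag 1..``max_lag``: the phi coefficient between the current
    choice side (restricted to UNDET trials) and the choice ``lag``
    trials back, with a permutation p-value (two-sided) and Bonferroni
    correction across lags.  Lags with too few pairs are omitted.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    part = partition_trials(trials)
    chooser = trials[(trials.task == "choice") & trials.valid] \
        .sort_values("trial_index")
    side = (chooser.choice_side == "R").astype(float).to_numpy()
    is_undet = chooser.trial_index.isin(
        part.trials_of_type("UNDET")).to_numpy()
    rows = []
    for lag in range(1, max_lag + 1):
        cur = side[lag:]
        prev = side[:-lag]
        mask = is_undet[lag:]
        x, y = cur[mask], prev[mask]
        if len(x) < 10 or x.std() == 0 or y.std() == 0:
            continue
        phi = _phi_coefficient(x, y)
        perms = np.empty(n_perm)
        for b in range(n_perm):
            perms[b] = _phi_coefficient(x, rng.permutation(y))
        p = float((np.abs(perms) >= abs(phi) - 1e-12).mean())
        rows.append(dict(lag=lag, n=len(x), phi=phi, p=p,
                         p_bonferroni=min(1.0, p * max_lag)))
    return pd.DataFrame(rows)


def behavioral_controls(trials: pd.DataFrame,
                        neuron_meta: pd.DataFrame | None = None,
                        max_lag: int = 10, n_perm: int = 10_000,
                        rng=None) -> dict:
    """Controls against trivial sources of apparent bias activity.

    (i) serial dependence of UNDET choices on up to ``max_lag`` earlier
    choices; (ii) binomial test that bias neurons' preferred directions
    split evenly (one-sided, majority direction vs. 0.5, matching the
    printed convention); (iii) chi-square of hemisphere x preferred
    direction.  ``neuron_meta`` needs columns ``preferred_label`` and
    ``hemisphere`` for (ii)/(iii).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = {"serial": serial_dependence(trials, max_lag, n_perm, rng)}
    if neuron_meta is not None and len(neuron_meta):
        pref = neuron_meta.preferred_label.to_numpy()
        n = len(pref)
        k = int(max((pref == "L").sum(), (pref == "R").sum(),
                    (pref == "small").sum(), (pref == "large").sum()))
        out["preferred_split"] = dict(
            n=n, n_majority=k, binomial_p=binomial_tail_p(k, n, 0.5))
        hemi = neuron_meta.hemisphere.to_numpy()
        if len(set(hemi)) > 1 and len(set(pref)) > 1:
            table = pd.crosstab(hemi, pref).to_numpy()
            expected = stats.contingency.expected_freq(table)
            if (expected < 1).any():
                if table.shape == (2, 2):
                    p, method = float(stats.fisher_exact(table).pvalue), "fisher"
                else:
                    p, method = np.nan, "undefined"
            else:
                p = float(stats.chi2_contingency(table,
                                                 correction=False).pvalue)
                method = "chi2"
            out["hemisphere_by_direction"] = dict(p=p, method=method)
        else:
            out["hemisphere_by_direction"] = dict(
                p=np.nan, method="degenerate_single_level")
    return out
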