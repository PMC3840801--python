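"""Population-statistics tests: cohort inference, overlap, false-negative
correction, error trials, behavioral controls."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import biasdecode as bd
from biasdecode import popstats
from biasdecode.popstats import (behavioral_controls, binomial_tail_p,
                                 choice_neuron_test, corrected_count,
                                 error_trial_analysis,
                                 estimated_bias_fraction,
                                 estimate_bias_spec, false_negative_rate,
                                 overlap_test, population_tests,
                                 serial_dependence, zscore_counts)


def _results_frame(percentiles, calls):
    return pd.DataFrame(dict(
        neuron_id=[f"n{i}" for i in range(len(calls))],
        included=True, percentile=percentiles, call=calls,
        accuracy=0.6, chance=0.5, proportion_explained=0.2))


class TestPopulationTests:
    def test_zero_bias_neurons_tail_is_one(self):
        res = _results_frame(np.linspace(10, 90, 100), ["none"] * 100)
        summ = population_tests(res)
        assert summ.binomial_p == 1.0

    def test_enriched_cohort_rejects(self, rng):
        # 30 of 100 bias calls, percentiles shifted high
        calls = ["bias"] * 30 + ["none"] * 70
        pct = np.concatenate([rng.uniform(95, 100, 30),
                              rng.uniform(0, 100, 70)])
        summ = population_tests(_results_frame(pct, calls))
        assert summ.binomial_p < 1e-10
        assert summ.wilcoxon_p < 0.01
        assert summ.top50_binomial_p < 0.05

    def test_all_percentiles_fifty_degenerate(self):
        res = _results_frame(np.full(10, 50.0), ["none"] * 10)
        summ = population_tests(res)
        assert summ.wilcoxon_p is None
        assert "wilcoxon_degenerate_all_percentiles_50" in summ.notes

    def test_trend_slope_on_graded_profile(self, rng):
        res = _results_frame(rng.uniform(0, 100, 20), ["none"] * 20)
        rows = []
        means = {"UNDET": 0.15, "WDET": 0.06, "SDET": 0.01, "NC": 0.0}
        for t, m in means.items():
            for i in range(20):
                rows.append(dict(window="pre_cue", trial_type=t,
                                 proportion_explained=rng.normal(m, 0.03)))
        summ = population_tests(res, profile=pd.DataFrame(rows))
        assert summ.trend_slope > 0
        assert summ.trend_p < 1e-6
        per = summ.per_type.set_index("trial_type")
        assert per.loc["UNDET", "t_p"] < 0.001
        assert per.loc["NC", "mean_pe"] == pytest.approx(0.0, abs=0.02)

    def test_binomial_tail_convention(self):
        assert binomial_tail_p(0, 100, 0.05) == 1.0
        assert binomial_tail_p(1, 1, 0.05) == pytest.approx(0.05)


class TestOverlap:
    def test_identical_sets_maximal_association(self):
        universe = [f"n{i}" for i in range(100)]
        p, method = overlap_test(universe[:20], universe[:20], universe)
        assert p < 1e-10

    def test_independent_looking_sets_large_p(self):
        universe = [f"n{i}" for i in range(100)]
        a = universe[:50]
        b = universe[25:75]      # overlap 25 = exactly independence
        p, _ = overlap_test(a, b, universe)
        assert p > 0.9

    def test_fisher_fallback_on_sparse_table(self):
        universe = [f"n{i}" for i in range(30)]
        p, method = overlap_test(universe[:1], universe[1:2], universe)
        assert method == "fisher" and 0 <= p <= 1

    def test_subset_requirement(self):
        with pytest.raises(ValueError):
            overlap_test(["x"], [], ["a", "b"])


class TestChoiceNeuron:
    def test_choice_locked_neuron_detected(self, small_session, rng):
        _, trials = small_session
        spec = bd.NeuronSpec(bias_gain=0.0, choice_gain=8.0,
                             preferred_label="R")
        ns = bd.generate_spikes(trials, spec, rng)
        is_choice, p = choice_neuron_test(ns, trials)
        assert is_choice and p < 0.01

    def test_unmodulated_neuron_rarely_flagged(self, small_session, rng):
        _, trials = small_session
        hits = []
        for i in range(20):
            ns = bd.generate_spikes(trials, bd.NeuronSpec(bias_gain=0.0),
                                    rng)
            flag, _ = choice_neuron_test(ns, trials)
            hits.append(bool(flag))
        assert np.mean(hits) <= 0.2

    def test_value_only_neuron_not_flagged(self, rng):
        # cue rate tracks the summed discounted value, not the choice:
        # the DV covariates must absorb it
        cfg = bd.dlpfc_config(n_blocks=6, include_control_blocks=False)
        trials = bd.generate_session(cfg, rng)
        hits = []
        for rep in range(10):
            spikes = {}
            for row in trials.itertuples():
                dv = (bd.discounted_value(0.4, row.d_large, 0.2)
                      + bd.discounted_value(0.26, row.d_small, 0.2))
                rate = 4.0 + 25.0 * dv
                n = rng.poisson(rate * 1.0)
                spikes[int(row.trial_index)] = np.sort(rng.uniform(0, 1, n))
            ns = bd.NeuronSession(f"v{rep}", "DLPFC", "L", "none", "none",
                                  spikes)
            flag, _ = choice_neuron_test(ns, trials)
            hits.append(bool(flag))
        assert np.mean(hits) <= 0.2


class TestFalseNegatives:
    def test_corrected_count_worked_example(self):
        assert corrected_count(12, 0.7) == 17

    def test_sensitivity_one_identity(self):
        assert corrected_count(5, 1.0) == 5

    def test_separated_rates_near_perfect_sensitivity(self, rng):
        spec = dict(neuron_id="s", rate_pref=20.0, rate_nonpref=2.0,
                    n_pref=30, n_nonpref=30)
        rep = false_negative_rate([spec], n_reps=25, n_shuffles=200,
                                  rng=rng)
        assert rep.mean_sensitivity > 0.9
        assert rep.corrected_count >= rep.n_detected

    def test_estimate_bias_spec_orientation(self, bias_neuron_pair):
        trials, ns = bias_neuron_pair
        spec = estimate_bias_spec(trials, ns, "spatial")
        assert spec["rate_pref"] >= spec["rate_nonpref"]
        assert spec["n_pref"] + spec["n_nonpref"] > 0

    def test_estimated_fraction_inverts_detection_rate(self):
        # d = f*s + (1-f)*alpha with f=0.3, s=0.7, alpha=0.05 -> d=0.245
        assert estimated_bias_fraction(245, 1000, 0.7, 0.05) == \
            pytest.approx(0.3, abs=1e-6)
        assert estimated_bias_fraction(0, 100, 0.7) == 0.0


class TestErrorTrials:
    def test_zscores_standardized(self, rng):
        z = zscore_counts(rng.poisson(10, 200))
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0)

    def test_no_error_trials_skips(self, rng):
        cfg = replace(bd.dlpfc_config(n_blocks=2),
                      delay_pairs=((0.0, 4.0), (0.0, 8.0)))
        trials = bd.generate_session(cfg, rng)
        ns = bd.generate_spikes(trials, bd.NeuronSpec(), rng)
        out = error_trial_analysis([(trials, ns)])
        assert out["skipped"]

    def test_aligned_error_trials_elevated(self, rng):
        # strong bias-choice coupling: errors on immediate-immediate pairs
        # co-occur with large bias excursions the neuron also reports
        cfg = bd.dlpfc_config(n_blocks=10, bias_choice_weight=2.0)
        pairs = []
        for i in range(30):
            trials = bd.generate_session(cfg, rng)
            pref = "R" if rng.random() < 0.5 else "L"
            spec = bd.NeuronSpec(neuron_id=f"e{i}", preferred_label=pref,
                                 bias_gain=4.0)
            pairs.append((trials, bd.generate_spikes(trials, spec, rng)))
        out = error_trial_analysis(pairs)
        assert not out["skipped"]
        assert out["mean_z_error"] > out["mean_z_rest"]


class TestBehavioralControls:
    def test_iid_choices_show_no_serial_dependence(self, rng):
        cfg = bd.dlpfc_config(n_blocks=10, bias_choice_weight=0.0,
                              include_control_blocks=False)
        trials = bd.generate_session(cfg, rng)
        tab = serial_dependence(trials, max_lag=10, n_perm=400, rng=rng)
        assert len(tab) > 0
        assert (tab.p_bonferroni > 0.05).all()

    def test_markov_choices_flag_lag_one(self, rng):
        # hand-built UNDET session with P(repeat) = 0.8
        n = 300
        side = np.empty(n)
        side[0] = 1
        for i in range(1, n):
            side[i] = side[i - 1] if rng.random() < 0.8 else 1 - side[i - 1]
        trials = pd.DataFrame(dict(
            session_id="m", trial_index=np.arange(n), task="choice",
            d_small=0.0, d_large=2.0,
            large_on_right=(side == 1),          # so reward split stays even
            instructed_target="none", latent_bias=0.0,
            choice_side=np.where(side == 1, "R", "L"),
            choice_reward=rng.permutation(
                np.array(["small", "large"] * (n // 2))),
            valid=True, t_go=1.0))
        tab = serial_dependence(trials, max_lag=5, n_perm=400, rng=rng)
        lag1 = tab[tab.lag == 1]
        assert len(lag1) and lag1.p_bonferroni.iloc[0] < 0.05

    def test_preferred_split_printed_anchor(self):
        # 17 of 29 neurons preferring one side: one-sided exact binomial
        assert binomial_tail_p(17, 29, 0.5) == pytest.approx(0.23, abs=0.005)

    def test_controls_report_structure(self, small_session, rng):
        _, trials = small_session
        meta = pd.DataFrame(dict(
            neuron_id=["a", "b", "c", "d"],
            preferred_label=["L", "L", "R", "L"],
            hemisphere=["L", "R", "L", "R"]))
        out = behavioral_controls(trials, meta, max_lag=3, n_perm=200,
                                  rng=rng)
        assert {"serial", "preferred_split",
                "hemisphere_by_direction"} <= set(out)
        assert out["preferred_split"]["n_majority"] == 3
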