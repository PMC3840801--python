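"""Decoder tests: logistic fits, LOOCV, shuffle nulls, bias calls.

The LOOCV engine is checked fold by fold against an independent oracle
that maximizes the same binomial likelihood by brute-force grid search,
on small instances (n <= 12, counts in {0, 1, 2}).
"""

import numpy as np
import pytest
from scipy.special import expit

import biasdecode as bd
from biasdecode.decode import (BiasDecoder, SingleNeuronLogistic,
                               chance_distribution, classify_bias,
                               fit_binary_logistic, loocv_accuracy,
                               loocv_predictions, period_profile,
                               proportion_explained)


# ---------------------------------------------------------------------------
# independent oracle: grid-search likelihood maximization per LOOCV fold
# ---------------------------------------------------------------------------

def _grid_ml_predict(x_train, y_train, x_test):
    """Grid-search ML logistic prediction; None when the MLE is not finite
    (single-class or separated training data, where grid search pushes to
    the box edge and the boundary placement is not identifiable)."""
    x0, x1 = x_train[y_train == 0], x_train[y_train == 1]
    if len(x0) == 0 or len(x1) == 0:
        return None
    if x0.max() <= x1.min() or x1.max() <= x0.min():
        return None
    icpts = np.linspace(-12, 12, 481)
    slopes = np.linspace(-12, 12, 481)
    eta = icpts[:, None, None] + slopes[None, :, None] * x_train[None, None, :]
    p = expit(eta)
    eps = 1e-12
    ll = (y_train * np.log(p + eps)
          + (1 - y_train) * np.log(1 - p + eps)).sum(-1)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    p_test = expit(icpts[i] + slopes[j] * x_test)
    if abs(p_test - 0.5) < 0.01:
        return None  # knife-edge: grid resolution decides, skip the fold
    return p_test >= 0.5


def test_loocv_matches_grid_search_oracle():
    checked = 0
    for seed in range(12):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        x = rng.integers(0, 3, n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        pred = loocv_predictions(x, y)
        for i in range(n):
            expected = _grid_ml_predict(np.delete(x, i), np.delete(y, i),
                                        x[i])
            if expected is not None:
                assert bool(pred[i]) == expected, f"seed {seed} fold {i}"
                checked += 1
    assert checked > 20  # the instances must exercise non-degenerate folds


class TestFitBinaryLogistic:
    def test_single_class_predicts_that_class(self):
        fit = fit_binary_logistic([1, 2, 3], [1, 1, 1])
        assert fit.kind == "single_class"
        np.testing.assert_allclose(fit.predict_proba([0, 10]), 1.0)

    def test_complete_separation_midpoint_rule(self):
        x = np.array([0] * 10 + [10] * 10)
        y = np.array([0] * 10 + [1] * 10)
        fit = fit_binary_logistic(x, y)
        assert fit.kind == "separated"
        assert fit.predict_proba([4])[0] == 0.0
        assert fit.predict_proba([6])[0] == 1.0
        assert fit.predict_proba([5])[0] == 0.5   # midpoint -> class 1
        assert fit.predict([5])[0]

    def test_uninformative_counts_slope_near_zero(self, rng):
        x = rng.poisson(10, 4000).astype(float)
        y = (rng.random(4000) < 0.7).astype(float)
        fit = fit_binary_logistic(x, y)
        assert fit.kind == "ml"
        assert abs(fit.slope) < 0.05
        assert fit.predict_proba([10])[0] == pytest.approx(0.7, abs=0.05)

    def test_matches_sklearn_on_overlapping_data(self, rng):
        # independent cross-check against an (almost) unpenalized fit
        from sklearn.linear_model import LogisticRegression
        x = rng.poisson(8, 300).astype(float)
        y = (rng.random(300) < expit(0.4 * (x - 8))).astype(float)
        fit = fit_binary_logistic(x, y)
        sk = LogisticRegression(C=1e6, tol=1e-10).fit(x[:, None], y)
        assert fit.slope == pytest.approx(sk.coef_[0, 0], abs=1e-3)
        assert fit.intercept == pytest.approx(sk.intercept_[0], abs=1e-2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_binary_logistic([1, 2], [1])


class TestLoocvAccuracy:
    def test_perfect_separation(self):
        x = np.array([0] * 10 + [10] * 10)
        y = np.array([0.] * 10 + [1.] * 10)
        assert loocv_accuracy(x, y) == 1.0

    def test_single_class_majority_rule(self):
        assert loocv_accuracy([3, 4, 5, 6], [1, 1, 1, 1]) == 1.0

    def test_constant_counts_majority(self):
        y = np.array([1.] * 18 + [0.] * 12)
        assert loocv_accuracy(np.zeros(30), y) == pytest.approx(0.6)

    def test_constant_counts_balanced_loocv_flip(self):
        # held-out trial always belongs to the post-removal minority
        y = np.array([1.] * 10 + [0.] * 10)
        assert loocv_accuracy(np.zeros(20), y) == 0.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            loocv_accuracy([1, 2], [0, 1])


class TestChanceDistribution:
    def test_single_class_degenerate(self, rng):
        null, c = chance_distribution(np.arange(10.), np.ones(10), 200, rng)
        assert c == 1.0 and (null == 1.0).all()

    def test_imbalanced_labels_raise_chance(self, rng):
        x = rng.poisson(10, 60).astype(float)
        y = (rng.random(60) < 0.65).astype(float)
        _, c = chance_distribution(x, y, 400, rng)
        assert 0.5 < c < 0.75

    def test_seed_stability_of_null_mean(self, rng):
        x = rng.poisson(8, 40).astype(float)
        y = (rng.random(40) < 0.5).astype(float)
        n1, c1 = chance_distribution(x, y, 600, np.random.default_rng(1))
        n2, c2 = chance_distribution(x, y, 600, np.random.default_rng(2))
        se = n1.std() / np.sqrt(n1.size)
        assert abs(c1 - c2) < 3 * np.hypot(se, n2.std() / np.sqrt(n2.size))

    def test_minimum_shuffles_enforced(self):
        with pytest.raises(ValueError):
            chance_distribution([1, 2, 3], [0, 1, 0], 10)


class TestProportionExplained:
    def test_printed_worked_example(self):
        assert round(proportion_explained(0.75, 0.65), 2) == 0.29

    def test_zero_at_chance(self):
        assert proportion_explained(0.65, 0.65) == 0.0

    def test_perfect_prediction(self):
        assert proportion_explained(1.0, 0.5) == 1.0

    def test_negative_below_chance(self):
        assert proportion_explained(0.4, 0.5) < 0

    def test_degenerate_chance_rejected(self):
        with pytest.raises(ValueError):
            proportion_explained(0.9, 1.0)


class TestClassifyBias:
    def test_above_all_null(self):
        pct, call = classify_bias(0.99, np.full(500, 0.5))
        assert pct == 100.0 and call == "bias"

    def test_at_median(self):
        null = np.linspace(0.3, 0.7, 501)
        pct, call = classify_bias(0.5, null)
        assert abs(pct - 50) < 1 and call == "none"

    def test_below_all_null(self):
        pct, call = classify_bias(0.0, np.full(500, 0.5))
        assert pct == 0.0 and call == "anti_bias"


class TestEstimators:
    def test_single_neuron_logistic_sklearn_surface(self, rng):
        from sklearn.base import clone
        x = rng.poisson(10, 50)[:, None].astype(float)
        y = (rng.random(50) < 0.5).astype(int)
        est = SingleNeuronLogistic().fit(x, y)
        assert est.predict(x).shape == (50,)
        assert est.predict_proba(x).shape == (50, 2)
        clone(est)  # estimator params round-trip

    def test_bias_decoder_detects_strong_coupling(self, rng):
        # counts strongly tied to the label -> top-of-null call
        y = (rng.random(60) < 0.5).astype(float)
        x = rng.poisson(np.where(y == 1, 20, 5)).astype(float)
        dec = BiasDecoder(n_shuffles=400, random_state=3).fit(x, y)
        assert dec.call_ == "bias"
        assert dec.accuracy_ > dec.chance_
        assert dec.proportion_explained_ > 0.3
        assert dec.percentile_ > 95

    def test_bias_decoder_get_set_params(self):
        dec = BiasDecoder(n_shuffles=200)
        assert dec.get_params()["n_shuffles"] == 200
        dec.set_params(alpha=0.01)
        assert dec.alpha == 0.01


class TestPeriodProfile:
    def test_null_neurons_flat_profile_on_average(self, small_session, rng):
        # per-cell proportion explained is noisy at small trial counts;
        # averaged over null neurons it must sit at 0
        _, trials = small_session
        pes = []
        for i in range(6):
            ns = bd.generate_spikes(
                trials, bd.NeuronSpec(neuron_id=f"z{i}", bias_gain=0.0), rng)
            prof = period_profile(ns, trials, "spatial", n_shuffles=300,
                                  rng=rng)
            pes.extend(prof.proportion_explained.dropna())
        assert len(pes) >= 40
        assert abs(np.mean(pes)) < 0.06

    def test_small_cells_reported_missing(self, rng):
        cfg = bd.dlpfc_config(n_blocks=1)
        trials = bd.generate_session(cfg, rng)
        ns = bd.generate_spikes(trials, bd.NeuronSpec(), rng)
        prof = period_profile(ns, trials, "spatial", n_shuffles=300,
                              min_trials=10, rng=rng)
        assert (prof.call == "missing").any()

    def test_calls_restricted_to_pre_cue_undet(self, bias_neuron_pair, rng):
        trials, ns = bias_neuron_pair
        prof = period_profile(ns, trials, "spatial", n_shuffles=300, rng=rng)
        callable_cells = prof[(prof.window == "pre_cue")
                              & (prof.trial_type == "UNDET")]
        other = prof.drop(callable_cells.index)
        assert set(other.call) <= {"none", "missing"}
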