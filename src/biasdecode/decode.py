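"""Single-neuron choice decoding with shuffle-null chance levels.

The core procedure: predict the upcoming binary choice (left/right or
small/large reward) from a single pre-cue spike count per trial, using
binomial logistic regression in leave-one-out cross-validation (LOOCV).
Each neuron's chance level is the mean LOOCV accuracy over label
shuffles (default 10,000), which absorbs the animal's behavioral side
preference; predictive power above chance is summarized as the
*proportion explained* (a - c) / (1 - c), and neurons whose accuracy
ranks in the top 5% of their own null distribution are *bias neurons*.

Because the null requires B full LOOCV fits per neuron, fits are run on
count-aggregated data (one binomial cell per unique count) with a
batched 2-parameter Newton solver, vectorized over all (shuffle, fold)
problems at once.  Degenerate training sets are handled by explicit
rules rather than divergent coefficients:

* single-class labels -> always predict that class;
* all trials share one count -> intercept-only majority rule;
* complete separation -> step at the midpoint between the two classes'
  count ranges (probability 0.5 at the midpoint -> class 1);
* quasi-complete separation (classes share exactly one count value) ->
  step at the shared count, with the majority vote of that cell there.

Predicted probability >= 0.5 maps to class 1 (right / large reward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .preprocess import AnalysisWindows, TrialTypePartition, \
    partition_trials, window_counts, inclusion_filter

__all__ = [
    "LogisticFit",
    "SingleNeuronLogistic",
    "BiasDecoder",
    "fit_binary_logistic",
    "loocv_accuracy",
    "loocv_predictions",
    "chance_distribution",
    "proportion_explained",
    "classify_bias",
    "choice_labels",
    "period_profile",
    "decode_cohort",
]

_NEWTON_ITER = 60
_NEWTON_TOL = 1e-10
_STEP_CAP = 4.0


# ---------------------------------------------------------------------------
# batched LOOCV engine
# ---------------------------------------------------------------------------

def _fit_newton_batch(K, N, z):
    """ML logistic fit on binomial cells, batched over problems.

    K, N : (P, m) successes / totals per cell;  z : (m,) standardized
    count value of each cell.  Returns intercept and slope arrays (P,).
    Only called on problems whose MLE exists (no separation).
    """
    P = K.shape[0]
    a = np.zeros(P)
    b = np.zeros(P)
    active = np.ones(P, dtype=bool)
    for _ in range(_NEWTON_ITER):
        if not active.any():
            break
        eta = a[active, None] + b[active, None] * z[None, :]
        p = expit(eta)
        Na, Ka = N[active], K[active]
        r = Ka - Na * p
        w = Na * p * (1.0 - p)
        g0, g1 = r.sum(1), (r * z).sum(1)
        h00, h01 = w.sum(1), (w * z).sum(1)
        h11 = (w * z * z).sum(1)
        det = h00 * h11 - h01 * h01
        det = np.where(det > 1e-300, det, 1e-300)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        norm = np.hypot(da, db)
        scale = np.where(norm > _STEP_CAP,
                         _STEP_CAP / np.maximum(norm, 1e-300), 1.0)
        da *= scale
        db *= scale
        a[active] += da
        b[active] += db
        still = norm >= _NEWTON_TOL
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    return a, b


def _loocv_predict(counts, Y):
    """LOOCV class predictions for every label row.

    counts : (n,) integer spike counts;  Y : (B, n) 0/1 label matrix.
    Returns (B, n) boolean predictions, entry [b, i] being the class
    predicted for trial i after training on the other n-1 trials of
    label row b.
    """
    counts = np.asarray(counts, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    B, n = Y.shape
    if counts.shape[0] != n:
        raise ValueError("counts and labels length mismatch")
    if n < 3:
        raise ValueError("LOOCV needs at least 3 trials")

    u, inv = np.unique(counts, return_inverse=True)
    m = u.size
    sd = counts.std()
    z = (u - counts.mean()) / (sd if sd > 0 else 1.0)
    OH = np.zeros((n, m))
    OH[np.arange(n), inv] = 1.0
    N_full = OH.sum(0)                       # (m,)
    Np = N_full[None, :] - OH                # (n, m) fold-adjusted totals
    cells_per_fold = (Np > 0).sum(1)         # depends on the fold only
    x_held = counts                          # held-out raw count per fold

    pred = np.empty((B, n), dtype=bool)
    chunk = max(1, int(2_000_000 // max(n * m, 1)))
    for s in range(0, B, chunk):
        Yc = Y[s:s + chunk]
        Bc = Yc.shape[0]
        K_full = Yc @ OH                                     # (Bc, m)
        Kp = K_full[:, None, :] - OH[None, :, :] * Yc[:, :, None]
        total1 = K_full.sum(1)[:, None] - Yc                 # (Bc, n)
        N0 = Np[None, :, :] - Kp

        ones = Kp > 0.5
        zeros = N0 > 0.5
        big = np.inf
        lo1 = np.where(ones, u, big).min(-1)
        hi1 = np.where(ones, u, -big).max(-1)
        lo0 = np.where(zeros, u, big).min(-1)
        hi0 = np.where(zeros, u, -big).max(-1)

        out = np.empty((Bc, n), dtype=bool)
        done = np.zeros((Bc, n), dtype=bool)

        m1 = total1 >= n - 1.5               # all-ones training
        out[m1] = True
        done |= m1
        m0 = (total1 <= 0.5) & ~done         # all-zeros training
        out[m0] = False
        done |= m0

        mi = (cells_per_fold[None, :] == 1) & ~done     # intercept only
        if mi.any():
            p1 = total1 / (n - 1)
            out[mi] = p1[mi] >= 0.5
        done |= mi

        xh = np.broadcast_to(x_held[None, :], (Bc, n))
        mp = (hi0 <= lo1) & ~done            # positive-slope separation
        if mp.any():
            comp = mp & (hi0 < lo1)
            out[comp] = xh[comp] >= (hi0[comp] + lo1[comp]) / 2.0
            quasi = mp & (hi0 == lo1)
            if quasi.any():
                out[quasi] = _quasi_predict(xh, hi0, Kp, Np, u, quasi,
                                            positive=True)
            done |= mp
        mn = (hi1 <= lo0) & ~done            # negative-slope separation
        if mn.any():
            comp = mn & (hi1 < lo0)
            out[comp] = xh[comp] <= (hi1[comp] + lo0[comp]) / 2.0
            quasi = mn & (hi1 == lo0)
            if quasi.any():
                out[quasi] = _quasi_predict(xh, hi1, Kp, Np, u, quasi,
                                            positive=False)
            done |= mn

        rest = ~done                         # finite MLE -> Newton
        if rest.any():
            bi, fi = np.nonzero(rest)
            a_hat, b_hat = _fit_newton_batch(Kp[bi, fi], Np[fi], z)
            zh = (x_held[fi] - counts.mean()) / (sd if sd > 0 else 1.0)
            out[rest] = a_hat + b_hat * zh >= 0.0
        pred[s:s + chunk] = out
    return pred


def _quasi_predict(xh, v, Kp, Np, u, mask, positive):
    """Step-at-shared-count rule for quasi-complete separation."""
    bi, fi = np.nonzero(mask)
    vv = v[mask]
    jv = np.searchsorted(u, vv)
    frac = Kp[bi, fi, jv] / np.maximum(Np[fi, jv], 1.0)
    x = xh[mask]
    if positive:
        return np.where(x > vv, True, np.where(x < vv, False, frac >= 0.5))
    return np.where(x < vv, True, np.where(x > vv, False, frac >= 0.5))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def loocv_predictions(counts, labels) -> np.ndarray:
    """Fold-by-fold LOOCV class predictions (booleans)."""
    return _loocv_predict(counts, np.asarray(labels))[0]


def loocv_accuracy(counts, labels) -> float:
    """Fraction of trials whose choice the neuron's count predicts in LOOCV."""
    labels = np.asarray(labels, dtype=float)
    return float((_loocv_predict(counts, labels)[0] == labels).mean())


def chance_distribution(counts, labels, n_shuffles: int = 10_000,
                        rng=None):
    """Shuffle-null distribution of LOOCV accuracies.

    Each replicate permutes the labels across trials (preserving class
    counts) and recomputes the LOOCV accuracy.  Returns ``(null, c)``
    with ``c`` the null mean — the neuron's chance level, which tracks
    the animal's behavioral preference rather than sitting at 0.5.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a usable null")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = np.asarray(labels, dtype=float)
    n = labels.size
    perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
    Y = labels[perms]
    pred = _loocv_predict(counts, Y)
    null = (pred == Y).mean(axis=1)
    return null, float(null.mean())


def proportion_explained(a: float, c: float) -> float:
    """(a - c) / (1 - c): the above-chance share of residual predictability.

    Negative when the neuron predicts below its chance level; undefined
    at c = 1 (degenerate single-class behavior).
    """
    if c >= 1.0:
        raise ValueError("chance level c = 1: proportion explained undefined "
                         "(degenerate single-class session)")
    return (a - c) / (1.0 - c)


def classify_bias(a: float, null_accuracies, alpha: float = 0.05):
    """Percentile of the accuracy in its null, and the bias call.

    Mid-rank percentile over ties; ``bias`` when the accuracy sits at or
    above the (1 - alpha) mid-rank percentile of the null, ``anti_bias``
    at or below the alpha percentile, else ``none``.
    """
    null = np.asarray(null_accuracies, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    pct = 100.0 * ((null < a).sum() + 0.5 * (null == a).sum()) / null.size
    if pct >= 100.0 * (1 - alpha):
        call = "bias"
    elif pct <= 100.0 * alpha:
        call = "anti_bias"
    else:
        call = "none"
    return pct, call


# ---------------------------------------------------------------------------
# single fits (reference surface; the LOOCV engine inlines the same rules)
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """A fitted single-covariate logistic rule.

    ``kind`` records how the fit resolved: ``ml`` (finite MLE),
    ``single_class``, ``intercept_only``, or ``separated`` (step rule at
    ``threshold`` with direction ``orientation``).
    """

    intercept: float
    slope: float
    kind: str
    threshold: float | None = None
    orientation: int = 1
    p_const: float | None = None

    def predict_proba(self, counts) -> np.ndarray:
        x = np.asarray(counts, dtype=float)
        if self.kind in ("single_class", "intercept_only"):
            return np.full(x.shape, self.p_const, dtype=float)
        if self.kind == "separated":
            side = self.orientation * (x - self.threshold)
            return np.where(side > 0, 1.0, np.where(side < 0, 0.0, 0.5))
        return expit(self.intercept + self.slope * x)

    def predict(self, counts) -> np.ndarray:
        return self.predict_proba(counts) >= 0.5


def fit_binary_logistic(counts, labels) -> LogisticFit:
    """Maximum-likelihood logistic fit of P(class 1) on a spike count.

    Falls back to the documented degenerate rules on single-class input,
    constant counts, or (quasi-)complete separation instead of returning
    divergent coefficients.
    """
    x = np.asarray(counts, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("counts and labels length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 trials")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        p = float(y[0])
        return LogisticFit(np.inf * (2 * p - 1), 0.0, "single_class",
                           p_const=p)
    u = np.unique(x)
    if u.size == 1:
        p = float(y.mean())
        return LogisticFit(np.log(p / (1 - p)) if 0 < p < 1 else np.nan,
                           0.0, "intercept_only", p_const=p)
    hi0, lo0 = x[y == 0].max(), x[y == 0].min()
    hi1, lo1 = x[y == 1].max(), x[y == 1].min()
    if hi0 <= lo1:   # positive-slope separation
        t = (hi0 + lo1) / 2.0
        return LogisticFit(-np.inf, np.inf, "separated",
                           threshold=t, orientation=1)
    if hi1 <= lo0:   # negative-slope separation
        t = (hi1 + lo0) / 2.0
        return LogisticFit(np.inf, -np.inf, "separated",
                           threshold=t, orientation=-1)
    mu, sd = x.mean(), x.std()
    inv = np.searchsorted(u, x)
    K = np.bincount(inv, weights=y, minlength=u.size)[None, :]
    N = np.bincount(inv, minlength=u.size)[None, :].astype(float)
    z = (u - mu) / sd
    a, b = _fit_newton_batch(K, N, z)
    slope = float(b[0] / sd)
    return LogisticFit(float(a[0]) - slope * mu, slope, "ml")


class SingleNeuronLogistic(ClassifierMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`fit_binary_logistic`.

    X is an (n, 1) array of spike counts; y a binary choice label.
    Predicted probability >= 0.5 maps to the positive class.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("expected a single spike-count feature")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size > 2:
            raise ValueError("binary labels required")
        y01 = (y == self.classes_[-1]).astype(float)
        self.fit_ = fit_binary_logistic(X[:, 0], y01)
        self.intercept_ = np.array([self.fit_.intercept])
        self.coef_ = np.array([[self.fit_.slope]])
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[:, 0]
        p1 = self.fit_.predict_proba(X)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        pos = self.classes_[-1] if self.classes_.size > 1 else self.classes_[0]
        neg = self.classes_[0]
        return np.where(p >= 0.5, pos, neg)


class BiasDecoder(BaseEstimator):
    """Per-neuron bias screen: LOOCV accuracy vs. a shuffle null.

    Parameters
    ----------
    n_shuffles : int
        Label permutations for the null (10,000 in the full procedure;
        tests and scaled-down runs use less).
    alpha : float
        Tail mass for the bias / anti-bias call (default 0.05).
    store_null : bool
        Keep the full null vector on the fitted object (otherwise only
        its mean and the quantiles needed for the call are retained).
    random_state : int, Generator or None

    Fitted attributes: ``accuracy_``, ``chance_``, ``percentile_``,
    ``proportion_explained_``, ``call_``, ``null_quantiles_``.
    """

    def __init__(self, n_shuffles: int = 10_000, alpha: float = 0.05,
                 store_null: bool = False, random_state=None):
        self.n_shuffles = n_shuffles
        self.alpha = alpha
        self.store_null = store_null
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        counts = X[:, 0] if X.ndim == 2 else X
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("labels must be 0/1")
        rng = self.random_state if isinstance(
            self.random_state, np.random.Generator) \
            else np.random.default_rng(self.random_state)
        self.n_trials_ = counts.size
        self.accuracy_ = loocv_accuracy(counts, y)
        null, c = chance_distribution(counts, y, self.n_shuffles, rng)
        self.chance_ = c
        self.degenerate_ = c >= 1.0
        self.proportion_explained_ = (
            np.nan if self.degenerate_
            else proportion_explained(self.accuracy_, c))
        self.percentile_, self.call_ = classify_bias(
            self.accuracy_, null, self.alpha)
        qs = (0.05, 0.25, 0.5, 0.75, 0.95)
        self.null_quantiles_ = dict(zip(qs, np.quantile(null, qs)))
        if self.store_null:
            self.null_accuracies_ = null
        return self


# ---------------------------------------------------------------------------
# full per-neuron profile and cohort driver
# ---------------------------------------------------------------------------

def choice_labels(trials: pd.DataFrame, analysis: str) -> pd.Series:
    """Binary labels per trial: 1 = rightward saccade (spatial analysis)
    or large-reward choice (reward analysis)."""
    if analysis == "spatial":
        y = (trials.choice_side == "R").astype(float)
    elif analysis == "reward":
        y = (trials.choice_reward == "large").astype(float)
    else:
        raise ValueError(f"unknown analysis {analysis!r}")
    return pd.Series(y.to_numpy(), index=trials.trial_index.to_numpy())


def period_profile(neuron, trials: pd.DataFrame, analysis: str = "spatial",
                   partition: TrialTypePartition | None = None,
                   windows: AnalysisWindows = AnalysisWindows(),
                   n_shuffles: int = 10_000, min_trials: int = 5,
                   alpha: float = 0.05, rng=None,
                   which_windows=("pre_cue", "cue", "go")) -> pd.DataFrame:
    """Decode a neuron in every (analysis window x trial type) cell.

    One row per cell with accuracy, chance level, percentile and
    proportion explained.  The bias call is made only on the
    pre-cue x UNDET cell; all other cells are evaluation-only.  Cells
    with fewer than ``min_trials`` trials are reported with NaNs
    (mirroring sessions in which weakly-determined pairs are absent).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if partition is None:
        partition = partition_trials(trials)
    labels_all = choice_labels(trials, analysis)
    rows = []
    for window in which_windows:
        counts = window_counts(neuron, trials, window, windows)
        for ttype in ("UNDET", "WDET", "SDET", "NC"):
            idx = partition.trials_of_type(ttype)
            idx = np.intersect1d(idx, counts.index.to_numpy())
            row = dict(neuron_id=neuron.neuron_id, analysis=analysis,
                       window=window, trial_type=ttype, n_trials=len(idx),
                       accuracy=np.nan, chance=np.nan, percentile=np.nan,
                       proportion_explained=np.nan, call="missing")
            if len(idx) >= max(min_trials, 3):
                x = counts.loc[idx].to_numpy()
                y = labels_all.loc[idx].to_numpy()
                a = loocv_accuracy(x, y)
                null, c = chance_distribution(x, y, n_shuffles, rng)
                pct, call = classify_bias(a, null, alpha)
                row.update(accuracy=a, chance=c, percentile=pct,
                           proportion_explained=(
                               proportion_explained(a, c) if c < 1 else np.nan),
                           call=(call if (window == "pre_cue"
                                          and ttype == "UNDET") else "none"))
            rows.append(row)
    return pd.DataFrame(rows)


def decode_cohort(pairs, analysis: str = "spatial",
                  n_shuffles: int = 10_000, alpha: float = 0.05,
                  windows: AnalysisWindows = AnalysisWindows(),
                  rng=None, full_profile: bool = False) -> pd.DataFrame:
    """Run inclusion + pre-cue UNDET bias identification over a cohort.

    ``pairs`` is an iterable of ``(trials, neuron)`` tuples (one session
    per neuron, as recorded with a single electrode).  Returns a flat
    results table, one row per included neuron (or per profile cell when
    ``full_profile``); excluded neurons appear with ``included=False``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for trials, neuron in pairs:
        part = partition_trials(trials)
        ok, reasons = inclusion_filter(neuron, trials, analysis, part, windows)
        if not ok:
            rows.append(dict(neuron_id=neuron.neuron_id, analysis=analysis,
                             window="pre_cue", trial_type="UNDET",
                             included=False, reasons=";".join(reasons),
                             n_trials=0, accuracy=np.nan, chance=np.nan,
                             percentile=np.nan, proportion_explained=np.nan,
                             call="excluded"))
            continue
        if full_profile:
            prof = period_profile(neuron, trials, analysis, part, windows,
                                  n_shuffles, alpha=alpha, rng=rng)
            prof["included"] = True
            prof["reasons"] = ""
            rows.extend(prof.to_dict("records"))
        else:
            idx = np.intersect1d(part.trials_of_type("UNDET"),
                                 trials.loc[trials.valid,
                                            "trial_index"].to_numpy())
            counts = window_counts(neuron, trials, "pre_cue", windows)
            x = counts.loc[idx].to_numpy()
            y = choice_labels(trials, analysis).loc[idx].to_numpy()
            dec = BiasDecoder(n_shuffles=n_shuffles, alpha=alpha,
                              random_state=rng).fit(x, y)
            rows.append(dict(
                neuron_id=neuron.neuron_id, analysis=analysis,
                window="pre_cue", trial_type="UNDET", included=True,
                reasons="", n_trials=dec.n_trials_, accuracy=dec.accuracy_,
                chance=dec.chance_, percentile=dec.percentile_,
                proportion_explained=dec.proportion_explained_,
                call=dec.call_))
    return pd.DataFrame(rows)
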