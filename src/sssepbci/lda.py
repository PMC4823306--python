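"""Multi-class shrinkage LDA (one-vs-all), cross-validation, chance level,
and two-classifier fusion.

Covariance shrinkage follows the analytic Schafer-Strimmer estimator with
the diagonal-variance target: off-diagonal entries of the unbiased sample
covariance are damped by ``1 - lambda*`` where ``lambda*`` is estimated from
the sampling variance of the covariance entries and clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "shrinkage_covariance",
    "ShrinkageLDA",
    "CvResult",
    "cross_validate",
    "chance_level",
    "predict_proba_scores",
    "fuse_decisions",
    "concat_feature_sets",
]


def shrinkage_covariance(
    X: np.ndarray,
    assume_centered: bool = False,
    shrinkage: float | None = None,
) -> tuple[np.ndarray, float]:
    """Shrunk covariance of a samples x features matrix and the intensity used.

    The target is the diagonal of the unbiased sample covariance; the
    analytic optimal intensity is

        lambda* = sum_{i != j} Var(s_ij) / sum_{i != j} s_ij^2

    with ``Var(s_ij) = n / (n-1)^3 * sum_k (w_kij - mean_k w_kij)^2`` and
    ``w_kij = xc_ki * xc_kj`` the centered cross products, clipped to [0, 1].
    Pass ``shrinkage`` to override the analytic value (0 disables shrinkage,
    1 returns the diagonal target).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two samples")
    Xc = X if assume_centered else X - X.mean(axis=0)
    w_bar = Xc.T @ Xc / n
    S = w_bar * (n / (n - 1))
    if shrinkage is None:
        sq = Xc**2
        m2 = sq.T @ sq / n - w_bar**2  # mean_k (w - w_bar)^2
        var_s = m2 * (n**2 / (n - 1) ** 3)
        off = ~np.eye(p, dtype=bool)
        denom = float((S[off] ** 2).sum())
        lam = 1.0 if denom == 0.0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    else:
        lam = float(np.clip(shrinkage, 0.0, 1.0))
    shrunk = S.copy()
    shrunk[~np.eye(p, dtype=bool)] *= 1.0 - lam
    return shrunk, lam


@dataclass
class ShrinkageLDA:
    """One-vs-all linear discriminant classifier with covariance shrinkage.

    One binary discriminant per class separates it from the pooled rest; all
    discriminants share the pooled within-class covariance, shrunk toward its
    diagonal with the analytic intensity (``shrinkage`` overrides).  Linear
    scores are mapped to class probabilities by a softmax.
    """

    shrinkage: float | None = None
    classes_: np.ndarray = field(default=None, repr=False)
    coef_: np.ndarray = field(default=None, repr=False)
    intercept_: np.ndarray = field(default=None, repr=False)
    shrinkage_: float = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if (counts < 2).any():
            raise ValueError("every class needs at least two samples")
        means = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        residuals = X - means[np.searchsorted(self.classes_, y)]
        cov, self.shrinkage_ = shrinkage_covariance(
            residuals, assume_centered=True, shrinkage=self.shrinkage
        )
        n = len(y)
        coefs, intercepts = [], []
        for k, c in enumerate(self.classes_):
            mu_in = means[k]
            mask = y == c
            mu_out = X[~mask].mean(axis=0)
            w = np.linalg.solve(cov, mu_in - mu_out)
            prior = counts[k] / n
            b = -0.5 * w @ (mu_in + mu_out) + np.log(prior / (1 - prior))
            coefs.append(w)
            intercepts.append(b)
        self.coef_ = np.stack(coefs)
        self.intercept_ = np.asarray(intercepts)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("model is not fitted")
        return np.asarray(X, dtype=float) @ self.coef_.T + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba_scores(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def clone(self) -> "ShrinkageLDA":
        return ShrinkageLDA(shrinkage=self.shrinkage)


def predict_proba_scores(scores: np.ndarray) -> np.ndarray:
    """Softmax mapping of one-vs-all linear scores to class probabilities."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fuse_decisions(
    proba_a: np.ndarray,
    proba_b: np.ndarray,
    classes: np.ndarray,
    threshold: float = 0.5,
):
    """Fuse two classifiers' probability vectors into one decision.

    Each classifier contributes its most probable class; the classifier with
    the higher maximum probability wins if that probability reaches the
    threshold, otherwise no decision is made (returns ``None``).  Exact ties
    go to the first classifier.
    """
    proba_a = np.asarray(proba_a, dtype=float)
    proba_b = np.asarray(proba_b, dtype=float)
    ka, kb = int(np.argmax(proba_a)), int(np.argmax(proba_b))
    pa, pb = proba_a[ka], proba_b[kb]
    winner_class, winner_p = (classes[ka], pa) if pa >= pb else (classes[kb], pb)
    if winner_p < threshold:
        return None
    return winner_class


@dataclass
class CvResult:
    """Repeated stratified cross-validation outcome.

    ``accuracy`` is the mean over all repeat x fold test sets, in percent.
    """

    accuracy: float
    fold_accuracies: np.ndarray  # n_repeats x n_folds, percent
    confusion: pd.DataFrame
    classes: np.ndarray

    @property
    def repeat_accuracies(self) -> np.ndarray:
        return self.fold_accuracies.mean(axis=1)

    def summary(self) -> str:
        sd = self.repeat_accuracies.std(ddof=1) if len(self.fold_accuracies) > 1 else 0.0
        lines = [
            "Cross-validation result",
            f"  accuracy: {self.accuracy:.1f}% "
            f"(repeat SD {sd:.1f}%, {self.fold_accuracies.size} folds)",
            "  confusion matrix (rows: true, cols: predicted):",
        ]
        lines.extend("    " + row for row in self.confusion.to_string().splitlines())
        return "\n".join(lines)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 10,
    n_folds: int = 10,
    rng_seed: int | None = None,
    estimator: ShrinkageLDA | None = None,
) -> CvResult:
    """Repeated stratified k-fold cross-validation (default 10 x 10)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if (counts < n_folds).any():
        raise ValueError(
            f"every class needs at least n_folds={n_folds} samples for "
            "stratified folding"
        )
    estimator = estimator or ShrinkageLDA()
    root = np.random.SeedSequence(rng_seed)
    seeds = [int(np.random.default_rng(s).integers(2**31)) for s in root.spawn(n_repeats)]
    fold_acc = np.zeros((n_repeats, n_folds))
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    class_index = {c: i for i, c in enumerate(classes)}
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seeds[r])
        for f, (train, test) in enumerate(skf.split(X, y)):
            model = estimator.clone().fit(X[train], y[train])
            pred = model.predict(X[test])
            fold_acc[r, f] = 100.0 * np.mean(pred == y[test])
            for yt, yp in zip(y[test], pred):
                confusion[class_index[yt], class_index[yp]] += 1
    conf = pd.DataFrame(confusion, index=classes, columns=classes)
    return CvResult(float(fold_acc.mean()), fold_acc, conf, classes)


def chance_level(
    n_trials_total: int,
    n_classes: int = 3,
    alpha: float = 0.01,
) -> float:
    """Real chance level: the smallest accuracy (in percent) a random
    classifier exceeds with probability below ``alpha``.

    Computed from the exact binomial tail: the smallest k with
    ``P(Binomial(n, 1/n_classes) >= k) < alpha`` gives ``100 * k / n``.
    """
    if n_trials_total < 1:
        raise ValueError("n_trials_total must be at least 1")
    n = int(n_trials_total)
    p = 1.0 / n_classes
    # sf(k - 1) = P(X >= k)
    ks = np.arange(n + 1)
    tail = stats.binom.sf(ks - 1, n, p)
    ok = np.flatnonzero(tail < alpha)
    if ok.size == 0:
        raise ValueError(
            f"no accuracy threshold attainable at alpha={alpha} with n={n}"
        )
    return 100.0 * ks[ok[0]] / n


def concat_feature_sets(feature_sets, standardize: bool = True):
    """Concatenate feature groups (e.g. SSSEP + P300 + blocking) on the
    intersection of their trials, optionally z-scoring each feature column.

    Returns a combined FeatureSet; per-group feature counts stay unequal, so
    the combined classifier inherits the groups' relative feature shares.
    """
    from .lockin import FeatureSet

    common = feature_sets[0].trial_ids
    for fs in feature_sets[1:]:
        common = np.intersect1d(common, fs.trial_ids)
    blocks, names = [], []
    y = None
    for fs in feature_sets:
        idx = np.flatnonzero(np.isin(fs.trial_ids, common))
        Xb = fs.X[idx]
        if standardize:
            sd = Xb.std(axis=0)
            sd[sd == 0] = 1.0
            Xb = (Xb - Xb.mean(axis=0)) / sd
        blocks.append(Xb)
        names.extend(fs.feature_names)
        y = fs.y[idx]
    return FeatureSet(np.hstack(blocks), y, names, "combined", common)
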