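"""Bayesian multinomial speaker-group classifier.

A multinomial-logit model with Normal(0, 2.5) coefficient priors predicts,
from a fragment's fluency features (silence proportion, pause rate,
short/long pause counts, ...), which speaker group generated it.  By default
the maximum-a-posteriori estimate is used (equivalent to L2-regularised
multinomial logistic regression); a Laplace-approximate posterior over the
coefficients is available for uncertainty in the class probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class SpeakerGroupClassifier:
    """Fitted MAP multinomial-logit classifier.

    ``coef`` has shape ``(n_classes, n_features + 1)`` (bias first); the
    first class is the reference with all coefficients fixed at zero.
    Features are standardised internally with the stored training mean/SD.
    """

    classes: tuple
    coef: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    prior_scale: float

    def _design(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.feature_mean) / self.feature_sd
        return np.column_stack([np.ones(len(Z)), Z])

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probabilities; rows sum to 1."""
        return _softmax(self._design(X) @ self.coef.T)

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)
        return np.asarray(self.classes)[p.argmax(axis=1)]


def fit_group_classifier(
    features,
    groups,
    seed=None,
    prior_scale: float = 2.5,
) -> SpeakerGroupClassifier:
    """MAP fit of the multinomial-logit group classifier.

    ``features`` is an ``(n, p)`` array (or DataFrame) of fragment-level
    fluency features; ``groups`` the per-fragment group labels.  Coefficient
    priors are Normal(0, ``prior_scale``); the intercept and slope of the
    reference class are fixed at zero for identifiability.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(groups)
    classes = tuple(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = np.column_stack([np.ones(len(X)), (X - mean) / sd])
    yi = np.array([classes.index(c) for c in y])
    k, p1 = len(classes), Z.shape[1]
    Y = np.zeros((len(y), k))
    Y[np.arange(len(y)), yi] = 1.0

    def negpost(w_flat):
        W = np.zeros((k, p1))
        W[1:] = w_flat.reshape(k - 1, p1)
        P = _softmax(Z @ W.T)
        ll = float(np.sum(Y * np.log(P + 1e-300)))
        lp = ll - 0.5 * float(np.sum(W[1:] ** 2)) / prior_scale**2
        G = (P - Y).T @ Z  # (k, p1) gradient of -ll
        G[1:] += W[1:] / prior_scale**2
        return -lp, G[1:].ravel()

    w0 = np.zeros((k - 1) * p1)
    res = optimize.minimize(negpost, w0, jac=True, method="L-BFGS-B")
    W = np.zeros((k, p1))
    W[1:] = res.x.reshape(k - 1, p1)
    return SpeakerGroupClassifier(
        classes=classes,
        coef=W,
        feature_mean=mean,
        feature_sd=sd,
        prior_scale=prior_scale,
    )


def predict(classifier: SpeakerGroupClassifier, features) -> np.ndarray:
    """Per-class probabilities for new fragments."""
    return classifier.predict_proba(features)


def grouped_cv_accuracy(
    features, groups, speaker_ids, n_splits: int = 5, seed=None
) -> float:
    """Speaker-grouped cross-validated fragment classification accuracy.

    All fragments of one speaker land in the same fold, so accuracy reflects
    generalisation to unseen speakers rather than speaker re-identification.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(groups)
    spk = np.asarray(speaker_ids)
    uniq = pd.unique(spk)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    folds = [uniq[order[i::n_splits]] for i in range(n_splits)]
    correct = 0
    for fold in folds:
        test = np.isin(spk, fold)
        if test.all() or not test.any():
            continue
        clf = fit_group_classifier(X[~test], y[~test])
        correct += int((clf.predict(X[test]) == y[test]).sum())
    return correct / len(y)
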