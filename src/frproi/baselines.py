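"""Channel-space comparator classifiers: HDCA and xDAWN + BLDA.

Both operate directly on the filtered 64-channel fixation epochs and use
the same stratified cross-validation contract as the hierarchical
classifier, so their Az values are directly comparable.

HDCA: the causal part of each epoch is split into 8 equal temporal
windows; channel means per window are reduced by a per-window LDA to one
score, and a logistic regression combines the 8 window scores.

xDAWN + BLDA: spatial filters maximizing the evoked-to-total power
ratio are obtained from the generalized symmetric eigenproblem
Sigma_evoked a = rho Sigma_total a (evoked = mean target epoch estimated
on the training fold); epochs are projected onto the 8 most discriminant
unit-norm filters and classified with a Bayesian linear discriminant —
a ridge regression whose two hyperparameters are optimized by evidence
maximization (fixed-point iteration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import BayesianRidge, LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .classify import compute_az


@dataclass
class BaselineResult:
    method: str
    az: float
    scores: np.ndarray
    fold_assignment: np.ndarray


def _stratified_folds(labels: np.ndarray, k: int, seed: int):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return skf.split(np.zeros(labels.size), labels)


# ---------------------------------------------------------------------------
# HDCA


def _window_means(epochs: np.ndarray, causal: np.ndarray,
                  n_windows: int) -> np.ndarray:
    """(trials, channels, n_windows) channel means over equal causal blocks.

    Causal samples are truncated by at most n_windows - 1 samples so the
    blocks tile evenly.
    """
    data = epochs[:, :, causal]
    nt = data.shape[2]
    usable = (nt // n_windows) * n_windows
    data = data[:, :, :usable]
    return data.reshape(data.shape[0], data.shape[1], n_windows, -1).mean(axis=3)


def hdca_fit_predict(epochs: np.ndarray, times: np.ndarray,
                     labels: np.ndarray, n_windows: int = 8,
                     folds: int = 5, seed: int = 0) -> BaselineResult:
    """Windowed spatial LDA scores fused by (lightly penalized) logistic.

    Parameters
    ----------
    epochs : (n_trials, n_channels, n_times)
    times : epoch time axis (s); windows tile the causal (t > 0) part.
    """
    labels = np.asarray(labels, dtype=int)
    causal = times > 0
    W = _window_means(epochs, causal, n_windows)
    n = labels.size
    scores = np.full(n, np.nan)
    assign = np.full(n, -1)
    for fold, (tr, te) in enumerate(_stratified_folds(labels, folds, seed)):
        win_tr = np.empty((tr.size, n_windows))
        win_te = np.empty((te.size, n_windows))
        for w in range(n_windows):
            lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            lda.fit(W[tr, :, w], labels[tr])
            win_tr[:, w] = lda.decision_function(W[tr, :, w])
            win_te[:, w] = lda.decision_function(W[te, :, w])
        logit = LogisticRegression(C=1e6, max_iter=1000)
        logit.fit(win_tr, labels[tr])
        scores[te] = logit.decision_function(win_te)
        assign[te] = fold
    return BaselineResult(method="hdca", az=compute_az(scores, labels),
                          scores=scores, fold_assignment=assign)


# ---------------------------------------------------------------------------
# xDAWN + BLDA


def xdawn_filters(epochs: np.ndarray, labels: np.ndarray,
                  n_filters: int = 8,
                  shrinkage: float = 1e-6) -> np.ndarray:
    """Spatial filters from the evoked-vs-total generalized eigenproblem.

    Returns (n_filters, n_channels), unit-norm rows ordered by decreasing
    evoked-to-total power ratio; rows are orthogonal in the
    whitened (Sigma_total) metric.
    """
    labels = np.asarray(labels, dtype=int)
    evoked = epochs[labels == 1].mean(axis=0)          # (ch, nt)
    sigma_s = evoked @ evoked.T / evoked.shape[1]
    flat = epochs.transpose(1, 0, 2).reshape(epochs.shape[1], -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    sigma_x = flat @ flat.T / flat.shape[1]
    sigma_x += shrinkage * np.trace(sigma_x) / sigma_x.shape[0] * np.eye(
        sigma_x.shape[0])
    vals, vecs = eigh(sigma_s, sigma_x)
    order = np.argsort(vals)[::-1][:n_filters]
    filt = vecs[:, order].T
    return filt / np.linalg.norm(filt, axis=1, keepdims=True)


def xdawn_blda_fit_predict(epochs: np.ndarray, labels: np.ndarray,
                           n_filters: int = 8, folds: int = 5,
                           seed: int = 0) -> BaselineResult:
    """Project epochs onto the 8 most discriminant filters, classify with
    an evidence-framework Bayesian linear discriminant."""
    labels = np.asarray(labels, dtype=int)
    if epochs.shape[1] < n_filters:
        raise ValueError("need at least as many channels as filters")
    n = labels.size
    scores = np.full(n, np.nan)
    assign = np.full(n, -1)
    for fold, (tr, te) in enumerate(_stratified_folds(labels, folds, seed)):
        filt = xdawn_filters(epochs[tr], labels[tr], n_filters)
        feats = np.einsum("fc,tcn->tfn", filt, epochs).reshape(n, -1)
        blda = BayesianRidge(max_iter=100)
        blda.fit(feats[tr], labels[tr].astype(float))
        scores[te] = blda.predict(feats[te])
        assign[te] = fold
    return BaselineResult(method="xdawn_blda", az=compute_az(scores, labels),
                          scores=scores, fold_assignment=assign)
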