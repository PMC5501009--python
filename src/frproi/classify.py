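"""Hierarchical single-trial classification of fixation epochs.

Stage one fits a ridge regression per ROI on the flattened time-frequency
features (all epoch times, frequencies <= 32 Hz).  The ridge penalty is
not cross-validated: it is set by the effective-degrees-of-freedom rule

    df(lambda) = sum_j d_j^2 / (d_j^2 + lambda),

with d_j the singular values of the training matrix, solved so that
df equals the number of training targets (with the task's 10:1
non-target:target ratio this is the "1 target and 10 non-target
observations per degree of freedom" heuristic).  Stage two fuses the six
ROI regression outputs with linear discriminant analysis.  Both stages
are fit inside a single stratified 5-fold cross-validation; performance
is the area under the ROC curve (Az) of pooled held-out scores.

For interpretation, regression weights W are mapped to a forward model
A = Sigma_X W / var(s_hat) (Haufe-style), whose magnitude summed over
frequencies gives a temporal activation profile and its center-of-mass
latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold


# ---------------------------------------------------------------------------
# effective degrees of freedom and the penalty rule


def effective_df(X: np.ndarray, lam: float) -> float:
    """df(lambda) = sum d_j^2 / (d_j^2 + lambda) over singular values of X.

    ``X`` may be the data matrix or a 1-D vector of precomputed singular
    values.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X = np.asarray(X, dtype=float)
    d = X if X.ndim == 1 else np.linalg.svd(X, compute_uv=False)
    d2 = d**2
    if lam == 0:
        tol = d.max() * max(X.shape if X.ndim == 2 else d.shape) * np.finfo(float).eps
        return float(np.sum(d > tol))
    return float(np.sum(d2 / (d2 + lam)))


def select_lambda(X: np.ndarray, n_target: int, tol: float = 0.5,
                  max_iter: int = 200) -> float:
    """Solve df(lambda) = n_target by bisection on the monotone df curve.

    Returns 0 (with a warning) when the requested df exceeds the rank.
    """
    if n_target < 1:
        raise ValueError("need at least one target observation")
    X = np.asarray(X, dtype=float)
    d = X if X.ndim == 1 else np.linalg.svd(X, compute_uv=False)
    d2 = np.sort(d**2)[::-1]
    rank = int(np.sum(d2 > d2[0] * 1e-20)) if d2.size else 0
    if n_target >= rank:
        if n_target > rank:
            warnings.warn("requested df exceeds rank; using lambda = 0")
        return 0.0
    lo, hi = 1e-6 * d2[0], 1e6 * d2[0]

    def df(lam):
        return np.sum(d2 / (d2 + lam))

    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        val = df(mid)
        if abs(val - n_target) <= min(tol, 1e-6 * n_target + 1e-9):
            return float(mid)
        if val > n_target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


# ---------------------------------------------------------------------------
# ridge regression on standardized features


@dataclass
class RidgeModel:
    """Ridge fit on standardized features; score = z(x) @ coef + intercept."""

    coef: np.ndarray
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    lam: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Z @ self.coef + self.intercept


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    zero = scale == 0
    if np.any(zero):
        scale = np.where(zero, 1.0, scale)
    return (X - center) / scale, center, scale


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeModel:
    """W = (Z'Z + lambda I)^-1 Z' (y - mean y) on standardized Z.

    Uses the algebraically identical dual form Z'(ZZ' + lambda I)^-1 when
    features outnumber samples.  lambda = 0 on full-rank tall data
    reproduces ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if n < 2 or len(np.unique(y)) < 2:
        raise ValueError("need >= 2 samples with both classes")
    Z, center, scale = _standardize(X)
    yc = y - y.mean()
    if m <= n:
        A = Z.T @ Z + lam * np.eye(m)
        coef = np.linalg.lstsq(A, Z.T @ yc, rcond=None)[0]
    else:
        G = Z @ Z.T + lam * np.eye(n)
        alpha = np.linalg.lstsq(G, yc, rcond=None)[0]
        coef = Z.T @ alpha
    return RidgeModel(coef=coef, intercept=float(y.mean()),
                      center=center, scale=scale, lam=lam)


# ---------------------------------------------------------------------------
# Az


def compute_az(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based area under the ROC curve; tied scores count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(np.sum(labels == 1))
    n0 = int(np.sum(labels == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for Az")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# hierarchical cross-validation


@dataclass
class FoldModels:
    """Stage-one and stage-two fits of one CV fold."""

    ridges: list                    # one RidgeModel per ROI
    lda: LinearDiscriminantAnalysis
    lambdas: np.ndarray


@dataclass
class CVResult:
    """Pooled held-out scores and Az of the hierarchical scheme."""

    roi_names: tuple
    roi_az: np.ndarray              # per-ROI Az on pooled held-out scores
    hierarchical_az: float
    roi_scores: np.ndarray          # (n_trials, n_rois) held-out ridge output
    scores: np.ndarray              # (n_trials,) held-out LDA score
    fold_assignment: np.ndarray
    lambdas: np.ndarray             # (n_folds, n_rois)
    folds: list = field(default_factory=list)   # FoldModels per fold


def _fit_fold_ridge(Xtr: np.ndarray, ytr: np.ndarray,
                    n_target: int) -> RidgeModel:
    """Standardize, pick lambda from the df rule, solve in the dual."""
    Z, center, scale = _standardize(Xtr)
    G = Z @ Z.T
    evals, evecs = np.linalg.eigh(G)
    evals = np.clip(evals, 0.0, None)
    lam = select_lambda(np.sqrt(evals), n_target)
    yc = ytr - ytr.mean()
    denom = evals + lam
    denom[denom == 0] = np.inf
    alpha = evecs @ ((evecs.T @ yc) / denom)
    coef = Z.T @ alpha
    return RidgeModel(coef=coef, intercept=float(ytr.mean()),
                      center=center, scale=scale, lam=lam)


def cross_validate(
    roi_features: list[np.ndarray],
    labels: np.ndarray,
    roi_names: tuple | None = None,
    k: int = 5,
    seed: int = 0,
    equal_priors: bool = False,
) -> CVResult:
    """Fit both stages inside a single stratified k-fold scheme.

    Within each split: six ridge models are fit on the training trials
    (penalty from the df rule with the training target count), LDA is
    fit on their training-set resubstitution score vectors, and held-out
    trials are scored through both stages.  Az is computed on the pooled
    held-out scores.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    n_rois = len(roi_features)
    roi_names = roi_names or tuple(f"roi{j}" for j in range(n_rois))
    if np.sum(labels == 1) < k or np.sum(labels == 0) < k:
        raise ValueError("need at least k trials of each class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    roi_scores = np.full((n, n_rois), np.nan)
    lda_scores = np.full(n, np.nan)
    fold_assign = np.full(n, -1)
    lambdas = np.zeros((k, n_rois))
    folds = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(n), labels)):
        ytr = labels[tr]
        n_target = int(np.sum(ytr == 1))
        ridges, train_scores = [], np.empty((tr.size, n_rois))
        for j in range(n_rois):
            model = _fit_fold_ridge(roi_features[j][tr], ytr.astype(float),
                                    n_target)
            ridges.append(model)
            lambdas[fold, j] = model.lam
            train_scores[:, j] = model.predict(roi_features[j][tr])
            roi_scores[te, j] = model.predict(roi_features[j][te])
        priors = np.array([0.5, 0.5]) if equal_priors else None
        lda = LinearDiscriminantAnalysis(priors=priors)
        lda.fit(train_scores, ytr)
        lda_scores[te] = lda.decision_function(roi_scores[te])
        fold_assign[te] = fold
        folds.append(FoldModels(ridges=ridges, lda=lda,
                                lambdas=lambdas[fold].copy()))
    roi_az = np.array([compute_az(roi_scores[:, j], labels)
                       for j in range(n_rois)])
    return CVResult(roi_names=tuple(roi_names), roi_az=roi_az,
                    hierarchical_az=compute_az(lda_scores, labels),
                    roi_scores=roi_scores, scores=lda_scores,
                    fold_assignment=fold_assign, lambdas=lambdas, folds=folds)


# ---------------------------------------------------------------------------
# forward model


@dataclass
class ForwardModelMap:
    """Haufe-style activation pattern of one ROI's ridge model."""

    A: np.ndarray                 # feature-space pattern (same shape as W)
    marginal: np.ndarray          # activation magnitude over time
    times: np.ndarray
    center_of_mass: float         # s, over causal times


def forward_model(X: np.ndarray, W: np.ndarray, scores: np.ndarray,
                  feature_shape: tuple | None = None,
                  times: np.ndarray | None = None) -> ForwardModelMap:
    """A = Sigma_X W / var(s_hat); pattern, temporal marginal, latency.

    ``X`` is the (training) feature matrix the model was fit on (in the
    same standardized space as ``W``), ``scores`` the model's outputs on
    those trials.  When ``feature_shape`` = (n_freq, n_times) and
    ``times`` are given, the marginal over frequencies and the causal
    center-of-mass latency are computed.
    """
    X = np.asarray(X, dtype=float)
    scores = np.asarray(scores, dtype=float)
    v = scores.var(ddof=1)
    if v <= 0:
        raise ValueError("score variance is zero")
    Xc = X - X.mean(axis=0)
    A = (Xc.T @ (Xc @ W)) / ((X.shape[0] - 1) * v)
    marginal = np.array([])
    com = np.nan
    if feature_shape is not None and times is not None:
        grid = np.abs(A.reshape(feature_shape))
        marginal = grid.sum(axis=0)
        causal = times > 0
        m = marginal[causal]
        if m.sum() > 0:
            com = float(np.sum(times[causal] * m) / m.sum())
    return ForwardModelMap(A=A, marginal=marginal,
                           times=times if times is not None else np.array([]),
                           center_of_mass=com)
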