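"""Effective-df rule, ridge fits, Az, hierarchical CV, forward model."""

import numpy as np
import pytest

from frproi.classify import (compute_az, cross_validate, effective_df,
                             fit_ridge, forward_model, select_lambda)


class TestEffectiveDf:
    def test_identity_matrix(self):
        assert effective_df(np.eye(3), 0.0) == pytest.approx(3.0)
        assert effective_df(np.eye(3), 1.0) == pytest.approx(1.5)
        assert effective_df(np.eye(3), 1e12) < 1e-9

    def test_matches_trace_formula(self, rng):
        """Oracle: df = trace(X (X'X + lam I)^-1 X') computed directly."""
        for _ in range(10):
            X = rng.standard_normal((10, 4))
            lam = float(rng.uniform(0.01, 50.0))
            direct = np.trace(
                X @ np.linalg.inv(X.T @ X + lam * np.eye(4)) @ X.T)
            assert effective_df(X, lam) == pytest.approx(direct, abs=1e-8)

    def test_strictly_decreasing_with_rank_limits(self, rng):
        X = rng.standard_normal((12, 5))
        grid = np.logspace(-4, 6, 25)
        vals = [effective_df(X, l) for l in grid]
        assert np.all(np.diff(vals) < 0)
        assert effective_df(X, 0.0) == pytest.approx(np.linalg.matrix_rank(X))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            effective_df(np.eye(2), -1.0)


class TestSelectLambda:
    def test_identity_closed_form(self):
        """X = I10: df = 10/(1+lam), so df=5 at lam=1 exactly."""
        lam = select_lambda(np.eye(10), 5)
        assert lam == pytest.approx(1.0, rel=1e-3)

    def test_scale_law(self, rng):
        d = rng.uniform(0.5, 3.0, size=8)
        lam1 = select_lambda(d, 3)
        lam2 = select_lambda(2.0 * d, 3)
        assert lam2 == pytest.approx(4.0 * lam1, rel=1e-3)

    def test_df_over_rank_returns_zero(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.warns(UserWarning):
            assert select_lambda(X, 10) == 0.0

    def test_solution_hits_requested_df(self, rng):
        X = rng.standard_normal((40, 25))
        lam = select_lambda(X, 8)
        assert effective_df(X, lam) == pytest.approx(8.0, abs=0.5)


class TestRidge:
    def test_lambda_zero_equals_ols(self, rng):
        X = rng.standard_normal((50, 5))
        y = (rng.random(50) > 0.7).astype(float)
        model = fit_ridge(X, y, 0.0)
        Z = (X - X.mean(0)) / X.std(0)
        beta = np.linalg.lstsq(Z, y - y.mean(), rcond=None)[0]
        assert np.allclose(model.coef, beta, atol=1e-8)

    def test_large_lambda_shrinks_to_prior_mean(self, rng):
        X = rng.standard_normal((30, 4))
        y = (rng.random(30) > 0.5).astype(float)
        model = fit_ridge(X, y, 1e12)
        assert np.max(np.abs(model.coef)) < 1e-6
        assert np.allclose(model.predict(X), y.mean(), atol=1e-5)

    def test_dual_equals_primal(self, rng):
        """Wide problems solved in the Gram form match the direct solve."""
        X = rng.standard_normal((15, 40))
        y = (np.arange(15) % 3 == 0).astype(float)
        lam = 2.5
        model = fit_ridge(X, y, lam)
        Z = (X - X.mean(0)) / np.where(X.std(0) == 0, 1.0, X.std(0))
        direct = np.linalg.solve(Z.T @ Z + lam * np.eye(40),
                                 Z.T @ (y - y.mean()))
        assert np.allclose(model.coef, direct, atol=1e-8)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ridge(rng.standard_normal((10, 3)), np.zeros(10), 1.0)


class TestAz:
    def test_perfect_separation_and_ties(self):
        assert compute_az([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
        assert compute_az([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
        assert compute_az([10, 1, 2], [0, 1, 1]) == 0.0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 8, size=n).astype(float)  # force ties
            labels = (rng.random(n) > 0.6).astype(int)
            if labels.sum() in (0, n):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert compute_az(scores, labels) == pytest.approx(
                wins / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(40)
        labels = (rng.random(40) > 0.5).astype(int)
        assert compute_az(np.exp(scores), labels) == pytest.approx(
            compute_az(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_az([1.0, 2.0], [1, 1])


def _toy_roi_sets(rng, n=200, separability=(3.0, 0.0, 2.0), m=30):
    """Six ROI feature blocks; some carry a shifted informative feature."""
    labels = np.zeros(n, int)
    labels[rng.choice(n, n // 5, replace=False)] = 1
    sets = []
    seps = list(separability) + [0.0] * (6 - len(separability))
    for s in seps:
        X = rng.standard_normal((n, m))
        X[:, 0] += s * labels
        sets.append(X)
    return sets, labels


class TestCrossValidate:
    def test_null_labels_give_chance_az(self, rng):
        sets, labels = _toy_roi_sets(rng, separability=(0.0,))
        cv = cross_validate(sets, labels, seed=3)
        assert 0.35 < cv.hierarchical_az < 0.65

    def test_separable_problem_and_fusion_gain(self, rng):
        sets, labels = _toy_roi_sets(rng, separability=(3.0, 0.0, 2.0))
        cv = cross_validate(sets, labels, seed=3)
        assert cv.hierarchical_az > 0.95
        assert cv.hierarchical_az >= cv.roi_az.max() - 0.02
        assert cv.roi_az[0] > 0.9 and cv.roi_az[1] < 0.75

    def test_heldout_trials_do_not_shape_the_fit(self, rng):
        """Corrupting held-out features leaves fitted parameters unchanged."""
        sets, labels = _toy_roi_sets(rng)
        cv1 = cross_validate(sets, labels, seed=9)
        te0 = np.flatnonzero(cv1.fold_assignment == 0)
        corrupted = [X.copy() for X in sets]
        for X in corrupted:
            X[te0] += 1e3 * rng.standard_normal((te0.size, X.shape[1]))
        cv2 = cross_validate(corrupted, labels, seed=9)
        for r1, r2 in zip(cv2.folds[0].ridges, cv1.folds[0].ridges):
            assert np.allclose(r1.coef, r2.coef)
            assert r1.lam == r2.lam
        tr_mask = cv1.fold_assignment != 0
        # scores on other folds' training sides unaffected as well
        assert np.allclose(cv1.lambdas[0], cv2.lambdas[0])

    def test_lambda_follows_target_count(self, rng):
        sets, labels = _toy_roi_sets(rng)
        cv = cross_validate(sets, labels, seed=1)
        for fold in cv.folds:
            for model in fold.ridges:
                assert model.lam > 0


class TestForwardModel:
    def test_whitened_data_pattern_proportional_to_weights(self, rng):
        n = 20000
        X = rng.standard_normal((n, 6))
        W = rng.standard_normal(6)
        s = X @ W
        fm = forward_model(X, W, s)
        assert np.allclose(fm.A / np.linalg.norm(fm.A),
                           W / np.linalg.norm(W), atol=0.05)

    def test_correlated_noise_suppressed(self, rng):
        """A single informative feature dominates A even when W spreads
        over correlated pure-noise features (Haufe-style correction)."""
        n = 3000
        signal = rng.standard_normal(n)
        distractor = rng.standard_normal(n)
        X = np.column_stack([signal, distractor, -distractor])
        W = np.array([1.0, 5.0, 5.0])     # weights cancel on the noise pair
        s = X @ W                          # equals the signal
        fm = forward_model(X, W, s)
        assert abs(fm.A[0]) > 10 * abs(fm.A[1])
        assert abs(fm.A[0]) > 10 * abs(fm.A[2])

    def test_center_of_mass_latency(self, rng):
        """With iid features, A ~ W: weights concentrated at one causal
        time pin the center-of-mass there."""
        times = np.arange(-2, 6) / 4.0
        shape = (2, times.size)
        W = np.zeros(shape)
        W[:, times == 0.5] = 2.0
        W = W.ravel()
        X = rng.standard_normal((20000, W.size))
        s = X @ W
        fm = forward_model(X, W, s, feature_shape=shape, times=times)
        assert fm.center_of_mass == pytest.approx(0.5, abs=0.03)
        assert np.argmax(fm.marginal) == int(np.flatnonzero(times == 0.5)[0])

    def test_zero_score_variance_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            forward_model(X, np.zeros(3), np.zeros(10))
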