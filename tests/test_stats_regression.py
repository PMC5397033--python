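"""Associations, stepwise logistic selection, AUC and direction visualization."""

import numpy as np
import pytest

from bodysam.stats_regression import (LogisticModel, auc, bivariate_assoc,
                                      fit_logistic, match_by_bins,
                                      predict_prob,
                                      regression_direction_visualization,
                                      stepwise_logistic)


class TestBivariate:
    def test_identical_series_give_perfect_correlation(self, rng):
        x = rng.normal(size=50)
        r, p = bivariate_assoc(x, x.copy(), "continuous")
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-20

    def test_r_matches_covariance_oracle(self, rng):
        x = rng.normal(size=80)
        y = 0.4 * x + rng.normal(size=80)
        r, _ = bivariate_assoc(x, y, "continuous")
        oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1)
                                               * np.std(y, ddof=1))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_binary_association_detects_group_shift(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(2, 1, 100)])
        labels = np.repeat([0.0, 1.0], 100)
        beta, p = bivariate_assoc(scores, labels, "binary")
        assert beta > 0 and p < 1e-6

    def test_null_type_one_error_near_nominal(self, rng):
        # independent covariates reject at about the nominal 5% rate
        n_reps, n = 1000, 40
        hits = 0
        for _ in range(n_reps):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            _, p = bivariate_assoc(x, y, "continuous")
            hits += p <= 0.05
        # binomial 99.9% interval around 0.05 with 1000 reps
        assert 27 <= hits <= 76

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            bivariate_assoc(np.ones(10), np.arange(10.0), "continuous")


class TestLogisticFit:
    def test_matches_statsmodels_on_regular_data(self, rng):
        # independent oracle: same likelihood optimum as statsmodels Logit
        import statsmodels.api as sm_api

        x = rng.normal(size=(200, 3))
        eta = 0.5 + x @ np.array([1.0, -0.7, 0.0])
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        model, _ = fit_logistic(x, y, [0, 1, 2])
        ref = sm_api.Logit(y, sm_api.add_constant(x)).fit(disp=0)
        ours = np.array([model.intercept] + [model.coefficients[i]
                                             for i in range(3)])
        assert np.abs(ours - ref.params).max() < 1e-6

    def test_perfect_separation_flagged_and_capped(self):
        x = np.concatenate([-np.ones(20), np.ones(20)])[:, None]
        y = np.concatenate([np.zeros(20), np.ones(20)])
        model, _ = fit_logistic(x, y, [0])
        assert model.separation_flag
        assert abs(model.coefficients[0]) <= 25.0

    def test_balanced_labels_constant_score_give_zero_intercept(self):
        scores = np.ones((40, 1))
        y = np.repeat([0.0, 1.0], 20)
        model = stepwise_logistic(scores, y)
        assert model.coefficients == {}
        assert model.intercept == pytest.approx(0.0, abs=1e-8)


class TestStepwise:
    def test_recovers_true_modes(self, rng):
        # labels generated from 2 of 10 modes: both true modes are selected
        # in nearly every replicate (a false extra entry is possible at the
        # ~1-0.95^8 family rate of the nominal threshold and is tolerated)
        both = 0
        reps = 30
        for _ in range(reps):
            scores = rng.normal(size=(400, 10))
            eta = 1.2 * scores[:, 2] - 1.0 * scores[:, 7]
            y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
            model = stepwise_logistic(scores, y)
            both += {2, 7} <= set(model.coefficients)
        assert both >= int(0.9 * reps)

    def test_null_labels_usually_empty_never_error(self, rng):
        empty = 0
        reps = 40
        for _ in range(reps):
            scores = rng.normal(size=(200, 5))
            y = (rng.random(200) < 0.5).astype(float)
            model = stepwise_logistic(scores, y)
            empty += not model.coefficients
        # about (1 - 0.05)^5 ~ 77% of replicates keep the intercept only
        assert empty >= int(0.5 * reps)

    def test_deterministic_tie_break_prefers_lower_index(self, rng):
        scores = rng.normal(size=(300, 4))
        scores[:, 3] = scores[:, 0]  # duplicated candidate
        eta = 1.5 * scores[:, 0]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        model = stepwise_logistic(scores, y)
        assert 0 in model.coefficients and 3 not in model.coefficients

    def test_single_class_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            stepwise_logistic(rng.normal(size=(20, 2)), np.ones(20))


class TestPredictAUC:
    def test_inverse_logit_values(self):
        model = LogisticModel(0.0, {0: 1.0})
        scores = np.array([[0.0], [1.0], [30.0]])
        probs = predict_prob(model, scores)
        assert probs[0] == pytest.approx(0.5)
        assert probs[1] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)
        # monotone and bounded: alpha -> +inf drives the probability to 1
        assert probs[2] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(probs) > 0)
        assert np.all((probs > 0) & (probs < 1))

    def test_missing_mode_key_raises(self):
        model = LogisticModel(0.0, {5: 1.0})
        with pytest.raises(KeyError):
            model.alpha(np.zeros((3, 2)))

    def test_perfect_separation_gives_unit_auc(self):
        probs = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert auc(probs, labels) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.ones(10), np.repeat([0, 1], 5)) == 0.5

    def test_matches_brute_force_pairwise_oracle(self, rng):
        probs = rng.random(20)
        probs[5] = probs[10]  # include a tie
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        pos = probs[labels == 1]
        neg = probs[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert auc(probs, labels) == pytest.approx(oracle, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        probs = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        assert auc(probs, labels) == pytest.approx(
            roc_auc_score(labels, probs), abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        probs = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert auc(np.exp(3 * probs), labels) == auc(probs, labels)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.random.rand(5), np.zeros(5))


class TestDirectionVisualization:
    def test_intercept_only_model_is_zero_direction(self, appearance):
        with pytest.raises(ValueError, match="zero direction"):
            regression_direction_visualization(appearance,
                                               LogisticModel(0.3, {}))

    def test_zero_sd_gives_black_difference(self, appearance):
        model = LogisticModel(0.0, {0: 1.0})
        low, high, diff = regression_direction_visualization(appearance,
                                                             model, k_sd=0.0)
        assert diff.max() == 0

    def test_single_mode_model_matches_mode_visualization(self, appearance):
        from bodysam.appearance_model import mode_visualization

        model = LogisticModel(0.0, {1: -0.4})
        low, high, _ = regression_direction_visualization(appearance, model,
                                                          k_sd=2.0)
        minus, plus = mode_visualization(appearance, 1, k_sd=2.0)
        # direction is mode 1 up to the coefficient sign (negative here)
        assert np.allclose(low[0].coords, plus[0].coords, atol=1e-8)
        assert np.allclose(high[0].coords, minus[0].coords, atol=1e-8)


class TestMatching:
    def test_matched_controls_balance_covariate(self, rng):
        # cases skew high on the covariate; matched controls should too
        n = 600
        cov = rng.normal(0, 1, n)
        p_case = 1 / (1 + np.exp(-1.5 * cov))
        labels = rng.random(n) < p_case
        idx = match_by_bins(cov, labels, n_bins=8, rng=rng)
        sel_cov = cov[idx]
        sel_lab = labels[idx]
        gap = abs(sel_cov[sel_lab].mean() - sel_cov[~sel_lab].mean())
        assert gap < 0.25 * cov.std()
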