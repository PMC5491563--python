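"""Classifier tests: normalization, confidence, GMM vs closed-form oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from mpdceus import classify, confidence, confusion_metrics, fit_gmm, normalize


class TestNormalize:
    def test_percentile_convention(self):
        """Column 1..10 -> linear-interpolated 90th percentile 9.1."""
        x = np.arange(1.0, 11.0)[:, None]
        xn, scales = normalize(x)
        assert scales[0] == pytest.approx(9.1)
        assert xn.max() == pytest.approx(10 / 9.1)

    def test_constant_column(self):
        x = np.full((7, 1), 4.2)
        xn, _ = normalize(x)
        assert np.all(xn == 1.0)

    def test_training_scales_reused_not_recomputed(self):
        train = np.arange(1.0, 11.0)[:, None]
        _, scales = normalize(train)
        test = 1000.0 * np.arange(1.0, 6.0)[:, None]
        xn, out_scales = normalize(test, scales)
        assert np.array_equal(out_scales, scales)
        assert xn.max() == pytest.approx(5000 / 9.1)

    def test_nonpositive_percentile_names_feature(self):
        x = np.column_stack([np.arange(1.0, 11.0), np.zeros(10)])
        with pytest.raises(ValueError, match="bad_col"):
            normalize(x, feature_names=["good", "bad_col"])


class TestConfidence:
    @pytest.mark.parametrize(
        "pa,pb,expected", [(0.75, 0.25, 0.5), (0.4, 0.4, 0.0), (1.0, 0.0, 1.0)]
    )
    def test_reference_values(self, pa, pb, expected):
        assert confidence(pa, pb) == pytest.approx(expected)

    @given(
        pmax=st.floats(1e-6, 1.0),
        ratio=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_bounds_and_antitone_in_ratio(self, pmax, ratio):
        """P lies in [0, 1] and decreases as min/max probability ratio grows."""
        p = confidence(pmax, ratio * pmax)
        assert 0.0 <= p <= 1.0
        p_worse = confidence(pmax, min(1.0, (ratio + 0.1)) * pmax)
        if ratio + 0.1 <= 1.0:
            assert p_worse <= p + 1e-12


class TestGmmOracle:
    def _train(self, seed=0, n=400, d=2):
        rng = np.random.default_rng(seed)
        x0 = rng.multivariate_normal([2.0, 3.0][:d], np.array([[1.0, 0.3], [0.3, 0.8]])[:d, :d], n)
        x1 = rng.multivariate_normal([4.0, 4.5][:d], np.array([[0.7, -0.2], [-0.2, 1.2]])[:d, :d], n)
        x = np.abs(np.vstack([x0, x1])) + 0.1
        y = np.repeat([0, 1], n)
        return x, y

    def test_single_component_matches_quadratic_discriminant(self):
        """Posteriors of the 1-component-per-class mixture equal the
        closed-form two-Gaussian discriminant to 1e-9 on a dense grid."""
        x, y = self._train()
        model = fit_gmm(x, y, n_components=1, reg_covar=1e-6)
        xn = x / model.scales
        # independent oracle: exact MLE mean/covariance + the same ridge
        dists = {}
        for cls in (0, 1):
            xc = xn[y == cls]
            cov = np.cov(xc, rowvar=False, bias=True) + 1e-6 * np.eye(x.shape[1])
            dists[cls] = multivariate_normal(xc.mean(axis=0), cov)
        g = np.linspace(0.05, 8.0, 40)
        grid = np.array([[a, b] for a in g for b in g])
        res = classify(model, grid * model.scales)
        logd = np.column_stack([dists[0].logpdf(grid), dists[1].logpdf(grid)])
        post1 = np.exp(logd[:, 1] - logsumexp(logd, axis=1))
        assert np.max(np.abs(res.p_malignant - post1)) < 1e-9

    def test_separable_clouds_perfect_training_accuracy(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(1, 0.1, (50, 2)), rng.normal(10, 0.1, (50, 2))])
        y = np.repeat([0, 1], 50)
        model = fit_gmm(x, y)
        assert np.array_equal(classify(model, x).labels, y)

    def test_label_swap_inverts_predictions(self):
        x, y = self._train(seed=2)
        res_a = classify(fit_gmm(x, y), x)
        res_b = classify(fit_gmm(x, 1 - y), x)
        assert np.array_equal(res_a.labels, 1 - res_b.labels)
        assert np.allclose(res_a.confidence, res_b.confidence, atol=1e-12)

    def test_both_classes_required(self):
        with pytest.raises(ValueError):
            fit_gmm(np.ones((5, 2)), np.zeros(5))


class TestConfusionMetrics:
    def test_reference_table(self):
        """TP=8, FN=2, TN=7, FP=3."""
        pred = np.array([1] * 8 + [0] * 2 + [0] * 7 + [1] * 3)
        truth = np.array([1] * 10 + [0] * 10)
        row = confusion_metrics(pred, truth)
        assert row.sensitivity == pytest.approx(80.0)
        assert row.specificity == pytest.approx(70.0)
        assert row.accuracy == pytest.approx(75.0)
        assert row.ppv == pytest.approx(72.7, abs=0.05)
        assert row.npv == pytest.approx(77.8, abs=0.05)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 0, 1, 1])
        row = confusion_metrics(truth, truth)
        assert (row.accuracy, row.sensitivity, row.specificity, row.ppv, row.npv) == (
            100.0, 100.0, 100.0, 100.0, 100.0,
        )

    def test_degenerate_all_malignant(self):
        truth = np.array([0, 0, 1, 1])
        row = confusion_metrics(np.ones(4, dtype=int), truth)
        assert row.sensitivity == 100.0
        assert row.specificity == 0.0
        assert np.isnan(row.npv)  # undefined, never zero

    def test_accuracy_identity(self):
        """accuracy = (sens*N_mal + spec*N_ben) / N on any confusion table."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            truth = rng.integers(0, 2, 50)
            if len(np.unique(truth)) < 2:
                continue
            pred = rng.integers(0, 2, 50)
            row = confusion_metrics(pred, truth)
            n_mal = truth.sum()
            n_ben = 50 - n_mal
            assert row.accuracy == pytest.approx(
                (row.sensitivity * n_mal + row.specificity * n_ben) / 50
            )
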