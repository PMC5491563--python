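"""Grouped cross-validation, subset search, and exclusion-sweep tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mpdceus import (
    classify,
    evaluate_loo,
    exclusion_sweep,
    fit_gmm,
    normalize,
    permutation_null_accuracy,
    subset_search,
)
from mpdceus.dataset import PixelDataset

from conftest import make_gaussian_dataset


class TestEvaluateLoo:
    def test_identical_separable_prostates(self):
        ds = make_gaussian_dataset(n_prostates=2, separation=12.0, prostate_sd=0.0, seed=1)
        res = evaluate_loo(ds, ds.feature_names)
        assert res.mean["accuracy"] == pytest.approx(100.0)
        assert res.sd["accuracy"] == pytest.approx(0.0)

    def test_row_order_invariance(self, gaussian_dataset):
        ds = gaussian_dataset
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds))
        shuffled = PixelDataset(
            features=ds.features.iloc[perm].reset_index(drop=True),
            labels=ds.labels[perm],
            prostate_id=ds.prostate_id[perm],
            plane_id=ds.plane_id[perm],
            roi_id=ds.roi_id[perm],
            aux=ds.aux.iloc[perm].reset_index(drop=True),
        )
        a = evaluate_loo(ds, ds.feature_names)
        b = evaluate_loo(shuffled, ds.feature_names)
        pd.testing.assert_frame_equal(a.per_prostate, b.per_prostate)

    def test_no_leakage_into_normalization_or_training(self, gaussian_dataset):
        """The held-out fold equals a manual train-only fit + classify."""
        ds = gaussian_dataset
        res = evaluate_loo(ds, ds.feature_names)
        held = 0
        test = ds.included & (ds.prostate_id == held)
        train = ds.included & (ds.prostate_id != held)
        x = ds.features.to_numpy()
        model = fit_gmm(x[train], ds.labels[train], feature_names=ds.feature_names)
        manual = classify(model, x[test])
        assert np.array_equal(res.pixel_pred[test], manual.labels)
        assert np.allclose(res.pixel_confidence[test], manual.confidence)
        # and the scales really are train-only percentiles
        _, train_scales = normalize(x[train])
        assert np.allclose(model.scales, train_scales)

    def test_above_chance_on_separated_cohort(self, gaussian_dataset):
        res = evaluate_loo(gaussian_dataset, gaussian_dataset.feature_names)
        null = permutation_null_accuracy(gaussian_dataset, gaussian_dataset.feature_names, seed=5)
        assert res.mean["accuracy"] - null > 30.0

    def test_two_prostates_required(self):
        ds = make_gaussian_dataset(n_prostates=1)
        with pytest.raises(ValueError):
            evaluate_loo(ds, ds.feature_names)


class TestSubsetSearch:
    def test_counts_match_combinatorial_oracle(self):
        ds = make_gaussian_dataset(n_features=5, n_per_class=30)
        table = subset_search(ds, max_size=3)
        expected = sum(
            1 for k in (1, 2, 3) for _ in itertools.combinations(range(5), k)
        )
        assert len(table) == expected == 25
        assert set(table["rank_accuracy"]) == set(range(1, 26))

    def test_single_feature_dataset(self):
        ds = make_gaussian_dataset(n_features=1)
        assert len(subset_search(ds, max_size=4)) == 1

    def test_duplicated_feature_is_redundant(self):
        """A subset {a, a_copy} scores like {a}: no information is added."""
        ds = make_gaussian_dataset(n_features=1, feature_names=["a"], seed=3)
        dup = ds.features.copy()
        dup["a_copy"] = dup["a"]
        ds2 = PixelDataset(
            features=dup, labels=ds.labels, prostate_id=ds.prostate_id,
            plane_id=ds.plane_id, roi_id=ds.roi_id, aux=ds.aux,
        )
        single = evaluate_loo(ds2, ("a",)).mean["accuracy"]
        pair = evaluate_loo(ds2, ("a", "a_copy")).mean["accuracy"]
        assert pair == pytest.approx(single, abs=0.5)

    def test_deterministic(self, gaussian_dataset):
        a = subset_search(gaussian_dataset, max_size=2)
        b = subset_search(gaussian_dataset, max_size=2)
        pd.testing.assert_frame_equal(a, b)


class TestExclusionSweep:
    @pytest.fixture()
    def loo_with_unfittable(self):
        ds = make_gaussian_dataset(separation=1.5, seed=7)
        # mark a block of rows unfittable: they must stay excluded throughout
        ds.aux.loc[: len(ds) // 10, "fittable"] = False
        res = evaluate_loo(ds, ds.feature_names)
        return ds, res

    def test_threshold_zero_retains_fittable_only(self, loo_with_unfittable):
        ds, res = loo_with_unfittable
        curve = exclusion_sweep(res, ds, "confidence", [0.0])
        assert curve.retained_fraction[0] == pytest.approx(ds.included.mean())

    def test_threshold_one_retains_only_certain_pixels(self, loo_with_unfittable):
        ds, res = loo_with_unfittable
        curve = exclusion_sweep(res, ds, "confidence", [1.0])
        n_certain = np.sum(ds.included & (res.pixel_confidence >= 1.0))
        assert curve.n_retained[0] == n_certain

    def test_retained_fraction_non_increasing(self, loo_with_unfittable):
        ds, res = loo_with_unfittable
        for measure in ("confidence", "r_squared", "absolute_probability"):
            curve = exclusion_sweep(res, ds, measure)
            assert np.all(np.diff(curve.retained_fraction) <= 1e-12)

    def test_empty_threshold_flags_undefined(self, loo_with_unfittable):
        ds, res = loo_with_unfittable
        curve = exclusion_sweep(res, ds, "confidence", [2.0])
        assert curve.n_retained[0] == 0
        assert np.isnan(curve.metrics["accuracy"][0])

    def test_peak_time_excludes_lowest_per_plane(self, loo_with_unfittable):
        ds, res = loo_with_unfittable
        curve = exclusion_sweep(res, ds, "peak_time", [0.0, 0.3])
        assert curve.retained_fraction[1] < curve.retained_fraction[0]
        # the excluded pixels are the lowest-PT ones within each plane
        pt = ds.aux["peak_time"].to_numpy()
        keep = ds.included & (pt >= np.quantile(pt[ds.included], 0.3))
        # same count within per-plane quantile granularity
        assert abs(curve.n_retained[1] - keep.sum()) <= 0.05 * len(ds)

    def test_unknown_measure(self, loo_with_unfittable):
        ds, res = loo_with_unfittable
        with pytest.raises(ValueError):
            exclusion_sweep(res, ds, "nonsense")
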