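import numpy as np
import pandas as pd
import pytest

from sonodense import evaluation, syndata
from sonodense.evaluation import (CVConfig, UndefinedMetricError, mse,
                                  partition_folds, r_squared, repeated_cv,
                                  spearman_profile, holdout_illustration)
from sonodense.models import ModelSpec


class TestMetrics:
    def test_mse_perfect(self):
        assert mse([0.2, 0.4], [0.2, 0.4]) == 0.0

    def test_mse_hand_computed(self):
        assert mse([0.0, 1.0], [1.0, 0.0]) == 1.0

    def test_mse_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(1000), rng.random(1000)
        naive = sum((x - y) ** 2 for x, y in zip(a, b)) / 1000
        assert abs(mse(a, b) - naive) < 1e-12

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            mse([1.0], [1.0, 2.0])

    def test_r2_perfect(self):
        assert r_squared([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == 1.0

    def test_r2_zero_for_mean_prediction(self):
        y = np.array([0.2, 0.4, 0.9])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_r2_negative_for_anticorrelated(self):
        # MSE 1.0 against variance 0.25 -> 1 - 4 = -3
        assert r_squared([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(-3.0)

    def test_r2_zero_variance_raises(self):
        with pytest.raises(UndefinedMetricError):
            r_squared([0.5, 0.5], [0.4, 0.6])


class TestPartition:
    def test_each_observation_in_exactly_one_fold(self):
        rng = np.random.default_rng(0)
        for n, k in [(168, 3), (40, 3), (30, 5), (9, 3)]:
            folds = partition_folds(n, k, rng)
            joined = np.concatenate(folds)
            assert sorted(joined) == list(range(n))
            sizes = [len(f) for f in folds]
            assert max(sizes) - min(sizes) <= 1

    def test_too_many_folds_raises(self):
        with pytest.raises(ValueError):
            partition_folds(2, 3, np.random.default_rng(0))


def _linear_table(n=90, seed=0, noise=0.05):
    X, y = syndata.linear_signal_cohort(n, 0.99, np.random.default_rng(seed))
    return X, y


class TestRepeatedCV:
    def test_null_model_cv_r2_is_negative(self):
        # the training mean degrades out of fold (Jensen-type pessimism)
        neg = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = rng.uniform(0, 1, 60)
            X = rng.standard_normal((60, 15))
            rep = repeated_cv((X, y), [ModelSpec("M0")],
                              CVConfig(repeats=1, folds=3, seed=seed))
            row = rep.summary.iloc[0]
            assert row.apparent_r2 == 0.0
            neg += row.cv_r2 <= 0.0
        assert neg == 50

    def test_every_record_triple_present_once(self):
        X, y = _linear_table()
        rep = repeated_cv((X, y), [ModelSpec("M0"), ModelSpec("M1")],
                          CVConfig(repeats=4, folds=3, seed=1))
        counts = rep.records.groupby(["repeat", "fold", "model_id"]).size()
        assert (counts == 1).all()
        assert len(rep.records) == 4 * 3 * 2

    def test_recovery_of_constructed_linear_signal(self):
        # generative oracle: population R^2 = 0.5 by construction
        vals = []
        for seed in range(5):
            X, y = syndata.linear_signal_cohort(500, 0.5, np.random.default_rng(seed))
            rep = repeated_cv((X, y), [ModelSpec("M1")],
                              CVConfig(repeats=5, folds=3, seed=seed))
            vals.append(rep.summary.cv_r2.iloc[0])
        assert abs(np.mean(vals) - 0.5) < 0.1

    def test_metric_consistency_ranking(self):
        # lower cv MSE <=> higher cv R^2 on identical partitions
        X, y = _linear_table(n=120, seed=3)
        specs = [ModelSpec(m) for m in ("M0", "M1", "M6")]
        rep = repeated_cv((X, y), specs, CVConfig(repeats=3, folds=3, seed=2))
        by_mse = rep.summary.sort_values("cv_mse")["model_id"].tolist()
        by_r2 = rep.summary.sort_values("cv_r2", ascending=False)["model_id"].tolist()
        assert by_mse == by_r2

    def test_final_model_has_smallest_cv_mse(self):
        X, y = _linear_table(n=100, seed=4)
        rep = repeated_cv((X, y), [ModelSpec("M0"), ModelSpec("M1")],
                          CVConfig(repeats=2, folds=3, seed=0))
        assert rep.final_model == rep.summary.loc[rep.summary.cv_mse.idxmin(),
                                                  "model_id"]

    def test_pooled_aggregation_close_to_fold_local(self):
        X, y = _linear_table(n=120, seed=5)
        rep_local = repeated_cv((X, y), [ModelSpec("M1")],
                                CVConfig(repeats=3, folds=3, seed=1))
        rep_pooled = repeated_cv((X, y), [ModelSpec("M1")],
                                 CVConfig(repeats=3, folds=3, seed=1,
                                          aggregation="pooled"))
        assert rep_pooled.summary.cv_mse.iloc[0] == pytest.approx(
            rep_local.summary.cv_mse.iloc[0], rel=0.05)

    def test_label_permutation_destroys_signal(self):
        X, y = syndata.linear_signal_cohort(150, 0.6, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        r2s = []
        for _ in range(10):
            y_perm = rng.permutation(y)
            rep = repeated_cv((X, y_perm), [ModelSpec("M1")],
                              CVConfig(repeats=1, folds=3, seed=0))
            r2s.append(rep.summary.cv_r2.iloc[0])
        assert np.mean(r2s) <= 0.05

    def test_fold_too_small_raises(self):
        X, y = _linear_table(n=4)
        with pytest.raises(ValueError):
            repeated_cv((X, y), [ModelSpec("M0")], CVConfig(repeats=1, folds=3))


class TestSpearmanProfile:
    def test_monotone_increasing_bin(self):
        y = np.linspace(0.1, 0.9, 30)
        X = np.column_stack([y**3] + [np.random.default_rng(0).random(30)
                                      for _ in range(14)])
        prof = spearman_profile(X, y)
        assert prof.spearman_rho.iloc[0] == pytest.approx(1.0)

    def test_monotone_decreasing_bin(self):
        y = np.linspace(0.1, 0.9, 30)
        X = np.column_stack([-y] + [np.zeros(30) + 0.5 for _ in range(14)])
        prof = spearman_profile(X, y)
        assert prof.spearman_rho.iloc[0] == pytest.approx(-1.0)

    def test_constant_bin_flagged_not_dropped(self):
        y = np.linspace(0, 1, 20)
        X = np.column_stack([y, np.full(20, 0.3)])
        prof = spearman_profile(X, y)
        assert len(prof) == 2
        assert np.isnan(prof.spearman_rho.iloc[1])

    def test_matches_rank_transform_oracle(self):
        from scipy.stats import rankdata
        rng = np.random.default_rng(8)
        X = rng.random((50, 15))
        y = rng.random(50)
        prof = spearman_profile(X, y)
        for j in range(15):
            rx, ry = rankdata(X[:, j]), rankdata(y)
            pearson_of_ranks = np.corrcoef(rx, ry)[0, 1]
            assert prof.spearman_rho.iloc[j] == pytest.approx(pearson_of_ranks,
                                                              abs=1e-10)

    def test_both_bin_labelings_reported(self):
        rng = np.random.default_rng(9)
        prof = spearman_profile(rng.random((30, 15)), rng.random(30))
        assert (prof.bin_white_ordered + prof.bin_black_ordered == 17).all()


class TestHoldout:
    def test_deterministic_given_seed(self):
        X, y = _linear_table(n=90, seed=0)
        t1, r1 = holdout_illustration((X, y), ModelSpec("M1"), seed=5)
        t2, r2 = holdout_illustration((X, y), ModelSpec("M1"), seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        assert r1 == r2

    def test_split_proportions(self):
        X, y = _linear_table(n=90, seed=1)
        table, _ = holdout_illustration((X, y), ModelSpec("M0"), seed=0)
        assert len(table) == 30  # one third held out

    def test_noiseless_linear_truth_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((90, 15))
        y = 0.3 + X @ rng.standard_normal(15)
        _, r2 = holdout_illustration((X, y), ModelSpec("M1"), seed=1)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_moderate_signal_recovery(self):
        # oracle out-of-sample R^2 is 0.3 by construction
        r2s = []
        for seed in range(20):
            X, y = syndata.linear_signal_cohort(504, 0.3, np.random.default_rng(seed))
            _, r2 = holdout_illustration((X, y), ModelSpec("M1"), seed=seed)
            r2s.append(r2)
        assert abs(np.mean(r2s) - 0.3) < 0.15
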