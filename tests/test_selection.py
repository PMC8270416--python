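"""Fold plans, tuning, nested CV, metrics, and the randomization test."""

import warnings

import numpy as np
import pytest

from tractsgl import (
    CVConfig,
    SearchSpace,
    SyntheticProfileSpec,
    compute_metrics,
    generate_profiles,
    make_fold_plan,
    matrix_from_dataset,
    nested_cv,
    randomization_test,
    tune_by_ebic,
    tune_hyperparams,
)
from tractsgl.errors import ConfigError, StratificationError
from tractsgl.selection import _fit_pipeline

TINY_SPACE = SearchSpace(alpha_grid=(0.0, 0.5, 1.0),
                         ratio_grid=(0.05, 0.2, 0.5))


class TestFoldPlan:
    def test_even_split(self):
        plan = make_fold_plan(10, 5, 2, seed=0)
        sizes = np.bincount(plan.outer)
        assert sizes.tolist() == [2] * 5

    def test_stratified_balanced_case_control(self):
        labels = np.array([0] * 24 + [1] * 24)
        plan = make_fold_plan(48, 10, 3, labels=labels, seed=1)
        for f in range(10):
            members = labels[plan.outer == f]
            assert len(members) in (4, 5)
            assert abs(np.sum(members == 0) - np.sum(members == 1)) <= 1

    def test_seed_determinism(self):
        p1 = make_fold_plan(30, 5, 3, seed=7)
        p2 = make_fold_plan(30, 5, 3, seed=7)
        p3 = make_fold_plan(30, 5, 3, seed=8)
        np.testing.assert_array_equal(p1.outer, p2.outer)
        for a, b in zip(p1.inner, p2.inner):
            np.testing.assert_array_equal(a, b)
        assert not np.array_equal(p1.outer, p3.outer)
        assert np.bincount(p3.outer).tolist() == [6] * 5

    def test_inner_partitions_train(self):
        plan = make_fold_plan(23, 4, 3, seed=2)
        for f in range(4):
            train, test = plan.outer_split(f)
            assert len(train) + len(test) == 23
            assert len(plan.inner[f]) == len(train)
            assert set(plan.inner[f]) == {0, 1, 2}

    def test_small_class_rejected(self):
        labels = np.array([0] * 27 + [1] * 3)
        with pytest.raises(StratificationError):
            make_fold_plan(30, 5, 3, labels=labels, seed=0)

    def test_invalid_sizes(self):
        with pytest.raises(ConfigError):
            make_fold_plan(10, 1, 3)
        with pytest.raises(ConfigError):
            make_fold_plan(3, 5, 3)


class TestTuneHyperparams:
    def _xy(self, seed=0, strong=True):
        spec = SyntheticProfileSpec(
            n_subjects=60, n_bundles=5, n_metrics=2, n_nodes=8,
            n_active_groups=2, within_group_active_fraction=1.0,
            effect_size=3.0 if strong else 0.0, seed=seed,
        )
        ds = generate_profiles(spec)
        M = matrix_from_dataset(ds, spec)
        return M.values, ds.target.values, M.groups

    def test_singleton_grid_returned(self):
        X, y, groups = self._xy()
        plan = make_fold_plan(60, 3, 3, seed=0)
        res = tune_hyperparams(
            X, y, groups, plan.inner[0], plan.outer_split(0)[0],
            method="grid",
            search_space=SearchSpace(alpha_grid=(1.0,), ratio_grid=(0.1,)),
            tol=1e-4, max_iter=500,
        )
        assert (res.alpha, res.lam_ratio) == (1.0, 0.1)

    def test_group_sparse_signal_prefers_group_penalty(self):
        # with a whole-group signal, some alpha < 1 matches or beats the
        # best pure-lasso candidate on inner CV in most seeds
        wins = 0
        for seed in range(5):
            X, y, groups = self._xy(seed=40 + seed)
            plan = make_fold_plan(60, 3, 3, seed=seed)
            res = tune_hyperparams(
                X, y, groups, plan.inner[0], plan.outer_split(0)[0],
                search_space=SearchSpace(alpha_grid=(0.0, 0.5, 1.0),
                                         ratio_grid=(0.02, 0.1, 0.3)),
                tol=1e-4, max_iter=800,
            )
            best_lasso = max(
                s for a, r, s in res.evaluations if a == 1.0
            )
            best_grouped = max(
                s for a, r, s in res.evaluations if a < 1.0
            )
            wins += best_grouped >= best_lasso
        assert wins >= 3

    def test_shuffled_target_scores_near_zero(self, rng):
        X, y, groups = self._xy(seed=5)
        y = rng.permutation(y)
        plan = make_fold_plan(60, 3, 3, seed=0)
        res = tune_hyperparams(
            X, y, groups, plan.inner[0], plan.outer_split(0)[0],
            search_space=TINY_SPACE, tol=1e-4, max_iter=500,
        )
        assert res.score <= 0.25  # selection cannot manufacture real signal

    def test_smbo_seeded_and_within_bounds(self):
        X, y, groups = self._xy()
        plan = make_fold_plan(60, 3, 3, seed=0)
        kwargs = dict(
            method="smbo", budget=8, seed=11, tol=1e-4, max_iter=500,
        )
        r1 = tune_hyperparams(X, y, groups, plan.inner[0],
                              plan.outer_split(0)[0], **kwargs)
        r2 = tune_hyperparams(X, y, groups, plan.inner[0],
                              plan.outer_split(0)[0], **kwargs)
        assert (r1.alpha, r1.lam_ratio) == (r2.alpha, r2.lam_ratio)
        assert len(r1.evaluations) == 8
        assert 0.0 <= r1.alpha <= 1.0
        assert 1e-3 <= r1.lam_ratio <= 1.0

    def test_ebic_mode_prefers_sparser_fit_than_cv(self):
        X, y, groups = self._xy(seed=9)
        plan = make_fold_plan(60, 3, 3, seed=0)
        cv = tune_hyperparams(
            X, y, groups, plan.inner[0], plan.outer_split(0)[0],
            search_space=TINY_SPACE, tol=1e-4, max_iter=800,
        )
        ebic = tune_by_ebic(X, y, groups, search_space=TINY_SPACE,
                            tol=1e-4, max_iter=800)
        assert ebic.lam_ratio >= cv.lam_ratio


class TestNestedCV:
    def test_noiseless_linear_recovery(self):
        spec = SyntheticProfileSpec(
            n_subjects=80, n_bundles=3, n_metrics=1, n_nodes=6,
            n_active_groups=2, within_group_active_fraction=1.0,
            effect_size=1.0, noise_sd=0.0, seed=13,
        )
        ds = generate_profiles(spec)
        M = matrix_from_dataset(ds, spec)
        cfg = CVConfig(
            estimator="sgl", k0=3, k1=3,
            search_space=SearchSpace(alpha_grid=(0.5,),
                                     ratio_grid=(1e-4, 1e-3)),
            seed=3, tol=1e-7, max_iter=5000,
        )
        res = nested_cv(M, ds.target, cfg)
        assert res.metrics["r2"] >= 0.99

    def test_every_subject_predicted_once(self, small_regression):
        _, ds, M = small_regression
        cfg = CVConfig(estimator="sgl", k0=2, k1=2,
                       search_space=SearchSpace(alpha_grid=(0.5,),
                                                ratio_grid=(0.1,)),
                       seed=1, tol=1e-4, max_iter=500)
        res = nested_cv(M, ds.target, cfg)
        assert not np.isnan(res.predictions).any()
        assert len(res.fold_records) == 2
        covered = np.concatenate(
            [res.plan.outer_split(f)[1] for f in range(2)]
        )
        assert sorted(covered.tolist()) == list(range(M.n_subjects))

    def test_shuffled_target_gives_chance_r2(self, small_regression, rng):
        _, ds, M = small_regression
        from tractsgl import PhenotypeTarget

        vals = []
        for s in range(3):
            r = np.random.default_rng(600 + s)
            shuffled = PhenotypeTarget(
                values=r.permutation(ds.target.values),
                kind="continuous", transform="identity",
                subject_ids=ds.target.subject_ids,
            )
            cfg = CVConfig(estimator="sgl", k0=3, k1=3,
                           search_space=TINY_SPACE, seed=s,
                           tol=1e-4, max_iter=500)
            vals.append(nested_cv(M, shuffled, cfg).metrics["r2"])
        assert np.mean(vals) <= 0.05

    def test_classification_with_bagging_runs(self, small_classification):
        _, ds, M = small_classification
        cfg = CVConfig(estimator="sgl", k0=3, k1=3, bag_m=3,
                       search_space=SearchSpace(alpha_grid=(0.5,),
                                                ratio_grid=(0.1,)),
                       seed=2, tol=1e-4, max_iter=500)
        res = nested_cv(M, ds.target, cfg)
        assert res.proba is not None
        assert np.all((res.proba >= 0) & (res.proba <= 1))
        assert set(np.unique(res.predictions)) <= {0.0, 1.0}
        assert res.metrics["accuracy"] > 0.5  # strong one-group signal

    def test_determinism(self, small_regression):
        _, ds, M = small_regression
        cfg = CVConfig(estimator="sgl", k0=3, k1=3,
                       search_space=TINY_SPACE, seed=5,
                       tol=1e-4, max_iter=500)
        r1 = nested_cv(M, ds.target, cfg)
        r2 = nested_cv(M, ds.target, cfg)
        np.testing.assert_array_equal(r1.predictions, r2.predictions)
        assert r1.metrics == r2.metrics
        assert [f["alpha"] for f in r1.fold_records] == \
            [f["alpha"] for f in r2.fold_records]

    def test_baselines_share_fold_plan(self, small_regression):
        _, ds, M = small_regression
        results = {}
        for est in ("lasso", "bundle_mean_lasso", "pcr_lasso",
                    "elastic_net", "pcr_sgl"):
            cfg = CVConfig(estimator=est, k0=2, k1=2,
                           search_space=SearchSpace(alpha_grid=(0.5,),
                                                    ratio_grid=(0.1, 0.3)),
                           seed=9, tol=1e-4, max_iter=500)
            results[est] = nested_cv(M, ds.target, cfg)
        plans = [r.plan.outer for r in results.values()]
        for p in plans[1:]:
            np.testing.assert_array_equal(plans[0], p)  # paired comparisons
        for r in results.values():
            assert np.isfinite(r.metrics["r2"])

    def test_train_only_parameters_ignore_heldout_rows(self,
                                                       small_regression):
        # perturbing held-out rows must not change anything fitted on train
        _, ds, M = small_regression
        plan = make_fold_plan(M.n_subjects, 3, 3, seed=4)
        train, test = plan.outer_split(0)
        X = M.values
        y = ds.target.values

        tune1 = tune_hyperparams(
            X, y, M.groups, plan.inner[0], train,
            search_space=TINY_SPACE, tol=1e-4, max_iter=500,
        )
        pipe1 = _fit_pipeline("pcr_sgl", X[train], y[train], M.groups,
                              "squared", tune1.alpha, tune1.lam_ratio,
                              tol=1e-5, max_iter=800)

        X2 = X.copy()
        X2[test] += 100.0  # gross perturbation of held-out rows only
        tune2 = tune_hyperparams(
            X2, y, M.groups, plan.inner[0], train,
            search_space=TINY_SPACE, tol=1e-4, max_iter=500,
        )
        pipe2 = _fit_pipeline("pcr_sgl", X2[train], y[train], M.groups,
                              "squared", tune2.alpha, tune2.lam_ratio,
                              tol=1e-5, max_iter=800)

        assert (tune1.alpha, tune1.lam_ratio) == (tune2.alpha,
                                                  tune2.lam_ratio)
        np.testing.assert_array_equal(pipe1.scaler.mean, pipe2.scaler.mean)
        np.testing.assert_array_equal(pipe1.scaler.scale, pipe2.scaler.scale)
        np.testing.assert_array_equal(pipe1.model.coefficients,
                                      pipe2.model.coefficients)


class TestComputeMetrics:
    def test_perfect_regression(self):
        y = np.array([1.0, 2.0, 3.0])
        m = compute_metrics(y, y, task="continuous")
        assert m["r2"] == 1.0 and m["mae"] == 0.0 and m["median_ae"] == 0.0

    def test_mean_prediction_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = compute_metrics(y, np.full(4, y.mean()), task="continuous")
        assert m["r2"] == pytest.approx(0.0)

    def test_perfect_and_chance_classifier(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        m = compute_metrics(y, y, task="binary", proba=y.astype(float))
        assert m["accuracy"] == 1.0 and m["roc_auc"] == 1.0
        m2 = compute_metrics(y, np.ones(4), task="binary",
                             proba=np.full(4, 0.5))
        assert m2["roc_auc"] == 0.5

    def test_single_class_auc_missing(self):
        with pytest.warns(RuntimeWarning, match="single-class"):
            m = compute_metrics(np.zeros(3), np.zeros(3), task="binary",
                                proba=np.full(3, 0.4))
        assert m["roc_auc"] is None


class TestRandomizationTest:
    def test_single_shuffle_reproducible(self, small_regression):
        _, ds, M = small_regression
        cfg = CVConfig(estimator="sgl", k0=2, k1=2,
                       search_space=SearchSpace(alpha_grid=(0.5,),
                                                ratio_grid=(0.1,)),
                       seed=6, tol=1e-4, max_iter=500)
        r1 = randomization_test(M, ds.target, cfg, n_shuffles=1, seed=1)
        r2 = randomization_test(M, ds.target, cfg, n_shuffles=1, seed=1)
        assert r1["null"][0] == r2["null"][0]
        assert r1["observed"] == r2["observed"]

    def test_strong_signal_beats_null(self, small_regression):
        _, ds, M = small_regression
        cfg = CVConfig(estimator="sgl", k0=2, k1=2,
                       search_space=SearchSpace(alpha_grid=(0.5,),
                                                ratio_grid=(0.05, 0.2)),
                       seed=6, tol=1e-4, max_iter=500)
        res = randomization_test(M, ds.target, cfg, n_shuffles=5, seed=2)
        assert res["observed"] > max(res["null"])
        assert res["quantile"] == 1.0
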