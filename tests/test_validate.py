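"""Validation-scheme tests: fold hygiene, calibration, power, KS behavior."""

import numpy as np
import pytest

from nmropls.preproc import pareto_stats
from nmropls.validate import (
    COMPARISONS,
    CvConfig,
    ks_significance,
    permutation_null,
    repeated_external_cv,
    run_all_pairwise,
    stratified_folds,
)
from nmropls.validate import _draw_partition  # fold construction internals
from tests.conftest import null_metabolites, preprocess
from nmropls.cohortsim import CohortConfig, simulate_cohort


def two_class_noise(rng, n_per_class=7, bins=30):
    X = rng.standard_normal((2 * n_per_class, bins))
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return X, y


class TestFoldConstruction:
    def test_every_sample_lands_in_exactly_one_fold(self, rng):
        y = np.array([True] * 7 + [False] * 7)
        fold = stratified_folds(y, 8, rng)
        assert fold.shape == (14,)
        assert fold.min() >= 0 and fold.max() < 8

    def test_partition_keeps_both_classes_in_every_training_split(self, rng):
        y = np.array([True] * 7 + [False] * 7)
        for _ in range(50):
            fold = _draw_partition(y, 8, rng)
            for f in range(8):
                train = y[fold != f]
                assert train.any() and (~train).any()
            assert np.unique(fold).size == 8

    def test_class_counts_per_fold_differ_by_at_most_one(self, rng):
        y = np.array([True] * 7 + [False] * 7)
        fold = stratified_folds(y, 8, rng)
        for cls in (True, False):
            counts = np.bincount(fold[y == cls], minlength=8)
            assert counts.max() - counts.min() <= 1


class TestRepeatedExternalCv:
    def test_model_count_is_folds_times_repetitions(self, rng):
        X, y = two_class_noise(rng)
        cfg = CvConfig(external_folds=4, repetitions=5, internal_folds=3, seed=0)
        res = repeated_external_cv(X, y, cfg, keep_models=False)
        assert len(res.records) == 20
        per_rep = res.records.groupby("repetition")["n_test"].sum()
        assert (per_rep == 14).all()  # each sample tested once per repetition

    def test_scaling_statistics_come_from_the_training_split(self, rng):
        X, y = two_class_noise(rng, bins=12)
        cfg = CvConfig(external_folds=4, repetitions=1, internal_folds=3, seed=5)
        res = repeated_external_cv(X, y, cfg, keep_models=True)
        # replay the engine's partition stream for repetition 0
        stream = np.random.SeedSequence([cfg.seed, 0]).spawn(1)[0]
        replay_rng = np.random.default_rng(stream)
        ypos = y == "A"
        fold = _draw_partition(ypos, cfg.external_folds, replay_rng)
        for f in range(cfg.external_folds):
            mu, sc = pareto_stats(X[fold != f])
            assert np.allclose(res.models[f].train_column_means, mu)
            assert np.allclose(res.models[f].train_column_scale, sc)

    def test_same_seed_reproduces_accuracies_exactly(self, rng):
        X, y = two_class_noise(rng)
        cfg = CvConfig(external_folds=4, repetitions=10, internal_folds=3, seed=21)
        a = repeated_external_cv(X, y, cfg, keep_models=False).accuracies
        b = repeated_external_cv(X, y, cfg, keep_models=False).accuracies
        assert np.array_equal(a, b)

    def test_strongly_separated_classes_classify_nearly_perfectly(self, rng):
        X, y = two_class_noise(rng)
        X = X.copy()
        X[:7, 0] += 10.0  # 10 sd shift on one bin
        res = repeated_external_cv(X, y, CvConfig(repetitions=25, seed=3), keep_models=False)
        assert res.mean_accuracy >= 0.95

    def test_null_data_accuracy_is_not_optimistic(self):
        # With the same labels reused every repetition, CV accuracy on null
        # data varies by dataset and is pessimistically biased; the critical
        # property is the absence of optimism.  Grand mean over independent
        # null datasets stays near or below chance.
        means = []
        for seed in range(4):
            X, y = two_class_noise(np.random.default_rng(seed))
            res = repeated_external_cv(
                X, y, CvConfig(repetitions=25, seed=seed), keep_models=False
            )
            means.append(res.mean_accuracy)
        grand = float(np.mean(means))
        assert 0.35 <= grand <= 0.55


class TestPermutationNull:
    def test_mean_permuted_accuracy_is_calibrated_for_noise_data(self, rng):
        X, y = two_class_noise(rng)
        acc = permutation_null(X, y, CvConfig(seed=2))
        assert acc.size == 800
        assert 0.45 <= acc.mean() <= 0.55

    def test_label_shuffling_destroys_strong_separation(self, rng):
        X, y = two_class_noise(rng)
        X = X.copy()
        X[:7, 0] += 10.0
        acc = permutation_null(X, y, CvConfig(repetitions=50, seed=2))
        assert 0.40 <= acc.mean() <= 0.60

    def test_fixed_seed_gives_identical_permuted_accuracies(self, rng):
        X, y = two_class_noise(rng)
        cfg = CvConfig(repetitions=10, seed=17)
        assert np.array_equal(permutation_null(X, y, cfg), permutation_null(X, y, cfg))


class TestKsSignificance:
    def test_identical_arrays_give_zero_statistic(self):
        acc = [0.4, 0.5, 0.6, 0.7]
        D, p, sig = ks_significance(acc, acc)
        assert D == 0.0 and not sig and p == pytest.approx(1.0)

    def test_disjoint_supports_give_statistic_one(self):
        D, _, _ = ks_significance([0.8, 0.9, 1.0], [0.1, 0.2, 0.3])
        assert D == 1.0

    def test_exact_p_matches_label_permutation_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.6, 0.1, 10)
        b = rng.normal(0.5, 0.1, 10)
        _, p_exact, _ = ks_significance(a, b, method="exact")
        pool = np.concatenate([a, b])
        xs = np.sort(pool)

        def dplus(true, perm):
            ft = np.searchsorted(np.sort(true), xs, side="right") / true.size
            fp = np.searchsorted(np.sort(perm), xs, side="right") / perm.size
            return np.max(fp - ft)

        obs = dplus(a, b)
        mc = np.random.default_rng(1)
        hits = 0
        n_perm = 5000
        for _ in range(n_perm):
            idx = mc.permutation(20)
            hits += dplus(pool[idx[:10]], pool[idx[10:]]) >= obs - 1e-12
        p_mc = hits / n_perm
        assert p_exact == pytest.approx(p_mc, abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            ks_significance([], [0.5])


@pytest.fixture(scope="module")
def quick_cfg():
    return CvConfig(repetitions=12, seed=9)


class TestRunAllPairwise:
    def test_missing_group_is_rejected(self, default_cohort, quick_cfg):
        design = default_cohort["design"]
        bad = design[design["group"] != "KO/WD"]
        with pytest.raises(ValueError, match="KO/WD"):
            run_all_pairwise(default_cohort["norm"].values[: len(bad)], bad, quick_cfg)

    def test_effect_cohort_flags_all_four_comparisons(self, default_cohort, quick_cfg):
        reports = run_all_pairwise(default_cohort["norm"], default_cohort["design"], quick_cfg)
        assert len(reports) == 4
        assert all(r.significant for r in reports.values())
        for r in reports.values():
            assert len(r.true.records) == len(r.perm.records) == 12 * 8

    def test_null_cohort_flags_nothing(self, quick_cfg):
        spectra, design, _ = simulate_cohort(CohortConfig(seed=5), null_metabolites())
        norm = preprocess(spectra)
        reports = run_all_pairwise(norm, design, quick_cfg)
        assert not any(r.significant for r in reports.values())

    def test_report_summary_is_json_ready(self, default_cohort, quick_cfg):
        import json

        reports = run_all_pairwise(
            default_cohort["norm"], default_cohort["design"], quick_cfg,
            comparisons=(("WT/CD", "KO/WD"),),
        )
        s = reports["WT/CD vs KO/WD"].summary()
        json.dumps(s)  # must not raise
        assert s["n_models"] == 96
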