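"""Modeling core: duplex splitting, PLS against closed-form oracles, CV, VIP."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from herbfp import chemometrics as chem
from herbfp.errors import (
    DimensionError,
    ParameterError,
    StratificationError,
    TrainingError,
)
from herbfp.preprocess import resolve_spec

from oracles import ols_predictions


class TestDuplex:
    def test_rectangle_corners_split_into_diagonal_pairs(self):
        # longest distances are the two diagonals; duplex seeds train with one
        # and test with the other, worked through by hand
        X = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 1.0], [0.0, 1.0]])
        split = chem.duplex_split(X, fraction=0.5)
        assert sorted(split.train_ids) == [0, 2]
        assert sorted(split.test_ids) == [1, 3]

    def test_deterministic_for_fixed_input(self, rng):
        X = rng.normal(size=(30, 8))
        a = chem.duplex_split(X, 0.25)
        b = chem.duplex_split(X, 0.25)
        assert a.train_ids == b.train_ids
        assert a.test_ids == b.test_ids

    def test_partition_sizes_and_disjointness(self, rng):
        X = rng.normal(size=(67, 5))
        split = chem.duplex_split(X, 0.25)
        assert len(split.test_ids) == 17
        assert len(split.train_ids) == 50
        assert not set(split.train_ids) & set(split.test_ids)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            chem.duplex_split(np.eye(3), 0.5)
        with pytest.raises(ParameterError):
            chem.duplex_split(np.eye(8), 0.7)


class TestPls:
    def test_rank_one_data_fit_with_single_factor(self, rng):
        t = rng.normal(size=15)
        p = rng.normal(size=9)
        X = np.outer(t, p)
        y = 2.0 * t + 1.0
        core = chem.pls_fit(X, y, A=1)
        assert np.allclose(core.predict(X), y, atol=1e-8)

    def test_zero_factors_predict_training_mean(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        core = chem.pls_fit(X, y, A=3)
        assert np.allclose(core.predict(X, A=0), y.mean())

    @pytest.mark.parametrize("seed", range(3))
    def test_full_rank_predictions_match_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 8))
        y = rng.normal(size=12)
        core = chem.pls_fit(X, y, A=8)
        expected = ols_predictions(X, y)
        rel = np.linalg.norm(core.predict(X) - expected) / np.linalg.norm(expected)
        assert rel < 1e-8

    def test_matches_sklearn_pls_on_new_data(self, rng):
        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + 0.2 * rng.normal(size=25)
        Xnew = rng.normal(size=(6, 10))
        for A in (1, 3, 5):
            core = chem.pls_fit(X, y, A)
            sk = PLSRegression(n_components=A, scale=False).fit(X, y)
            assert np.allclose(core.predict(Xnew, A), sk.predict(Xnew).ravel(), atol=1e-8)

    def test_scores_are_mutually_orthogonal(self, rng):
        X = rng.normal(size=(20, 12))
        y = rng.normal(size=20)
        core = chem.pls_fit(X, y, A=6)
        G = core.T.T @ core.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_excess_factors_truncated_with_warning(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        core = chem.pls_fit(X, y, A=10)
        assert core.n_factors <= 4
        assert any("admissible" in w for w in core.warnings)

    def test_feature_mismatch_raises(self, rng):
        core = chem.pls_fit(rng.normal(size=(8, 5)), rng.normal(size=8), A=2)
        with pytest.raises(DimensionError):
            core.predict(rng.normal(size=(3, 4)))


class TestCompression:
    def test_training_projection_consistency(self, rng):
        X = rng.normal(size=(14, 40))
        y = rng.normal(size=14)
        scores_train, scores_other, core = chem.pls_compress(X, y, X, k=5)
        assert np.allclose(scores_other, scores_train, atol=1e-9)

    def test_full_rank_compression_preserves_training_predictions(self, rng):
        X = rng.normal(size=(12, 20))
        y = np.where(rng.uniform(size=12) < 0.5, 1.0, 2.0)
        k = 11  # full admissible rank
        s_tr, _, comp = chem.pls_compress(X, y, None, k)
        direct = chem.pls_fit(X, y, A=k).predict(X)
        via_scores = chem.pls_fit(s_tr, y, A=k).predict(s_tr)
        assert np.allclose(via_scores, direct, atol=1e-6)

    def test_rank_one_separable_single_score(self, rng):
        t = np.r_[rng.normal(3, 0.2, 8), rng.normal(-3, 0.2, 8)]
        X = np.outer(t, rng.normal(size=30))
        y = np.r_[np.ones(8), np.full(8, 2.0)]
        s_tr, _, _ = chem.pls_compress(X, y, None, k=1)
        core = chem.pls_fit(s_tr, y, A=1)
        assert np.array_equal(chem.codes_from_values(core.predict(s_tr)), y.astype(int))


class TestDecisionRule:
    def test_code_endpoints_and_tie(self):
        assert chem.codes_from_values(np.array([1.0, 2.0, 1.49, 1.51])).tolist() == [1, 2, 1, 2]
        # a prediction exactly on the midpoint resolves to 'absent'
        assert chem.codes_from_values(np.array([1.5]))[0] == chem.NEGATIVE

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(TrainingError):
            chem.plsda_fit(X, np.ones(10), A=1)


class TestCrossValidation:
    def test_fold_sizes_balanced_on_fifty_samples(self):
        y = np.r_[np.ones(42), np.full(8, 2.0)]
        fold_of = chem.stratified_folds(y, folds=10, seed=0)
        sizes = np.bincount(fold_of, minlength=10)
        assert sizes.tolist() == [5] * 10

    def test_fold_training_part_missing_class_raises(self):
        y = np.r_[np.ones(9), [2.0]]  # one negative, two folds -> one fold trains without it
        with pytest.raises(StratificationError):
            chem.stratified_folds(y, folds=2, seed=0)

    def test_chosen_complexity_is_smallest_at_maximum(self, rng):
        X = rng.normal(size=(40, 15))
        y = np.where(X[:, 0] + 0.1 * rng.normal(size=40) > 0, 1.0, 2.0)
        cv = chem.cross_validate(X, y, max_A=8, folds=5, seed=1)
        curve = cv.ccr_curve
        assert cv.chosen_a == int(np.argmax(curve)) + 1
        assert np.all(curve[: cv.chosen_a - 1] < curve[cv.chosen_a - 1])

    def test_separable_data_reaches_perfect_cv(self, rng):
        n = 30
        y = np.r_[np.ones(n // 2), np.full(n // 2, 2.0)]
        X = rng.normal(size=(n, 10))
        X[:, 3] += (y - 1.5) * 8  # one strongly informative feature
        cv = chem.cross_validate(X, y, max_A=6, folds=5, seed=0, k_compress=5)
        assert cv.best_ccr == 100.0
        assert cv.chosen_a <= 2

    def test_perturbing_one_fold_leaves_that_folds_other_predictions_alone(self, rng):
        # leakage sentinel: a validation row's values must never influence the
        # model its own fold is predicted with
        X = rng.normal(size=(30, 12))
        y = np.r_[np.ones(20), np.full(10, 2.0)]
        cv1 = chem.cross_validate(X, y, max_A=4, folds=5, seed=3)
        k = 7  # perturb one sample
        X2 = X.copy()
        X2[k] += rng.normal(size=12) * 5
        cv2 = chem.cross_validate(X2, y, max_A=4, folds=5, seed=3)
        same_fold = (cv1.fold_of == cv1.fold_of[k]) & (np.arange(30) != k)
        assert np.array_equal(cv1.predictions[same_fold], cv2.predictions[same_fold])


class TestEvaluation:
    def test_ccr_from_printed_confusions(self):
        ilex_test = chem.StageReport.from_confusion(tp=14, fp=0, tn=2, fn=1)
        assert ilex_test.ccr_pct == 94
        aristolochia_cv = chem.StageReport.from_confusion(tp=43, fp=0, tn=7, fn=0)
        assert aristolochia_cv.ccr_pct == 100

    def test_all_wrong_gives_zero_with_ids(self):
        rep = chem.StageReport.from_predictions([1, 1, 2, 2], [2, 2, 1, 1], ids=list("abcd"))
        assert rep.ccr == 0.0
        assert rep.misclassified == list("abcd")
        assert (rep.fn, rep.fp) == (2, 2)

    def test_counts_partition_the_stage(self, rng):
        y = rng.choice([1, 2], size=25)
        p = rng.choice([1, 2], size=25)
        rep = chem.StageReport.from_predictions(y, p)
        assert rep.tp + rep.fp + rep.tn + rep.fn == 25
        assert rep.ccr == pytest.approx(100 * np.mean(y == p))

    def test_empty_partition_rejected(self):
        with pytest.raises(ParameterError):
            chem.StageReport.from_predictions([], [])


class TestVip:
    @pytest.mark.parametrize("seed,A", [(0, 1), (1, 3), (2, 5)])
    def test_mean_squared_vip_is_one(self, seed, A):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 15))
        y = X @ rng.normal(size=15) + rng.normal(size=20)
        vips = chem.vip_scores(chem.pls_fit(X, y, A))
        assert np.mean(vips**2) == pytest.approx(1.0, abs=1e-10)

    def test_single_informative_feature_dominates(self, rng):
        X = rng.normal(size=(30, 10))
        y = 3.0 * X[:, 4] + 0.01 * rng.normal(size=30)
        vips = chem.vip_scores(chem.pls_fit(X, y, A=1))
        assert int(np.argmax(vips)) == 4

    def test_single_factor_vip_orders_like_weights(self, rng):
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8)
        core = chem.pls_fit(X, y, A=1)
        vips = chem.vip_scores(core, A=1)
        assert np.array_equal(np.argsort(vips), np.argsort(np.abs(core.W[:, 0])))

    def test_uninformative_fit_rejected(self, rng):
        with pytest.raises(ParameterError):
            core = chem.pls_fit(rng.normal(size=(10, 5)), np.zeros(10), A=2)
            chem.vip_scores(core)
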