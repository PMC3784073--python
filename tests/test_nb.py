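import numpy as np
import pytest

from nbhnb import (DiscreteDataset, fit_nb, nb_posterior, nb_predict,
                   rank_features, select_top)
from .conftest import random_discrete_dataset


def _dataset(X, y, n_cat):
    return DiscreteDataset(np.asarray(X), np.asarray(y),
                           n_categories=np.asarray(n_cat))


def test_smoothed_prior_arithmetic():
    # 3 + 7 samples, alpha = 1 -> P(c0) = 4/12
    d = _dataset([[0]] * 10, [0] * 3 + [1] * 7, [1])
    m = fit_nb(d, alpha=1.0)
    np.testing.assert_allclose(m.prior, [4 / 12, 8 / 12])


def test_smoothing_floor_for_unseen_category():
    # class 0 has 5 samples, none with value 7, cardinality 10:
    # P(7 | c0) = (0 + 1) / (5 + 10) = 1/15
    X = [[0]] * 5 + [[7]] * 5
    y = [0] * 5 + [1] * 5
    m = fit_nb(_dataset(X, y, [10]), alpha=1.0)
    assert m.cond[0, 7, 0] == pytest.approx(1 / 15)
    assert np.all(m.cond[0, :, :][np.arange(10) < 10] > 0)


def test_unsmoothed_tables_match_counting_oracle(rng):
    d = random_discrete_dataset(rng, n_samples=60, n_features=3,
                                n_categories=2, n_classes=2)
    # ensure every (feature, value, class) cell is occupied for alpha=0
    d.X[:8] = np.array([[u, u, u] for u in (0, 1)] * 4)
    d.y[:8] = [0, 0, 1, 1] * 2
    m = fit_nb(d, alpha=0.0)
    for i in range(3):
        for v in range(2):
            for c in range(2):
                expect = np.sum((d.X[:, i] == v) & (d.y == c)) / np.sum(d.y == c)
                assert m.cond[i, v, c] == pytest.approx(expect, abs=1e-15)


def test_posterior_with_empty_subset_is_the_prior(small_dataset):
    m = fit_nb(small_dataset, alpha=1.0)
    post = nb_posterior(m, small_dataset.X[0], feature_subset=[])
    np.testing.assert_allclose(post, m.prior / m.prior.sum(), atol=1e-15)


def test_posterior_two_term_normalization():
    # uniform priors, single feature with P(v|c0)=0.9, P(v|c1)=0.1
    X = [[0]] * 9 + [[1]] + [[1]] * 9 + [[0]]
    y = [0] * 10 + [1] * 10
    m = fit_nb(_dataset(X, y, [2]), alpha=0.0)
    post = nb_posterior(m, np.array([0]))
    np.testing.assert_allclose(post, [0.9, 0.1], atol=1e-12)


def test_posterior_matches_direct_product_oracle(rng):
    d = random_discrete_dataset(rng, n_samples=100, n_features=4,
                                n_categories=3, n_classes=3)
    m = fit_nb(d, alpha=1.0)
    for e in d.X[:10]:
        scores = np.array([
            m.prior[c] * np.prod([m.cond[i, e[i], c] for i in range(4)])
            for c in range(3)
        ])
        np.testing.assert_allclose(nb_posterior(m, e), scores / scores.sum(),
                                   atol=1e-12)


def test_fitted_tables_are_normalized(rng):
    for _ in range(10):
        d = random_discrete_dataset(rng, n_samples=rng.integers(10, 60),
                                    n_features=4, n_categories=3, n_classes=3)
        m = fit_nb(d, alpha=1.0)
        assert abs(m.prior.sum() - 1) < 1e-12
        np.testing.assert_allclose(m.cond.sum(axis=1), 1.0, atol=1e-12)
        post = nb_posterior(m, d.X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


def test_single_class_and_empty_inputs_rejected():
    with pytest.raises(ValueError, match="class"):
        fit_nb(_dataset([[0], [1]], [0, 0], [2]))
    with pytest.raises(ValueError, match="empty"):
        fit_nb(DiscreteDataset(np.empty((0, 1), dtype=int),
                               np.empty(0, dtype=int), [2]))


def test_unseen_category_with_zero_alpha_advises_smoothing():
    d = _dataset([[0], [0], [1], [1]], [0, 0, 1, 1], [3])
    m = fit_nb(d, alpha=0.0)
    with pytest.raises(ValueError, match="alpha > 0"):
        nb_posterior(m, np.array([2]))


def test_perfect_predictor_ranks_first(rng):
    d = random_discrete_dataset(rng, n_samples=60, n_features=5,
                                n_categories=2, n_classes=2)
    d.X[:, 3] = d.y  # feature 3 copies the label
    ranking = rank_features(d, cv_folds=5, seed=0)
    assert ranking.order[0] == 3
    assert ranking.scores[0] == 1.0


def test_label_independent_feature_scores_near_chance(rng):
    n = 400
    X = rng.integers(0, 2, size=(n, 1))
    y = np.tile([0, 1], n // 2)
    ranking = rank_features(DiscreteDataset(X, y, [2]), cv_folds=5, seed=0)
    assert abs(ranking.scores[0] - 0.5) < 3 * np.sqrt(0.25 / n) + 0.05


def test_tied_scores_order_by_feature_index(rng):
    d = random_discrete_dataset(rng, n_samples=40, n_features=4,
                                n_categories=2, n_classes=2)
    d.X[:, 1] = d.X[:, 0]
    d.X[:, 2] = d.X[:, 0]  # identical features -> identical scores
    ranking = rank_features(d, cv_folds=5, seed=0)
    tied = [int(f) for f in ranking.order if f in (0, 1, 2)]
    assert tied == sorted(tied)


def test_cv_folds_beyond_minority_class_rejected():
    d = _dataset([[0], [1], [0], [1], [0]], [0, 0, 0, 0, 1], [2])
    with pytest.raises(ValueError, match="minority"):
        rank_features(d, cv_folds=2, seed=0)


def test_resubstitution_and_factor_schemes_run(small_dataset):
    r1 = rank_features(small_dataset, cv_folds=None, seed=0)
    r2 = rank_features(small_dataset, scheme="nb_factor_score")
    assert len(r1.order) == len(r2.order) == small_dataset.n_features
    assert np.all(np.diff(r1.scores) <= 0) and np.all(np.diff(r2.scores) <= 0)


def _ranking_with_scores(scores):
    from nbhnb import FeatureRanking
    order = np.argsort(-np.asarray(scores), kind="stable")
    return FeatureRanking(order=order, scores=np.asarray(scores)[order],
                          scheme="single_feature_accuracy")


def test_select_top_cap_binds_when_many_pass():
    ranking = _ranking_with_scores(np.linspace(0.99, 0.76, 60))
    sel = select_top(ranking, threshold=0.75, cap=40)
    assert len(sel.selected) == 40
    assert sel.threshold_met


def test_select_top_threshold_binds_when_few_pass():
    ranking = _ranking_with_scores([0.9, 0.85, 0.8, 0.79, 0.76] + [0.5] * 20)
    sel = select_top(ranking, threshold=0.75, cap=40)
    assert len(sel.selected) == 5


def test_select_top_falls_back_with_warning_when_none_pass():
    ranking = _ranking_with_scores(np.linspace(0.6, 0.4, 50))
    with pytest.warns(UserWarning, match="keeping top"):
        sel = select_top(ranking, threshold=0.75, cap=40)
    assert len(sel.selected) == 40
    assert not sel.threshold_met


def test_predict_batch_matches_per_sample(small_dataset):
    m = fit_nb(small_dataset, alpha=1.0)
    batch = nb_predict(m, small_dataset.X[:5])
    singles = [nb_predict(m, x) for x in small_dataset.X[:5]]
    assert batch.tolist() == singles
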