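import numpy as np
import pytest

from nbhnb import (DiscreteDataset, compute_weights,
                   conditional_mutual_information, estimate_cmi_matrix,
                   estimate_pairwise_cpts, fit_hnb, fit_nb, hnb_posterior,
                   hnb_predict, nb_posterior)
from .conftest import random_discrete_dataset


def brute_force_cmi(joint):
    """Triple-sum CMI oracle, nested loops, no vectorization."""
    vi, vj, nc = joint.shape
    p_c = joint.sum(axis=(0, 1))
    p_ic = joint.sum(axis=1)
    p_jc = joint.sum(axis=0)
    total = 0.0
    for u in range(vi):
        for v in range(vj):
            for c in range(nc):
                p = joint[u, v, c]
                if p > 0:
                    total += p * np.log(p * p_c[c] / (p_ic[u, c] * p_jc[v, c]))
    return total


def brute_force_hnb_posterior(model, sample):
    """Direct nested-loop evaluation of the hidden-parent classification rule."""
    f = model.n_features
    n_classes = model.nb.prior.shape[0]
    scores = np.zeros(n_classes)
    for c in range(n_classes):
        val = model.nb.prior[c]
        for i in range(f):
            if model.no_parent[i]:
                val *= model.nb.cond[i, sample[i], c]
            else:
                mix = 0.0
                for j in range(f):
                    if j != i:
                        mix += (model.weights[i, j]
                                * model.pair_cond[i, j, sample[i], sample[j], c])
                val *= mix
        scores[c] = val
    return scores / scores.sum()


def test_identical_binary_features_give_deterministic_copy_cpt():
    X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]] * 3)
    y = np.array([0, 1] * 6)
    d = DiscreteDataset(X, y, [2, 2])
    pair_cond, _ = estimate_pairwise_cpts(d, alpha=0.0)
    for u in (0, 1):
        for c in (0, 1):
            assert pair_cond[0, 1, u, u, c] == pytest.approx(1.0)


def test_pairwise_smoothing_floor_is_positive():
    X = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
    y = np.array([0, 0, 1, 1])
    d = DiscreteDataset(X, y, [2, 2])
    pair_cond, _ = estimate_pairwise_cpts(d, alpha=1.0)
    # (u=1, v=0, c=0) never observed: (0 + 1)/(count_{j=0,c=0} + 1*2) = 1/4
    assert pair_cond[0, 1, 1, 0, 0] == pytest.approx(1 / 4)


def test_pairwise_tables_match_counting_oracle(rng):
    d = random_discrete_dataset(rng, n_samples=50, n_features=3,
                                n_categories=2, n_classes=2)
    pair_cond, joint = estimate_pairwise_cpts(d, alpha=1.0)
    X, y = d.X, d.y
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            for u in range(2):
                for v in range(2):
                    for c in range(2):
                        n_uvc = np.sum((X[:, i] == u) & (X[:, j] == v) & (y == c))
                        n_vc = np.sum((X[:, j] == v) & (y == c))
                        assert pair_cond[i, j, u, v, c] == pytest.approx(
                            (n_uvc + 1) / (n_vc + 2), abs=1e-15)
                        assert joint[i, j, u, v, c] == pytest.approx(
                            (n_uvc + 1) / (50 + 2 * 2 * 2), abs=1e-15)


def test_cmi_zero_for_conditionally_independent_pair():
    # product joint: A_i and A_j independent within each class
    pi = np.array([0.3, 0.7])
    pj = np.array([0.6, 0.4])
    pc = np.array([0.5, 0.5])
    joint = pi[:, None, None] * pj[None, :, None] * pc[None, None, :]
    assert conditional_mutual_information(joint) == pytest.approx(0.0, abs=1e-14)


def test_cmi_of_deterministic_binary_copy_is_log2():
    joint = np.zeros((2, 2, 1))
    joint[0, 0, 0] = joint[1, 1, 0] = 0.5
    assert conditional_mutual_information(joint) == pytest.approx(np.log(2))


def test_cmi_matches_triple_sum_oracle_on_dirichlet_joints(rng):
    for _ in range(20):
        joint = rng.dirichlet(np.ones(18)).reshape(3, 3, 2)
        assert conditional_mutual_information(joint) == pytest.approx(
            brute_force_cmi(joint), abs=1e-12)


def test_unnormalized_joint_rejected():
    with pytest.raises(ValueError, match="not normalized"):
        conditional_mutual_information(np.full((2, 2, 1), 0.3))


def test_weights_split_equally_for_equal_cmi():
    cmi = np.array([[0.0, 0.3, 0.3], [0.3, 0.0, 0.3], [0.3, 0.3, 0.0]])
    W, no_parent = compute_weights(cmi)
    np.testing.assert_allclose(W[0], [0.0, 0.5, 0.5])
    assert not no_parent.any()


def test_weight_row_normalization_arithmetic():
    cmi = np.array([[0.0, 0.2, 0.0, 0.6],
                    [0.2, 0.0, 0.0, 0.0],
                    [0.0, 0.0, 0.0, 0.0],
                    [0.6, 0.0, 0.0, 0.0]])
    W, no_parent = compute_weights(cmi)
    np.testing.assert_allclose(W[0], [0.0, 0.25, 0.0, 0.75])
    assert no_parent.tolist() == [False, False, True, False]


def test_negative_cmi_beyond_tolerance_rejected():
    with pytest.raises(ValueError, match="negative CMI"):
        compute_weights(np.array([[0.0, -1e-6], [-1e-6, 0.0]]))


def test_fitted_model_invariants(rng):
    for _ in range(5):
        d = random_discrete_dataset(rng, n_samples=40, n_features=4,
                                    n_categories=3, n_classes=3)
        m = fit_hnb(d, alpha=1.0)
        # pairwise conditionals normalized over a_i
        sums = m.pair_cond.sum(axis=2)
        off_diag = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(sums[off_diag], 1.0, atol=1e-12)
        # CMI symmetric, nonnegative, zero diagonal
        np.testing.assert_allclose(m.cmi, m.cmi.T, atol=1e-12)
        assert np.all(m.cmi >= 0)
        assert np.all(np.diag(m.cmi) == 0)
        # weight rows normalized unless flagged
        rows = ~m.no_parent
        np.testing.assert_allclose(m.weights[rows].sum(axis=1), 1.0, atol=1e-12)
        # posterior normalized
        post = hnb_posterior(m, d.X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


def test_single_feature_model_reduces_to_nb(rng):
    d = random_discrete_dataset(rng, n_samples=30, n_features=1,
                                n_categories=3, n_classes=2)
    m = fit_hnb(d, alpha=1.0)
    assert m.no_parent.all()
    for x in d.X[:5]:
        np.testing.assert_allclose(hnb_posterior(m, x),
                                   nb_posterior(m.nb, x), atol=1e-12)


def test_posterior_matches_nested_loop_oracle(rng):
    for _ in range(10):
        d = random_discrete_dataset(rng, n_samples=30, n_features=3,
                                    n_categories=2, n_classes=2)
        m = fit_hnb(d, alpha=1.0)
        for x in d.X[:5]:
            np.testing.assert_allclose(hnb_posterior(m, x),
                                       brute_force_hnb_posterior(m, x),
                                       atol=1e-12)


def test_modal_class_pattern_is_classified_to_that_class(rng):
    # class 1 concentrates on the all-ones pattern, class 0 on all-zeros
    n = 100
    y = np.repeat([0, 1], n // 2)
    X = np.where(rng.random((n, 4)) < 0.9, y[:, None], 1 - y[:, None])
    d = DiscreteDataset(X, y, [2] * 4)
    m = fit_hnb(d, alpha=1.0)
    assert hnb_predict(m, np.ones(4, dtype=int)) == 1
    assert hnb_predict(m, np.zeros(4, dtype=int)) == 0


def test_prediction_tie_breaks_to_smallest_class_index():
    # perfectly symmetric data -> exactly tied posterior
    X = np.array([[0, 0], [1, 1], [0, 0], [1, 1]])
    y = np.array([0, 0, 1, 1])
    m = fit_hnb(DiscreteDataset(X, y, [2, 2]), alpha=1.0)
    post = hnb_posterior(m, np.array([0, 0]))
    assert post[0] == pytest.approx(post[1])
    assert hnb_predict(m, np.array([0, 0])) == 0


def test_batch_prediction_equals_per_sample(small_dataset):
    m = fit_hnb(small_dataset, alpha=1.0)
    batch = hnb_predict(m, small_dataset.X[:8])
    assert batch.tolist() == [hnb_predict(m, x) for x in small_dataset.X[:8]]


def test_zero_cmi_model_reduces_to_nb_exactly(rng):
    d = random_discrete_dataset(rng, n_samples=40, n_features=4,
                                n_categories=2, n_classes=2)
    m = fit_hnb(d, alpha=1.0)
    m.cmi[:] = 0.0
    m.weights[:] = 0.0
    m.no_parent[:] = True
    nb_m = fit_nb(d, alpha=1.0)
    np.testing.assert_allclose(hnb_posterior(m, d.X), nb_posterior(nb_m, d.X),
                               atol=1e-12)


def test_subset_restriction_equals_refit_on_subset(rng):
    """Restricting a fitted model to a feature subset (with renormalized
    hidden-parent weights) must equal refitting HNB on those features."""
    d = random_discrete_dataset(rng, n_samples=60, n_features=5,
                                n_categories=3, n_classes=2)
    m_full = fit_hnb(d, alpha=1.0)
    subset = np.array([0, 2, 4])
    m_sub = fit_hnb(d.subset_features(subset), alpha=1.0)
    post_restricted = hnb_posterior(m_full, d.X, feature_subset=subset)
    post_refit = hnb_posterior(m_sub, d.X[:, subset])
    np.testing.assert_allclose(post_restricted, post_refit, atol=1e-12)


def test_single_class_cmi_estimate_is_label_free(rng):
    X = rng.integers(0, 2, size=(80, 3))
    d1 = DiscreteDataset(X, np.zeros(80, dtype=int), [2] * 3)
    cmi = estimate_cmi_matrix(d1, alpha=1.0)
    assert cmi.shape == (3, 3)
    np.testing.assert_allclose(cmi, cmi.T, atol=1e-12)
    assert np.all(cmi >= 0)


def test_fewer_than_two_features_rejected_for_pairwise():
    d = DiscreteDataset(np.zeros((4, 1), dtype=int), np.array([0, 0, 1, 1]), [1])
    with pytest.raises(ValueError, match="plain NB"):
        estimate_pairwise_cpts(d, alpha=1.0)
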