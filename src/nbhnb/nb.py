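"""Naive Bayes filter: smoothed NB models, per-feature ranking, top-m selection.

The filter interrogates each marker separately: a single-feature NB model is
scored by stratified cross-validated prediction accuracy, features are
ranked by that score, and the top-ranked subset (score >= threshold, capped
at ``m``) is handed to the Hidden Naive Bayes step.

Estimation uses Laplace smoothing with pseudocount ``alpha`` (default 1):

    P(c)        = (N_c + alpha) / (N + alpha |C|)
    P(a_i=v|c)  = (N_{ivc} + alpha) / (N_c + alpha V_i)

Posteriors are evaluated in log space and normalized; argmax ties break
toward the smallest class index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset import DiscreteDataset

__all__ = [
    "NBModel", "FeatureRanking",
    "fit_nb", "nb_posterior", "nb_predict",
    "rank_features", "select_top",
]


@dataclass
class NBModel:
    """Class priors and per-feature conditional tables.

    ``cond`` is a dense array of shape ``(n_features, V_max, n_classes)``;
    cells beyond a feature's cardinality ``V_i`` are zero and never
    indexed by valid data.
    """

    prior: np.ndarray
    cond: np.ndarray
    n_categories: np.ndarray
    alpha: float
    class_names: list = None
    feature_names: list = None

    @property
    def n_classes(self) -> int:
        return self.prior.shape[0]

    @property
    def n_features(self) -> int:
        return self.cond.shape[0]


def _class_feature_counts(X: np.ndarray, y: np.ndarray, n_classes: int,
                          v_max: int) -> tuple[np.ndarray, np.ndarray]:
    """counts[i, v, c] and class totals, one pass per class."""
    n_features = X.shape[1]
    counts = np.zeros((n_features, v_max, n_classes))
    class_counts = np.bincount(y, minlength=n_classes).astype(float)
    feat_idx = np.arange(n_features)[None, :]
    for c in range(n_classes):
        Xc = X[y == c]
        if Xc.shape[0]:
            np.add.at(counts[:, :, c], (feat_idx, Xc), 1.0)
    return counts, class_counts


def fit_nb(train: DiscreteDataset, alpha: float = 1.0) -> NBModel:
    """Fit a smoothed Naive Bayes model on discrete training data."""
    if train.n_samples == 0 or train.n_features == 0:
        raise ValueError("empty dataset")
    if train.n_classes < 2 or len(np.unique(train.y)) < 2:
        raise ValueError("need at least 2 classes with >= 1 sample each")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    v_max = int(train.n_categories.max())
    counts, class_counts = _class_feature_counts(
        train.X, train.y, train.n_classes, v_max)
    prior = (class_counts + alpha) / (train.n_samples + alpha * train.n_classes)
    denom = class_counts[None, None, :] + alpha * train.n_categories[:, None, None]
    valid = np.arange(v_max)[None, :, None] < train.n_categories[:, None, None]
    cond = np.where(valid, (counts + alpha) / denom, 0.0)
    return NBModel(prior=prior, cond=cond, n_categories=train.n_categories.copy(),
                   alpha=alpha, class_names=train.class_names,
                   feature_names=train.feature_names)


def _as_batch(sample: np.ndarray) -> tuple[np.ndarray, bool]:
    sample = np.asarray(sample)
    if sample.ndim == 1:
        return sample[None, :], True
    return sample, False


def nb_posterior(model: NBModel, sample, feature_subset=None) -> np.ndarray:
    """Normalized per-class posterior P(c | a) over a feature subset.

    ``sample`` may be one attribute vector or a batch; the empty subset
    returns the prior.  Computed in log space.
    """
    X, single = _as_batch(sample)
    if X.shape[1] != model.n_features:
        raise ValueError("sample width does not match the model")
    subset = (np.arange(model.n_features) if feature_subset is None
              else np.asarray(feature_subset, dtype=np.int64))
    log_score = np.tile(np.log(model.prior)[None, :], (X.shape[0], 1))
    if subset.size:
        p = model.cond[subset[None, :], X[:, subset], :]  # (n, |S|, C)
        if np.any(p.sum(axis=2) == 0):
            raise ValueError(
                "category unseen in training for every class; refit with alpha > 0"
            )
        with np.errstate(divide="ignore"):
            log_score += np.sum(np.log(p), axis=1)
    log_score -= log_score.max(axis=1, keepdims=True)
    post = np.exp(log_score)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if single else post


def nb_predict(model: NBModel, sample, feature_subset=None) -> np.ndarray:
    """argmax of :func:`nb_posterior`; ties break to the smallest class index."""
    post = nb_posterior(model, sample, feature_subset)
    return int(np.argmax(post)) if post.ndim == 1 else np.argmax(post, axis=1)


@dataclass
class FeatureRanking:
    """Features ordered by filter score (descending, ties by feature index)."""

    order: np.ndarray          # feature ids, best first
    scores: np.ndarray         # aligned with order, non-increasing
    scheme: str
    threshold: float = None
    cap: int = None
    selected: np.ndarray = field(default=None)
    threshold_met: bool = True

    def to_tsv(self) -> str:
        lines = ["feature\tscore"]
        lines += [f"{int(f)}\t{s:.6f}" for f, s in zip(self.order, self.scores)]
        return "\n".join(lines) + "\n"


def _single_feature_cv_scores(train: DiscreteDataset, cv_folds: int,
                              seed, alpha: float) -> np.ndarray:
    """CV accuracy of a one-feature NB model, all features at once.

    One smoothed count table per fold covers every feature, so the cost is
    a single pass over the fold per feature — linear in feature count.
    """
    X, y = train.X, train.y
    v_max = int(train.n_categories.max())
    n_classes = train.n_classes
    correct = np.zeros(train.n_features)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    feat_idx = np.arange(train.n_features)[None, :]
    for tr, te in skf.split(X, y):
        counts, class_counts = _class_feature_counts(X[tr], y[tr], n_classes, v_max)
        prior = (class_counts + alpha) / (len(tr) + alpha * n_classes)
        denom = class_counts[None, None, :] + alpha * train.n_categories[:, None, None]
        cond = (counts + alpha) / denom
        # (n_test, F, C): per-feature single-feature posteriors, log space
        with np.errstate(divide="ignore"):
            score = np.log(cond[feat_idx, X[te]]) + np.log(prior)[None, None, :]
        pred = np.argmax(score, axis=2)
        correct += (pred == y[te][:, None]).sum(axis=0)
    return correct / train.n_samples


def _factor_scores(train: DiscreteDataset, alpha: float) -> np.ndarray:
    """Sample-mean of the best-class NB factor max_c P(c) P(a_i|c)."""
    model = fit_nb(train, alpha)
    factors = model.cond[np.arange(train.n_features)[None, :], train.X, :]
    return np.mean(np.max(factors * model.prior[None, None, :], axis=2), axis=0)


def rank_features(train: DiscreteDataset,
                  scheme: str = "single_feature_accuracy",
                  cv_folds: int | None = 10,
                  seed: int = 0,
                  alpha: float = 1.0) -> FeatureRanking:
    """Score every feature on its own and rank descending.

    Default scheme scores each feature by the stratified ``cv_folds``-fold
    CV accuracy of an NB model using only that feature (``cv_folds=None``
    scores by training resubstitution instead).  The ``nb_factor_score``
    scheme ranks by the sorted NB factor value.  Ties break by ascending
    feature index.
    """
    if train.n_classes < 2:
        raise ValueError("ranking needs at least 2 classes")
    if scheme == "single_feature_accuracy":
        if cv_folds is not None:
            minority = np.bincount(train.y).min()
            if cv_folds > minority:
                raise ValueError(
                    f"cv_folds={cv_folds} exceeds minority class count {minority}"
                )
            scores = _single_feature_cv_scores(train, cv_folds, seed, alpha)
        else:  # resubstitution
            model = fit_nb(train, alpha)
            p = model.cond[np.arange(train.n_features)[None, :], train.X, :]
            with np.errstate(divide="ignore"):
                pred = np.argmax(np.log(p) + np.log(model.prior)[None, None, :], axis=2)
            scores = (pred == train.y[:, None]).mean(axis=0)
    elif scheme == "nb_factor_score":
        scores = _factor_scores(train, alpha)
    else:
        raise ValueError(f"unknown ranking scheme {scheme!r}")
    # stable sort on -score keeps ascending feature index among ties
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(order=order.astype(np.int64), scores=scores[order],
                          scheme=scheme)


def select_top(ranking: FeatureRanking, threshold: float = 0.75,
               cap: int = 40) -> FeatureRanking:
    """Keep the top-ranked features whose score passes ``threshold``, at most ``cap``.

    If no feature passes, the top ``cap`` are kept and a warning recorded —
    an uninformative panel is still better diagnosed downstream than an
    empty one.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if ranking.order.size == 0:
        raise ValueError("empty ranking")
    n_pass = int(np.sum(ranking.scores >= threshold))
    if n_pass == 0:
        warnings.warn(
            f"no feature reached accuracy {threshold}; keeping top {cap} anyway",
            stacklevel=2)
        selected = ranking.order[:cap]
        met = False
    else:
        selected = ranking.order[:min(cap, n_pass)]
        met = True
    return FeatureRanking(order=ranking.order, scores=ranking.scores,
                          scheme=ranking.scheme, threshold=threshold, cap=cap,
                          selected=selected.copy(), threshold_met=met)
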