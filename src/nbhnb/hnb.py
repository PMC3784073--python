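"""Hidden Naive Bayes classifier with CMI-weighted hidden parents.

Plain Naive Bayes assumes the attributes are independent given the class —
rarely true for co-regulated genes or linked markers.  HNB keeps the
one-pass estimation of NB but gives every attribute ``A_i`` a *hidden
parent*: a mixture over all other attributes' pairwise conditionals,

    P(a_i | a_hp_i, c) = sum_{j != i} W_ij P(a_i | a_j, c),

with mixture weights proportional to the conditional mutual information

    I(A_i; A_j | C) = sum_{a_i, a_j, c} P(a_i, a_j, c)
                      log [ P(a_i, a_j | c) / (P(a_i | c) P(a_j | c)) ],

row-normalized so sum_{j != i} W_ij = 1.  Classification is
argmax_c P(c) prod_i P(a_i | a_hp_i, c).

Numerical conventions: natural log throughout (the base cancels in the
weights); smoothed CMI estimates are clipped at 0; an all-zero CMI row has
no usable parent and falls back to the univariate conditional P(a_i | c),
which also makes the single-feature and zero-dependence cases collapse
exactly to plain NB.  The per-feature mixture is accumulated in linear
space, the product across features in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataset import DiscreteDataset
from .nb import NBModel, _as_batch, _class_feature_counts, fit_nb

__all__ = [
    "HNBModel", "estimate_pairwise_cpts", "conditional_mutual_information",
    "compute_weights", "estimate_cmi_matrix", "fit_hnb", "hnb_posterior",
    "hnb_predict",
]

_CMI_TOL = 1e-12


@dataclass
class HNBModel:
    """Fitted HNB: embedded NB, pairwise CPTs, CMI matrix, hidden-parent weights.

    ``pair_cond[i, j, u, v, c] = P(a_i = u | a_j = v, c)`` for ``i != j``
    (the diagonal block is unused).  ``cmi`` is symmetric with zero
    diagonal; ``weights`` rows sum to 1 except flagged ``no_parent`` rows.
    """

    nb: NBModel
    pair_cond: np.ndarray
    cmi: np.ndarray
    weights: np.ndarray
    no_parent: np.ndarray
    alpha: float

    @property
    def n_features(self) -> int:
        return self.nb.n_features

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "prior": self.nb.prior.tolist(),
                "cond": self.nb.cond.tolist(),
                "n_categories": self.nb.n_categories.tolist(),
                "pair_cond": self.pair_cond.tolist(),
                "cmi": self.cmi.tolist(),
                "weights": self.weights.tolist(),
                "no_parent": self.no_parent.astype(bool).tolist(),
                "class_names": self.nb.class_names,
                "feature_names": self.nb.feature_names,
            },
            sort_keys=True,
        )


def _pairwise_counts(X: np.ndarray, y: np.ndarray, n_classes: int,
                     v_max: int) -> np.ndarray:
    """counts[i, j, u, v, c] = #samples in class c with a_i=u and a_j=v."""
    n, f = X.shape
    counts = np.zeros((f, f, v_max, v_max, n_classes))
    ii = np.broadcast_to(np.arange(f)[:, None], (f, f))
    jj = np.broadcast_to(np.arange(f)[None, :], (f, f))
    for c in range(n_classes):
        Xc = X[y == c]
        if not Xc.shape[0]:
            continue
        u = np.broadcast_to(Xc[:, :, None], (Xc.shape[0], f, f))
        v = np.broadcast_to(Xc[:, None, :], (Xc.shape[0], f, f))
        np.add.at(counts[:, :, :, :, c],
                  (ii[None], jj[None], u, v), 1.0)
    return counts


def estimate_pairwise_cpts(train: DiscreteDataset, alpha: float = 1.0):
    """Smoothed pairwise conditionals and the joint they derive from.

    Returns ``(pair_cond, joint)`` where ``joint[i, j]`` is the smoothed
    probability table P(a_i, a_j, c), normalized per ordered pair, and
    ``pair_cond[i, j, u, v, c] = P(a_i = u | a_j = v, c)``.
    """
    if train.n_features < 2:
        raise ValueError("pairwise tables need >= 2 features; use plain NB")
    v_max = int(train.n_categories.max())
    n_classes = train.n_classes
    counts = _pairwise_counts(train.X, train.y, n_classes, v_max)
    V = train.n_categories.astype(float)
    valid_u = np.arange(v_max)[None, :] < train.n_categories[:, None]  # (F, V)
    cell_valid = (valid_u[:, None, :, None, None]
                  & valid_u[None, :, None, :, None])                   # (F,F,V,V,1)
    # joint over (a_i, a_j, c), smoothing spread over the V_i*V_j*|C| valid cells
    denom_joint = (train.n_samples
                   + alpha * V[:, None] * V[None, :] * n_classes)
    joint = (counts + alpha * cell_valid) / denom_joint[:, :, None, None, None]
    joint *= cell_valid
    # conditional on (a_j, c): univariate counts of a_j per class
    uni, _ = _class_feature_counts(train.X, train.y, n_classes, v_max)
    denom_cond = uni[None, :, None, :, :] + (alpha * V)[:, None, None, None, None]
    pair_cond = (counts + alpha * cell_valid) / denom_cond
    pair_cond *= cell_valid
    return pair_cond, joint


def conditional_mutual_information(joint: np.ndarray) -> float:
    """CMI I(A_i; A_j | C) in nats from a normalized joint P(a_i, a_j, c).

    ``joint`` has shape ``(V_i, V_j, n_classes)``; zero cells contribute
    zero.  The marginals are taken from the joint itself, so the result is
    nonnegative up to float round-off.
    """
    joint = np.asarray(joint, dtype=float)
    if joint.ndim != 3:
        raise ValueError("joint must be a (V_i, V_j, n_classes) table")
    total = joint.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"joint not normalized (sums to {total!r})")
    p_c = joint.sum(axis=(0, 1))          # P(c)
    p_ic = joint.sum(axis=1)              # P(a_i, c)
    p_jc = joint.sum(axis=0)              # P(a_j, c)
    num = joint * p_c[None, None, :]
    den = p_ic[:, None, :] * p_jc[None, :, :]
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, joint * np.log(np.where(mask, num / den, 1.0)), 0.0)
    return float(terms.sum())


def _cmi_all_pairs(joint: np.ndarray) -> np.ndarray:
    """Vectorized CMI for every ordered pair from (F, F, V, V, C) joints."""
    p_c = joint.sum(axis=(2, 3))                      # (F, F, C)
    p_ic = joint.sum(axis=3)                          # (F, F, V, C)
    p_jc = joint.sum(axis=2)                          # (F, F, V, C)
    num = joint * p_c[:, :, None, None, :]
    den = p_ic[:, :, :, None, :] * p_jc[:, :, None, :, :]
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(mask, joint * np.log(np.where(mask, num / den, 1.0)), 0.0)
    cmi = terms.sum(axis=(2, 3, 4))
    np.fill_diagonal(cmi, 0.0)
    return np.clip(cmi, 0.0, None)


def estimate_cmi_matrix(train: DiscreteDataset, alpha: float = 1.0) -> np.ndarray:
    """Estimated CMI matrix I(A_i; A_j | C) for every feature pair.

    Works for single-class data too (conditioning on a constant class),
    which is how the dependent-chain fixtures validate the estimator.
    """
    _, joint = estimate_pairwise_cpts(train, alpha)
    cmi = _cmi_all_pairs(joint)
    return 0.5 * (cmi + cmi.T)


def compute_weights(cmi: np.ndarray):
    """Row-normalize a CMI matrix into hidden-parent weights.

    Returns ``(W, no_parent)``; rows with zero total CMI carry no weights
    and are flagged so prediction can fall back to P(a_i | c).
    """
    cmi = np.asarray(cmi, dtype=float)
    if cmi.ndim != 2 or cmi.shape[0] != cmi.shape[1]:
        raise ValueError("cmi must be square")
    if np.any(cmi < -_CMI_TOL):
        raise ValueError("negative CMI entry; clip numerical CMI at 0 upstream")
    cmi = np.clip(cmi, 0.0, None)
    cmi = cmi.copy()
    np.fill_diagonal(cmi, 0.0)
    row_sum = cmi.sum(axis=1)
    no_parent = row_sum <= 0.0
    W = np.zeros_like(cmi)
    np.divide(cmi, row_sum[:, None], out=W, where=~no_parent[:, None])
    return W, no_parent


def fit_hnb(train: DiscreteDataset, alpha: float = 1.0) -> HNBModel:
    """Fit the full HNB model: NB tables, pairwise CPTs, CMI, weights."""
    nb = fit_nb(train, alpha)
    f = train.n_features
    if f < 2:
        v_max = int(train.n_categories.max())
        return HNBModel(nb=nb,
                        pair_cond=np.zeros((f, f, v_max, v_max, nb.n_classes)),
                        cmi=np.zeros((f, f)), weights=np.zeros((f, f)),
                        no_parent=np.ones(f, dtype=bool), alpha=alpha)
    pair_cond, joint = estimate_pairwise_cpts(train, alpha)
    cmi = _cmi_all_pairs(joint)
    cmi = 0.5 * (cmi + cmi.T)  # exact symmetry against round-off
    W, no_parent = compute_weights(cmi)
    return HNBModel(nb=nb, pair_cond=pair_cond, cmi=cmi, weights=W,
                    no_parent=no_parent, alpha=alpha)


def _subset_weights(model: HNBModel, subset: np.ndarray):
    """Hidden-parent weights renormalized over a feature subset.

    The pairwise CPTs and CMI are per-pair quantities, so restricting the
    model to a subset and renormalizing the weight rows reproduces exactly
    the model one would get by refitting on those features.
    """
    cmi_s = model.cmi[np.ix_(subset, subset)].copy()
    np.fill_diagonal(cmi_s, 0.0)
    return compute_weights(cmi_s)


def hnb_posterior(model: HNBModel, sample, feature_subset=None,
                  _chunk_cells: int = 4_000_000) -> np.ndarray:
    """Normalized per-class HNB posterior for one sample or a batch.

    ``feature_subset`` restricts the model to those features with weights
    renormalized accordingly (used heavily by backward elimination).
    """
    X, single = _as_batch(sample)
    if X.shape[1] != model.n_features:
        raise ValueError("sample width does not match the model")
    subset = (np.arange(model.n_features) if feature_subset is None
              else np.asarray(feature_subset, dtype=np.int64))
    s = subset.size
    if s == 0:
        raise ValueError("feature subset is empty")
    n = X.shape[0]
    prior = model.nb.prior
    n_classes = prior.shape[0]
    if s == 1 or model.no_parent.all():
        from .nb import nb_posterior
        post = nb_posterior(model.nb, X, feature_subset=subset)
        return post[0] if single and post.ndim == 2 else post
    W, no_parent = _subset_weights(model, subset)
    A = model.pair_cond[np.ix_(subset, subset)]       # (s, s, V, V, C)
    Xs = X[:, subset]
    log_post = np.empty((n, n_classes))
    chunk = max(1, _chunk_cells // max(1, s * s * n_classes))
    ii = np.broadcast_to(np.arange(s)[:, None], (s, s))
    jj = np.broadcast_to(np.arange(s)[None, :], (s, s))
    for start in range(0, n, chunk):
        xb = Xs[start:start + chunk]
        nb_ = xb.shape[0]
        u = np.broadcast_to(xb[:, :, None], (nb_, s, s))
        v = np.broadcast_to(xb[:, None, :], (nb_, s, s))
        term = A[ii[None], jj[None], u, v]            # (nb, s, s, C)
        mix = np.einsum("ij,nijc->nic", W, term)
        if no_parent.any():
            rows = np.where(no_parent)[0]
            mix[:, rows, :] = model.nb.cond[subset[rows][None, :],
                                            xb[:, rows], :]
        if np.any(mix <= 0):
            raise ValueError(
                "zero mixture probability; refit with alpha > 0")
        log_post[start:start + chunk] = (
            np.log(prior)[None, :] + np.log(mix).sum(axis=1))
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    return post[0] if single else post


def hnb_predict(model: HNBModel, sample, feature_subset=None):
    """argmax class of :func:`hnb_posterior`; ties break to the smallest index."""
    post = hnb_posterior(model, sample, feature_subset)
    return int(np.argmax(post)) if post.ndim == 1 else np.argmax(post, axis=1)
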