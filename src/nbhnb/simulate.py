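"""Synthetic -omics generators with planted ground truth.

Three fixture families cover the input types the framework targets:

* Gaussian expression matrices — null features are standard normal in both
  classes; a small planted set is mean-shifted by ``effect`` SD units in
  the case class (emulating differentially expressed genes among thousands
  of nulls).
* SNP genotype matrices — 0/1/2 counts drawn under Hardy-Weinberg
  equilibrium per class; planted SNPs differ in allele frequency by
  ``effect`` between classes.
* Dependent discrete chains — children copy a parent category with
  fidelity ``f`` (else resample uniformly among the *other* categories),
  giving every (child, parent) pair a closed-form conditional mutual
  information for validating the HNB estimator.

All generators are deterministic given ``spec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import DiscreteDataset
from .evaluation import stratified_kfold
from .hnb import fit_hnb, hnb_predict
from .nb import FeatureRanking

__all__ = [
    "SyntheticSpec", "generate_gaussian_omics", "generate_genotype_matrix",
    "generate_dependent_discrete", "analytic_chain_cmi",
    "resample_marker_panels",
]


@dataclass
class SyntheticSpec:
    """Parameters shared by the fixture generators.

    ``effect`` is the class-mean shift in SD units (Gaussian mode) or the
    allele-frequency difference between classes (genotype mode).
    ``dependencies`` lists ``(child, parent, fidelity)`` triples for the
    discrete-chain mode; fidelity lives in [1/V, 1] with 1/V meaning
    independence (for binary features that is 0.5).
    """

    n_samples: int = 200
    n_features: int = 1000
    n_informative: int = 10
    effect: float = 2.0
    class_balance: float = 0.5
    n_classes: int = 2
    n_categories: int = 2
    dependencies: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must be in (0, 1)")
        for child, parent, f in self.dependencies:
            if not (0.0 <= f <= 1.0):
                raise ValueError("copy fidelity must be in [0, 1]")


def _labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Deterministic class sizes: round(balance * n) cases, shuffled."""
    if spec.n_classes == 1:
        return np.zeros(spec.n_samples, dtype=np.int64)
    n_case = int(round(spec.class_balance * spec.n_samples))
    y = np.zeros(spec.n_samples, dtype=np.int64)
    y[:n_case] = 1
    rng.shuffle(y)
    return y


def generate_gaussian_omics(spec: SyntheticSpec):
    """Two-class Gaussian expression matrix with planted shifted features.

    Returns ``(X, y, informative_ids)``: continuous matrix, 0/1 labels
    (1 = case), and the indices of the ``n_informative`` features whose
    case-class mean is shifted by ``effect`` standard deviations.
    """
    rng = np.random.default_rng(spec.seed)
    y = _labels(spec, rng)
    X = rng.standard_normal((spec.n_samples, spec.n_features))
    informative = rng.choice(spec.n_features, size=spec.n_informative,
                             replace=False)
    informative = np.sort(informative)
    X[np.ix_(y == 1, informative)] += spec.effect
    return X, y, informative


def generate_genotype_matrix(spec: SyntheticSpec, base_freq_range=(0.2, 0.8)):
    """SNP matrix of 0/1/2 minor-allele counts under HWE per class.

    Null SNPs share one allele frequency across classes; informative SNPs
    use ``p - effect/2`` in controls and ``p + effect/2`` in cases with
    ``p = 0.5``.  Frequencies must stay inside [0.05, 0.95].
    """
    rng = np.random.default_rng(spec.seed)
    y = _labels(spec, rng)
    lo, hi = base_freq_range
    freqs = rng.uniform(lo, hi, size=spec.n_features)
    informative = np.sort(rng.choice(spec.n_features, size=spec.n_informative,
                                     replace=False))
    p_by_class = np.tile(freqs, (2, 1))  # (class, snp)
    p_by_class[0, informative] = 0.5 - spec.effect / 2
    p_by_class[1, informative] = 0.5 + spec.effect / 2
    if np.any(p_by_class < 0.05) or np.any(p_by_class > 0.95):
        raise ValueError("allele frequency outside [0.05, 0.95]")
    X = np.empty((spec.n_samples, spec.n_features), dtype=np.int64)
    for c in (0, 1):
        rows = y == c
        X[rows] = rng.binomial(2, p_by_class[c][None, :],
                               size=(int(rows.sum()), spec.n_features))
    return X, y, informative


def analytic_chain_cmi(fidelity: float, n_categories: int) -> float:
    """Population CMI (nats) of a child copying a uniform parent.

    The child equals the parent with probability ``f`` and otherwise is
    uniform over the remaining ``V - 1`` categories, independently of the
    class, so I(child; parent | class) = log V + f log f
    + (1 - f) log((1 - f)/(V - 1)).  At f = 1/V the pair is independent
    (CMI 0); at f = 1 the copy is deterministic (CMI log V).
    """
    V = n_categories
    f = fidelity
    h = 0.0
    if f > 0:
        h += f * math.log(f)
    if f < 1:
        h += (1 - f) * math.log((1 - f) / (V - 1))
    return math.log(V) + h


def generate_dependent_discrete(spec: SyntheticSpec):
    """Discrete dataset with known pairwise conditional dependencies.

    Root features (those never listed as a child) are uniform over
    ``n_categories``; each child copies its parent with the stated
    fidelity.  Returns ``(DiscreteDataset, {(child, parent): cmi})`` with
    the analytic population CMI per dependent pair.
    """
    rng = np.random.default_rng(spec.seed)
    V = spec.n_categories
    deps = list(spec.dependencies)
    children = [c for c, _, _ in deps]
    if len(set(children)) != len(children):
        raise ValueError("each feature may have at most one parent")
    # topological order; cycles are rejected
    order, placed = [], set()
    parent_of = {c: p for c, p, _ in deps}
    remaining = set(range(spec.n_features))
    while remaining:
        progress = False
        for i in sorted(remaining):
            p = parent_of.get(i)
            if p is None or p in placed:
                order.append(i)
                placed.add(i)
                remaining.discard(i)
                progress = True
        if not progress:
            raise ValueError("dependency structure contains a cycle")
    fidelity = {c: f for c, _, f in deps}
    X = np.empty((spec.n_samples, spec.n_features), dtype=np.int64)
    for i in order:
        if i not in parent_of:
            X[:, i] = rng.integers(0, V, size=spec.n_samples)
        else:
            f = fidelity[i]
            parent = X[:, parent_of[i]]
            copy = rng.random(spec.n_samples) < f
            # uniform over the V-1 categories other than the parent's value
            shift = rng.integers(1, V, size=spec.n_samples)
            X[:, i] = np.where(copy, parent, (parent + shift) % V)
    y = _labels(spec, rng)
    data = DiscreteDataset(X, y, n_categories=np.full(spec.n_features, V))
    cmi = {(c, p): analytic_chain_cmi(f, V) for c, p, f in deps}
    return data, cmi


def resample_marker_panels(data: DiscreteDataset, ranking: FeatureRanking,
                           panel_size: int = 20, source: str = "top_ranked",
                           n_draws: int = 100, cv_folds: int = 10,
                           seed: int = 0, alpha: float = 1.0) -> np.ndarray:
    """Accuracy distribution of random marker panels from a ranking stratum.

    Panels of ``panel_size`` markers are drawn with replacement from either
    the selected top-ranked stratum or the lower-ranked remainder; each
    panel is scored by HNB stratified ``cv_folds``-fold CV accuracy.
    Returns the ``n_draws`` accuracies.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if ranking.selected is None:
        raise ValueError("ranking has no selection; run select_top first")
    selected = np.asarray(ranking.selected)
    if source == "top_ranked":
        stratum = selected
    elif source == "lower_ranked":
        stratum = np.asarray([f for f in ranking.order if f not in set(selected.tolist())])
    else:
        raise ValueError(f"unknown source {source!r}")
    if stratum.size == 0:
        raise ValueError(f"stratum {source!r} is empty")
    rng = np.random.default_rng(seed)
    folds = stratified_kfold(data.y, k=cv_folds, seed=seed)
    accs = np.empty(n_draws)
    for d in range(n_draws):
        panel = rng.choice(stratum, size=panel_size, replace=True)
        sub = data.subset_features(panel)
        correct = 0
        for tr, te in folds:
            model = fit_hnb(sub.subset_samples(tr), alpha=alpha)
            pred = hnb_predict(model, sub.X[te])
            correct += int(np.sum(pred == sub.y[te]))
        accs[d] = correct / data.n_samples
    return accs
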