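"""Equal-width discretization of continuous signal matrices.

Continuous omics signals (expression intensities, SELDI-TOF peaks) are
binned into ``n_bins`` intervals of equal width over the training range of
each feature before any Bayes modelling.  Bin edges are always fit on
training data only; blind/test values falling outside the training range
clamp to the extreme bins so no unseen category can appear downstream.

Interval convention: left-closed / right-open, except the last bin which is
closed, so the training maximum maps to bin ``n_bins - 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataset import DiscreteDataset

__all__ = ["DiscretizationSpec", "fit_equal_width", "transform", "discretize"]


@dataclass
class DiscretizationSpec:
    """Fitted equal-width binning: interior edges per feature.

    ``edges`` has shape ``(n_features, n_bins - 1)`` with strictly
    ascending interior cut points per row; rows of features whose training
    range was zero are marked ``degenerate`` and map everything to bin 0.
    """

    edges: np.ndarray
    n_bins: int
    degenerate: np.ndarray
    equal_interval: bool = True

    @property
    def n_features(self) -> int:
        return self.edges.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_bins": self.n_bins,
                "equal_interval": self.equal_interval,
                "degenerate": self.degenerate.astype(bool).tolist(),
                "edges": self.edges.tolist(),
            },
            sort_keys=True,
        )

    @staticmethod
    def from_json(text: str) -> "DiscretizationSpec":
        d = json.loads(text)
        return DiscretizationSpec(
            edges=np.asarray(d["edges"], dtype=float),
            n_bins=int(d["n_bins"]),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
            equal_interval=bool(d["equal_interval"]),
        )


def _check_finite(X: np.ndarray) -> None:
    bad = ~np.isfinite(X)
    if bad.any():
        e, i = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value at sample {e}, feature {i}; "
            "clean or impute the matrix before discretization"
        )


def fit_equal_width(X, n_bins: int) -> DiscretizationSpec:
    """Fit per-feature equal-width bin edges on a training matrix.

    For a feature with training range ``[lo, hi]`` the interior edges sit
    at ``lo + k (hi - lo) / n_bins`` for ``k = 1 .. n_bins - 1``.  Features
    with zero range are flagged degenerate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one sample and feature")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    _check_finite(X)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    degenerate = hi == lo
    k = np.arange(1, n_bins)
    edges = lo[:, None] + k[None, :] * ((hi - lo) / n_bins)[:, None]
    edges[degenerate] = 0.0
    return DiscretizationSpec(edges=edges, n_bins=n_bins, degenerate=degenerate)


def transform(X, spec: DiscretizationSpec) -> np.ndarray:
    """Map a continuous matrix to bin indices in ``[0, n_bins - 1]``.

    Out-of-range values clamp to the extreme bins.  Returns an integer
    matrix of the same shape; pair with labels via :func:`discretize` to
    obtain a :class:`~nbhnb.dataset.DiscreteDataset`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.n_features:
        raise ValueError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} features, "
            f"spec was fit on {spec.n_features}"
        )
    _check_finite(X)
    codes = np.empty(X.shape, dtype=np.int64)
    for i in range(spec.n_features):
        if spec.degenerate[i]:
            codes[:, i] = 0
        else:
            # side='right': a value equal to an interior edge joins the
            # upper bin (left-closed intervals); values past the last edge
            # land in bin n_bins-1, which also clamps values > training max.
            codes[:, i] = np.searchsorted(spec.edges[i], X[:, i], side="right")
    return codes


def discretize(X, y, n_bins: int = 10, spec: DiscretizationSpec | None = None,
               feature_names=None):
    """Fit (unless ``spec`` given) and apply equal-width binning.

    Returns ``(DiscreteDataset, DiscretizationSpec)``.  Every feature is
    assigned cardinality ``n_bins`` so train and blind splits share one
    category space.
    """
    if spec is None:
        spec = fit_equal_width(X, n_bins)
    codes = transform(X, spec)
    n_cat = np.full(spec.n_features, spec.n_bins, dtype=np.int64)
    data = DiscreteDataset.from_labels(codes, y, n_categories=n_cat,
                                       feature_names=feature_names)
    return data, spec
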