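"""Categorical sample matrix shared by every modelling stage.

A :class:`DiscreteDataset` holds the samples-by-features matrix after
binning (or raw categorical input such as 0/1/2 genotypes), integer class
labels, and the per-feature category cardinalities the smoothed estimators
need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DiscreteDataset"]


@dataclass
class DiscreteDataset:
    """Discrete samples-by-features matrix with class labels.

    Parameters
    ----------
    X
        Integer matrix of shape ``(n_samples, n_features)``; entry
        ``X[e, i]`` is the category index of attribute ``i`` in sample
        ``e`` and must lie in ``[0, n_categories[i])``.
    y
        Integer class indices of shape ``(n_samples,)`` in
        ``[0, n_classes)``.
    n_categories
        Per-feature cardinality ``V_i``.  Inferred as ``max + 1`` per
        column when omitted.
    class_names, feature_names
        Optional human-readable names aligned with the integer codes.
    """

    X: np.ndarray
    y: np.ndarray
    n_categories: np.ndarray = None
    class_names: list = None
    feature_names: list = None
    n_classes: int = field(init=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"y has shape {self.y.shape}, expected ({self.X.shape[0]},)"
            )
        if not np.issubdtype(self.X.dtype, np.integer):
            if not np.all(self.X == np.floor(self.X)):
                raise ValueError("X must contain integer category codes")
            self.X = self.X.astype(np.int64)
        if not np.issubdtype(self.y.dtype, np.integer):
            raise ValueError("y must contain integer class indices")
        if self.X.size and self.X.min() < 0:
            raise ValueError("category codes must be non-negative")
        if self.n_categories is None:
            self.n_categories = (
                self.X.max(axis=0) + 1 if self.X.size else np.ones(self.X.shape[1])
            )
        self.n_categories = np.asarray(self.n_categories, dtype=np.int64)
        if self.n_categories.shape != (self.X.shape[1],):
            raise ValueError("n_categories must have one entry per feature")
        if self.X.size and np.any(self.X >= self.n_categories[None, :]):
            raise ValueError("category code exceeds declared cardinality")
        self.n_classes = int(self.y.max()) + 1 if self.y.size else 0
        if self.class_names is not None and len(self.class_names) < self.n_classes:
            raise ValueError("fewer class names than observed classes")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_samples(self, idx) -> "DiscreteDataset":
        """Row subset sharing cardinalities and names."""
        return DiscreteDataset(
            self.X[idx], self.y[idx], self.n_categories,
            self.class_names, self.feature_names,
        )

    def subset_features(self, idx) -> "DiscreteDataset":
        idx = np.asarray(idx)
        names = (
            [self.feature_names[i] for i in idx]
            if self.feature_names is not None else None
        )
        return DiscreteDataset(
            self.X[:, idx], self.y, self.n_categories[idx],
            self.class_names, names,
        )

    @staticmethod
    def from_labels(X, labels, n_categories=None, feature_names=None) -> "DiscreteDataset":
        """Build from arbitrary (hashable) label values; codes follow sorted label order."""
        classes, y = np.unique(np.asarray(labels), return_inverse=True)
        return DiscreteDataset(
            np.asarray(X), y.astype(np.int64), n_categories,
            class_names=[str(c) for c in classes], feature_names=feature_names,
        )
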