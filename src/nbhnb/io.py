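"""Readers and writers for delimited matrices and ARFF files.

Samples are rows and features are columns; microarray files shipped
transposed can be flipped with ``transpose=True``.  CSV/TSV must carry a
header row and a designated class column.  ARFF numeric attributes load as
continuous features, nominal attributes as discrete categories with their
declared category order preserved.
"""

from __future__ import annotations

import io as _io
import os

import numpy as np
import pandas as pd
from scipy.io import arff as _scipy_arff

__all__ = ["read_matrix", "write_csv", "write_arff", "detect_discrete"]


def _from_frame(df: pd.DataFrame, class_column: str, transpose: bool):
    if transpose:
        df = df.T
    if class_column not in df.columns:
        raise ValueError(f"class column {class_column!r} not found")
    names = [c for c in df.columns if c != class_column]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature names: {dupes}")
    y = df[class_column].to_numpy()
    feat = df[names]
    try:
        X = feat.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in a feature column: {exc}") from exc
    return X, y, [str(n) for n in names]


def read_matrix(path, fmt: str | None = None, class_column: str = "class",
                transpose: bool = False):
    """Load ``(X, labels, feature_names)`` from CSV, TSV or ARFF.

    ``fmt`` defaults from the file extension.  ARFF nominal feature
    attributes are returned as integer category codes following the
    declared order; the class attribute keeps its raw values.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower().lstrip(".")
        fmt = {"csv": "csv", "tsv": "tsv", "arff": "arff"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path!r}; pass fmt=")
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        names = [h for h in header if h != class_column]
        if len(set(names)) != len(names):  # pandas would silently mangle these
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        df = pd.read_csv(path, sep=sep)
        return _from_frame(df, class_column, transpose)
    if fmt != "arff":
        raise ValueError(f"unsupported format {fmt!r}")
    raw, meta = _scipy_arff.loadarff(str(path))
    df = pd.DataFrame(raw)
    if class_column not in df.columns:
        raise ValueError(f"class column {class_column!r} not found")
    names = [c for c in df.columns if c != class_column]
    cols = []
    for name in names:
        kind, cats = meta[name]
        col = df[name]
        if kind == "numeric":
            cols.append(col.to_numpy(dtype=float))
        else:  # nominal: map onto declared category order
            values = col.map(lambda b: b.decode() if isinstance(b, bytes) else b)
            lookup = {c: i for i, c in enumerate(cats)}
            try:
                cols.append(values.map(lookup).to_numpy(dtype=float))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"undeclared nominal value in attribute {name!r}") from exc
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    if transpose:
        raise ValueError("transpose is not supported for ARFF input")
    y = df[class_column].to_numpy()
    y = np.array([v.decode() if isinstance(v, bytes) else v for v in y])
    return X, y, [str(n) for n in names]


def detect_discrete(X: np.ndarray, max_levels: int = 20) -> bool:
    """Heuristic: every column integer-valued with <= ``max_levels`` levels."""
    X = np.asarray(X)
    if not np.all(np.isfinite(X)):
        return False
    if not np.all(X == np.floor(X)):
        return False
    return all(np.unique(X[:, i]).size <= max_levels for i in range(X.shape[1]))


def write_csv(path, X, labels, feature_names=None, class_column: str = "class",
              sep: str = ",") -> None:
    """Write a samples-by-features matrix plus labels as delimited text."""
    X = np.asarray(X)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=feature_names)
    df[class_column] = np.asarray(labels)
    df.to_csv(path, sep=sep, index=False)


def write_arff(path, X, labels, feature_names=None, relation: str = "nbhnb",
               class_column: str = "class", nominal: bool | None = None) -> None:
    """Write an ARFF file; discrete matrices become nominal attributes.

    ``nominal`` defaults to :func:`detect_discrete` on the matrix.
    """
    X = np.asarray(X)
    labels = np.asarray(labels)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if nominal is None:
        nominal = detect_discrete(X)
    buf = _io.StringIO()
    buf.write(f"@relation {relation}\n\n")
    for i, name in enumerate(feature_names):
        if nominal:
            levels = ",".join(str(int(v)) for v in np.unique(X[:, i]))
            buf.write(f"@attribute {name} {{{levels}}}\n")
        else:
            buf.write(f"@attribute {name} numeric\n")
    classes = ",".join(str(c) for c in np.unique(labels))
    buf.write(f"@attribute {class_column} {{{classes}}}\n\n@data\n")
    for row, lab in zip(X, labels):
        if nominal:
            cells = [str(int(v)) for v in row]
        else:
            cells = [repr(float(v)) for v in row]
        buf.write(",".join(cells + [str(lab)]) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
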