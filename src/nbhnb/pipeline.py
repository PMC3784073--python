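"""End-to-end two-step Bayes pipeline.

Stage order: blind holdout -> equal-width discretization (continuous input
only, edges fit on the training split) -> per-feature NB ranking ->
top-m selection -> HNB backward elimination -> final HNB refit on the full
training split with the selected panel -> single blind-set evaluation.

Defaults follow the framework's standard settings: 10 bins, accuracy
threshold 0.75, cap m = 40, 10-fold CV, 10% blind holdout, Laplace alpha 1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .dataset import DiscreteDataset
from .discretize import discretize
from .evaluation import EvaluationReport, compute_metrics, holdout_split
from .hnb import fit_hnb, hnb_posterior
from .io import detect_discrete, read_matrix
from .nb import rank_features, select_top
from .selection import backward_eliminate

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline settings; every default matches the standard protocol."""

    input_path: str = None
    fmt: str = None                  # csv | tsv | arff (inferred if None)
    class_column: str = "class"
    transpose: bool = False
    discrete: bool = None            # None = auto-detect (logged)
    n_bins: int = 10
    threshold: float = 0.75
    cap: int = 40
    alpha: float = 1.0
    cv_folds: int = 10
    holdout_fraction: float = 0.10
    seed: int = 0
    ranking_scheme: str = "single_feature_accuracy"
    accuracy_mode: str = "cv"        # cv | resubstitution
    output_dir: str = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass
class RunResult:
    config: RunConfig
    ranking: object
    trace: object
    panel: tuple
    panel_names: list
    model: object
    report: EvaluationReport
    log: dict = field(default_factory=dict)


def _log_entry(config: RunConfig, detected_discrete: bool) -> dict:
    # output_dir is not part of the scientific configuration: exclude it so
    # identical analyses hash (and serialize) identically wherever they land
    cfg = {k: v for k, v in dataclasses.asdict(config).items()
           if k != "output_dir"}
    cfg_json = json.dumps(cfg, sort_keys=True)
    return {
        "nbhnb_version": __version__,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_treated_as_discrete": bool(detected_discrete),
    }


def run_pipeline(config: RunConfig, data=None) -> RunResult:
    """Run the full framework; ``data=(X, labels, feature_names)`` bypasses file IO.

    Writes ranking/trace/model/report artifacts to ``config.output_dir``
    when set.  Every stage derives its randomness from ``config.seed``.
    """
    if data is None:
        if config.input_path is None:
            raise ValueError("provide config.input_path or data=")
        X, labels, feature_names = read_matrix(
            config.input_path, fmt=config.fmt,
            class_column=config.class_column, transpose=config.transpose)
    else:
        X, labels, feature_names = data
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(np.asarray(X).shape[1])]
    X = np.asarray(X)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    y = y.astype(np.int64)

    is_discrete = config.discrete
    if is_discrete is None:
        is_discrete = detect_discrete(X)
    log = _log_entry(config, is_discrete)

    train_idx, blind_idx = holdout_split(
        y, fraction=config.holdout_fraction, seed=config.seed)
    if is_discrete:
        codes = X.astype(np.int64)
        n_cat = codes.max(axis=0) + 1
        train = DiscreteDataset(codes[train_idx], y[train_idx], n_cat,
                                class_names=[str(c) for c in classes],
                                feature_names=feature_names)
        blind = DiscreteDataset(codes[blind_idx], y[blind_idx], n_cat,
                                class_names=[str(c) for c in classes],
                                feature_names=feature_names)
        disc_spec = None
    else:
        train, disc_spec = discretize(X[train_idx], y[train_idx],
                                      n_bins=config.n_bins,
                                      feature_names=feature_names)
        blind, _ = discretize(X[blind_idx], y[blind_idx], spec=disc_spec,
                              feature_names=feature_names)
        train.class_names = [str(c) for c in classes]
        blind.class_names = [str(c) for c in classes]

    ranking = rank_features(train, scheme=config.ranking_scheme,
                            cv_folds=config.cv_folds, seed=config.seed,
                            alpha=config.alpha)
    ranking = select_top(ranking, threshold=config.threshold, cap=config.cap)
    trace = backward_eliminate(train, ranking, cv_folds=config.cv_folds,
                               seed=config.seed, alpha=config.alpha,
                               accuracy_mode=config.accuracy_mode)
    panel = trace.selected
    panel_idx = np.asarray(panel, dtype=np.int64)
    model = fit_hnb(train.subset_features(panel_idx), alpha=config.alpha)

    # the blind set is touched exactly once, here
    blind_sub = blind.subset_features(panel_idx)
    post = hnb_posterior(model, blind_sub.X)
    pred = np.argmax(post, axis=1)
    pos_idx = int(np.argmax([str(c) for c in classes])) if classes.size == 2 else None
    report = compute_metrics(
        truth=blind.y, predicted=pred,
        positive_scores=post[:, pos_idx] if pos_idx is not None else None,
        positive_class=pos_idx,
        panel_size=len(panel),
        protocol={"blind_fraction": config.holdout_fraction,
                  "cv_folds": config.cv_folds, "seed": config.seed},
    )
    if pos_idx is not None:
        report.positive_class = str(classes[pos_idx])
    panel_names = [feature_names[i] for i in panel_idx]
    result = RunResult(config=config, ranking=ranking, trace=trace,
                       panel=panel, panel_names=panel_names, model=model,
                       report=report, log=log)
    if config.output_dir:
        _write_artifacts(result, disc_spec)
    return result


def _write_artifacts(result: RunResult, disc_spec) -> None:
    out = result.config.output_dir
    os.makedirs(out, exist_ok=True)
    def _put(name, text):
        with open(os.path.join(out, name), "w") as fh:
            fh.write(text)
    _put("ranking.tsv", result.ranking.to_tsv())
    _put("trace.tsv", result.trace.to_tsv())
    _put("trace.json", result.trace.to_json())
    _put("model.json", result.model.to_json())
    _put("report.json", result.report.to_json())
    _put("report.txt", result.report.to_text())
    _put("run_log.json", json.dumps(result.log, sort_keys=True, indent=2))
    _put("panel.json", json.dumps(
        {"panel": [int(f) for f in result.panel],
         "panel_names": result.panel_names}, sort_keys=True))
    if disc_spec is not None:
        _put("discretization.json", disc_spec.to_json())
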