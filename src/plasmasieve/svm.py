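"""SVM-based false-positive removal with nested leave-one-patient-out CV.

Variant filtering is posed as binary classification against hotspot-panel
ground truth in the regions shared by both panels.  Hyperparameters (linear
kernel x 11 C values, RBF kernel x 11 C x 11 gamma values; 132 candidate
configurations) are tuned by stratified fourfold cross-validation on the
training patients' pooled calls; evaluation holds out one whole patient per
outer iteration.  The feature standardizer is refit inside every training
split, never on held-out rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import (
    ALL_FEATURE_NAMES,
    FeatureVector,
    N_FEATURES,
    Standardizer,
    fit_standardizer,
)
from .metrics import MetricsReport, compute_metrics, f1_from_pr_rc
from .rules import FilterRule, apply_rule, select_rule_cv
from .variant_io import VariantCall, VariantKey

log = logging.getLogger(__name__)

PARAM_GRID = (1e-4, 1e-3, 1e-2, 0.1, 0.5, 1, 2, 5, 10, 20, 50)


@dataclass(frozen=True)
class SvmConfig:
    kernel: Literal["linear", "rbf"]
    C: float
    gamma: float | None = None  # rbf only
    decision_threshold: float = 0.0


def hyperparameter_grid() -> list[SvmConfig]:
    """Candidate configurations in deterministic order: linear C sweep, then
    RBF (C-major, gamma-minor); 11 + 121 = 132 entries."""
    grid = [SvmConfig("linear", c) for c in PARAM_GRID]
    grid += [SvmConfig("rbf", c, g) for c in PARAM_GRID for g in PARAM_GRID]
    return grid


@dataclass
class LabeledVariant:
    """A ground-truth-labeled call.

    ``label`` is True when the hotspot panel called the same variant in the
    same patient.  Hotspot variants with no matching call on the large panel
    are represented as label-only rows (``features is None``): they are
    false negatives of every filtering strategy and never enter training.
    """

    patient_id: str
    key: VariantKey
    label: bool
    features: FeatureVector | None = None
    call: VariantCall | None = None


@dataclass
class SvmModel:
    config: SvmConfig
    standardizer: Standardizer
    classifier: SVC
    feature_names: tuple[str, ...] = ALL_FEATURE_NAMES
    training_fingerprint: str = ""

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "SvmModel":
        model = joblib.load(path)
        if not isinstance(model, SvmModel):
            raise TypeError(f"{path} does not contain an SvmModel")
        return model


def _design_matrix(rows: Sequence[LabeledVariant]) -> tuple[np.ndarray, np.ndarray]:
    feat_rows = [r for r in rows if r.features is not None]
    X = np.vstack([r.features.values for r in feat_rows]) if feat_rows else np.empty((0, N_FEATURES))
    y = np.array([bool(r.label) for r in feat_rows])
    return X, y


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = joblib.hash((np.ascontiguousarray(X), np.ascontiguousarray(y)))
    return str(h)


def _fit_svc(config: SvmConfig, X: np.ndarray, y: np.ndarray) -> SVC:
    svc = SVC(
        kernel=config.kernel,
        C=config.C,
        gamma=config.gamma if config.kernel == "rbf" else "scale",
        random_state=0,
    )
    svc.fit(X, y)
    return svc


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    # redraw with successive seeds if a training fold loses a class
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        try:
            splits = list(skf.split(np.zeros((len(y), 1)), y))
        except ValueError as exc:
            raise ValueError(f"cannot form {folds} stratified folds: {exc}") from exc
        if all(len(np.unique(y[tr])) == 2 for tr, _ in splits):
            if attempt:
                log.info("fold assignment redrawn %d time(s) to avoid single-class folds", attempt)
            return splits
    raise ValueError("could not form folds with both classes in every training split")


def tune_hyperparameters(
    train: Sequence[LabeledVariant],
    folds: int = 4,
    seed: int = 0,
) -> SvmConfig:
    """Grid-search kernel/C/gamma by mean stratified-fourfold F1.

    The standardizer is refit on each fold's training rows; ties break
    toward the earlier configuration in grid order.
    """
    X, y = _design_matrix(train)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for tuning")
    splits = _stratified_folds(y, folds, seed)
    grid = hyperparameter_grid()
    mean_f1 = np.zeros(len(grid))
    for tr_idx, te_idx in splits:
        s = fit_standardizer(X[tr_idx])
        Xtr, Xte = s.transform(X[tr_idx]), s.transform(X[te_idx])
        ytr, yte = y[tr_idx], y[te_idx]
        for gi, config in enumerate(grid):
            svc = _fit_svc(config, Xtr, ytr)
            pred = svc.decision_function(Xte) >= config.decision_threshold
            tp = int(np.sum(pred & yte))
            fp = int(np.sum(pred & ~yte))
            fn = int(np.sum(~pred & yte))
            pr = tp / (tp + fp) if tp + fp else 0.0
            rc = tp / (tp + fn) if tp + fn else 0.0
            mean_f1[gi] += f1_from_pr_rc(pr, rc) / len(splits)
    return grid[int(np.argmax(mean_f1))]


def train(rows: Sequence[LabeledVariant], config: SvmConfig) -> SvmModel:
    """Fit the classifier (and its own standardizer) on labeled rows."""
    X, y = _design_matrix(rows)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    standardizer = fit_standardizer(X)
    svc = _fit_svc(config, standardizer.transform(X), y)
    return SvmModel(
        config=config,
        standardizer=standardizer,
        classifier=svc,
        training_fingerprint=_fingerprint(X, y),
    )


def predict(
    model: SvmModel,
    features: Sequence[FeatureVector] | np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Decision scores and thresholded keep/remove labels.

    The default threshold 0 is the operating point used downstream; passing
    a different threshold supports precision-recall sweeps.
    """
    if threshold is None:
        threshold = model.config.decision_threshold
    if isinstance(features, np.ndarray):
        X = np.atleast_2d(features)
    else:
        X = np.vstack([f.values for f in features]) if len(features) else np.empty((0, N_FEATURES))
    if X.shape[-1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES}-dimensional features, got {X.shape[-1]}")
    if X.shape[0] == 0:
        return np.array([], dtype=bool), np.array([])
    scores = model.classifier.decision_function(model.standardizer.transform(X))
    return scores >= threshold, scores


@dataclass
class LopoResult:
    per_patient: list[tuple[str, MetricsReport]]
    pooled: MetricsReport
    chosen_configs: list[tuple[str, object]]
    tuner_fingerprints: list[tuple[str, frozenset]] = field(default_factory=list)


Strategy = Literal["svm", "rule", "none", "fixed"]


def _strategy_predictions(
    strategy: Strategy,
    train_rows: list[LabeledVariant],
    test_rows: list[LabeledVariant],
    inner_folds: int,
    seed: int,
    keep_predicate: Callable[[LabeledVariant], bool] | None,
) -> tuple[np.ndarray, object]:
    """Keep/remove predictions for the feature-bearing test rows."""
    if strategy == "none":
        return np.ones(len(test_rows), dtype=bool), None
    if strategy == "fixed":
        # training-free strategies, e.g. post-processing-only filtering
        if keep_predicate is None:
            raise ValueError("strategy 'fixed' requires a keep_predicate")
        return np.array([bool(keep_predicate(r)) for r in test_rows]), None
    if strategy == "rule":
        labeled = [(r.call, r.label) for r in train_rows if r.call is not None]
        rule = select_rule_cv(labeled, folds=inner_folds, seed=seed)
        kept = {id(c) for c in apply_rule(rule, [r.call for r in test_rows])}
        return np.array([id(r.call) in kept for r in test_rows]), rule
    config = tune_hyperparameters(train_rows, folds=inner_folds, seed=seed)
    model = train(train_rows, config)
    pred, _ = predict(model, [r.features for r in test_rows])
    return pred, config


def lopo_evaluate(
    cohort: Sequence[LabeledVariant],
    strategy: Strategy = "svm",
    inner_folds: int = 4,
    seed: int = 0,
    keep_predicate: Callable[[LabeledVariant], bool] | None = None,
) -> LopoResult:
    """Leave-one-patient-out evaluation of a filtering strategy.

    Each outer iteration holds out all of one patient's calls, tunes on the
    pooled calls of the remaining patients, retrains with the winning
    configuration and scores the held-out patient.  Strategies: ``svm``
    (nested tuning + retrain), ``rule`` (cutoff-grid CV), ``none`` (keep
    everything) and ``fixed`` (a training-free keep predicate, e.g.
    post-processing-only filtering).  Label-only rows
    (hotspot-panel variants the large panel never called) count as false
    negatives of every strategy.  Patients with no labeled calls contribute
    zeros to the pooled counts and are omitted from the per-patient list.
    """
    patients = sorted({r.patient_id for r in cohort})
    if len(patients) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    per_patient: list[tuple[str, MetricsReport]] = []
    chosen: list[tuple[str, object]] = []
    fingerprints: list[tuple[str, frozenset]] = []
    tp = fp = tn = fn = 0
    for held_out in patients:
        train_rows = [r for r in cohort if r.patient_id != held_out and r.features is not None]
        test_rows = [r for r in cohort if r.patient_id == held_out]
        feat_test = [r for r in test_rows if r.features is not None]
        n_label_only_pos = sum(1 for r in test_rows if r.features is None and r.label)
        fingerprints.append((held_out, frozenset(r.patient_id for r in train_rows)))
        if not test_rows:
            continue
        pred, config = _strategy_predictions(strategy, train_rows, feat_test,
                                             inner_folds, seed, keep_predicate)
        chosen.append((held_out, config))
        truth = np.array([r.label for r in feat_test], dtype=bool)
        p_tp = int(np.sum(pred & truth))
        p_fp = int(np.sum(pred & ~truth))
        p_tn = int(np.sum(~pred & ~truth))
        p_fn = int(np.sum(~pred & truth)) + n_label_only_pos
        tp, fp, tn, fn = tp + p_tp, fp + p_fp, tn + p_tn, fn + p_fn
        if p_tp + p_fp + p_tn + p_fn > 0:
            per_patient.append((held_out, compute_metrics(p_tp, p_fp, p_tn, p_fn)))
    return LopoResult(
        per_patient=per_patient,
        pooled=compute_metrics(tp, fp, tn, fn),
        chosen_configs=chosen,
        tuner_fingerprints=fingerprints,
    )


def train_final(
    cohort: Sequence[LabeledVariant],
    folds: int = 4,
    seed: int = 0,
) -> SvmModel:
    """Production model: tune on the full cohort, then refit on all rows."""
    rows = [r for r in cohort if r.features is not None]
    config = tune_hyperparameters(rows, folds=folds, seed=seed)
    return train(rows, config)
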