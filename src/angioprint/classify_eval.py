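"""Standardized 1-NN identification under stratified k-fold CV, plus metrics.

The classifier is deliberately plain: Euclidean distance, one neighbor,
equal vote weight, features standardized per training fold.  Its accuracy
therefore measures the feature pipeline, not classifier tuning.  Folds are
stratified so that every subject appears in every training fold; test
predictions are pooled over folds before computing metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .imageset_io import SubjectDataset
from .lbp_features import FeatureMatrix, build_feature_matrix
from .nca_selection import apply_selection, default_k, nca_fit, select_top_k

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVConfig:
    """Cross-validated nearest-neighbor settings."""

    n_folds: int = 10
    k_neighbors: int = 1
    distance: str = "euclidean"
    standardize: bool = True
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be at least 1")
        if self.distance != "euclidean":
            raise ValueError("only the Euclidean metric is supported")


@dataclass
class EvaluationReport:
    """Pooled CV predictions, confusion matrix and summary metrics (%)."""

    classes: np.ndarray
    y_true: np.ndarray
    pooled_predictions: np.ndarray
    fold_assignment: np.ndarray
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    per_subject_recall: dict = field(default_factory=dict)
    n_misclassified: int = 0

    def rounded(self, ndigits: int = 2) -> dict:
        """Headline metrics rounded for reporting."""
        return {
            "accuracy": round(self.accuracy, ndigits),
            "macro_precision": round(self.macro_precision, ndigits),
            "macro_recall": round(self.macro_recall, ndigits),
            "macro_f1": round(self.macro_f1, ndigits),
        }

    def save(self, out_dir: str | Path) -> None:
        """Write the report as JSON plus CSV tables."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "classes": [str(c) for c in self.classes],
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "n_misclassified": self.n_misclassified,
            "per_subject_recall": {str(k): v for k, v in self.per_subject_recall.items()},
            "y_true": [str(v) for v in self.y_true],
            "pooled_predictions": [str(v) for v in self.pooled_predictions],
            "fold_assignment": self.fold_assignment.tolist(),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        cls = [str(c) for c in self.classes]
        pd.DataFrame(self.confusion, index=cls, columns=cls).to_csv(
            out / "confusion_matrix.csv"
        )
        pd.DataFrame(
            {"subject": cls, "recall_pct": [self.per_subject_recall[c] for c in cls]}
        ).to_csv(out / "per_subject_recall.csv", index=False)


def make_folds(labels: np.ndarray, cfg: CVConfig) -> np.ndarray:
    """Assign each sample a fold id in 0..n_folds-1.

    Stratified: per-class counts differ by at most one across folds.
    Deterministic given ``cfg.seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if cfg.stratified:
        classes, counts = np.unique(labels, return_counts=True)
        small = classes[counts < cfg.n_folds]
        if len(small):
            raise ValueError(
                f"class(es) {', '.join(map(str, small))} have fewer than "
                f"{cfg.n_folds} samples; stratified {cfg.n_folds}-fold CV is undefined"
            )
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        )
        split = splitter.split(np.zeros((n, 1)), labels)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        split = splitter.split(np.zeros((n, 1)))
    assignment = np.empty(n, dtype=np.int64)
    for fold_id, (_, test_idx) in enumerate(split):
        assignment[test_idx] = fold_id
    return assignment


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale by training mean/std; zero-variance columns pass through unscaled."""
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    zero = std == 0.0
    if zero.any():
        logger.debug("%d zero-variance column(s) left unscaled", int(zero.sum()))
        std = np.where(zero, 1.0, std)
    return (train - mean) / std, (test - mean) / std


def knn_cv_predict(
    X: np.ndarray, y: np.ndarray, cfg: CVConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled k-fold 1-NN predictions.

    Per fold: standardize columns with the training fold's statistics, then
    predict each test sample by its nearest training sample (Euclidean;
    distance ties go to the lower training-sample index).  Returns
    ``(predictions, fold_assignment)``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if cfg.k_neighbors != 1:
        raise ValueError("this evaluation is defined for a single neighbor")
    folds = make_folds(y, cfg)
    pred = np.empty(len(y), dtype=y.dtype)
    for fold_id in range(cfg.n_folds):
        test = folds == fold_id
        train = ~test
        Xtr, Xte = X[train], X[test]
        if cfg.standardize:
            Xtr, Xte = _standardize(Xtr, Xte)
        d = cdist(Xte, Xtr, metric="euclidean")
        nearest = d.argmin(axis=1)  # argmin returns the first (lowest) index on ties
        pred[test] = y[train][nearest]
    return pred, folds


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """Confusion matrix plus overall and per-subject metrics, in percent.

    Macro metrics average per-class precision/recall/F1 with equal class
    weight (a class never predicted contributes precision 0); micro metrics
    pool counts and equal accuracy for single-label classification.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
        )
    classes = np.unique(np.concatenate([y_true, y_pred]))
    conf = _sk_confusion(y_true, y_pred, labels=classes)
    n = len(y_true)
    correct = int(np.trace(conf))
    accuracy = 100.0 * correct / n

    row = conf.sum(axis=1).astype(float)  # true counts per class
    col = conf.sum(axis=0).astype(float)  # predicted counts per class
    diag = np.diag(conf).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall_c = np.where(row > 0, diag / row, 0.0)
        precision_c = np.where(col > 0, diag / col, 0.0)
        f1_c = np.where(
            precision_c + recall_c > 0,
            2 * precision_c * recall_c / (precision_c + recall_c),
            0.0,
        )
    return EvaluationReport(
        classes=classes,
        y_true=y_true,
        pooled_predictions=y_pred,
        fold_assignment=np.zeros(n, dtype=np.int64),
        confusion=conf,
        accuracy=accuracy,
        macro_precision=100.0 * precision_c.mean(),
        macro_recall=100.0 * recall_c.mean(),
        macro_f1=100.0 * f1_c.mean(),
        micro_precision=accuracy,
        micro_recall=accuracy,
        micro_f1=accuracy,
        per_subject_recall={
            str(c): 100.0 * recall_c[i] for i, c in enumerate(classes)
        },
        n_misclassified=n - correct,
    )


def run_pipeline(
    ds: SubjectDataset,
    config=None,
    out_dir: str | Path | None = None,
) -> EvaluationReport:
    """Full evaluation: preprocessing -> LBP -> NCA selection -> 1-NN CV.

    With ``nested_selection`` enabled in the config, NCA is refit on each
    training fold and applied to its test fold (leakage-free); otherwise
    selection is fit once on the full matrix before cross-validation, which
    mirrors the select-then-classify protocol this pipeline evaluates.
    """
    from .config import PipelineConfig

    cfg = config if config is not None else PipelineConfig()
    logger.info("extracting features for %d images", ds.n_images)
    fm = build_feature_matrix(ds, cfg)
    report = evaluate_features(fm, cfg)
    if out_dir is not None:
        report.save(out_dir)
    return report


def evaluate_features(fm: FeatureMatrix, config=None) -> EvaluationReport:
    """NCA selection + standardized 1-NN CV on a prebuilt feature matrix."""
    from .config import PipelineConfig

    cfg = config if config is not None else PipelineConfig()
    cv = CVConfig(
        n_folds=cfg.cv_folds,
        k_neighbors=cfg.cv_neighbors,
        standardize=cfg.cv_standardize,
        stratified=cfg.cv_stratified,
        seed=cfg.cv_seed,
    )
    k = default_k(fm.n_features, cfg.select_fraction)
    y = fm.labels

    if cfg.nested_selection:
        logger.info("nested NCA selection inside each of %d folds", cv.n_folds)
        folds = make_folds(y, cv)
        pred = np.empty(len(y), dtype=y.dtype)
        for fold_id in range(cv.n_folds):
            test = folds == fold_id
            train = ~test
            weights = nca_fit(
                fm.values[train],
                y[train],
                lam=cfg.nca_lambda,
                sigma=cfg.nca_sigma,
                epochs=cfg.nca_epochs,
                learning_rate=cfg.nca_lr,
                seed=cfg.nca_seed,
            )
            sel = select_top_k(weights, k)
            Xtr, Xte = fm.values[train][:, sel.indices], fm.values[test][:, sel.indices]
            if cv.standardize:
                Xtr, Xte = _standardize(Xtr, Xte)
            d = cdist(Xte, Xtr, metric="euclidean")
            pred[test] = y[train][d.argmin(axis=1)]
    else:
        logger.info("fitting NCA on the full %dx%d matrix", fm.n_samples, fm.n_features)
        weights = nca_fit(
            fm.values,
            y,
            lam=cfg.nca_lambda,
            sigma=cfg.nca_sigma,
            epochs=cfg.nca_epochs,
            learning_rate=cfg.nca_lr,
            seed=cfg.nca_seed,
        )
        sel = select_top_k(weights, k)
        reduced = apply_selection(fm, sel)
        logger.info("1-NN %d-fold CV on %d selected features", cv.n_folds, sel.k)
        pred, folds = knn_cv_predict(reduced.values, y, cv)

    report = compute_metrics(y, pred)
    report.fold_assignment = folds
    return report
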