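"""Multi-classifier evaluation harness.

Trains the requested classifier families on a selected gene subset and
reports, per classifier, the confusion matrix and the standard binary
metrics — accuracy (TP+TN)/(TP+FN+FP+TN), recall TP/(TP+FN), precision
TP/(TP+FP), F1 = 2PR/(P+R) — plus the ROC area computed from continuous
scores via the rank (Mann-Whitney) statistic with ties averaged.  The
tumour class is the positive class throughout.  Under k-fold protocols
the out-of-fold predictions are pooled into a single confusion matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .classifiers import make_classifier
from .data_io import ExpressionDataset, FeatureSubset, SplitPlan, iter_folds


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn}


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with tumour (=1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} truths vs {y_pred.shape[0]} predictions"
        )
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp + cm.tn, cm.total, "accuracy")


def recall(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")


def precision(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")


def f1(cm: ConfusionMatrix) -> float:
    p = precision(cm)
    r = recall(cm)
    return f1_from_pr(p, r)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if p + r == 0:
        warnings.warn("F1 denominator is zero; reporting 0", stacklevel=2)
        return 0.0
    return 2.0 * p * r / (p + r)


def roc_auc(y_true, scores) -> float:
    """Area under the ROC curve via the rank statistic, ties averaged."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def reduction_percentage(n_before: int, n_after: int) -> float:
    """Percent of features removed, to one decimal: 100 (1 - after/before)."""
    if n_before <= 0 or n_after < 0 or n_after > n_before:
        raise ValueError(f"invalid counts: before={n_before}, after={n_after}")
    return round(100.0 * (1.0 - n_after / n_before), 1)


@dataclass
class EvaluationReport:
    """Per-classifier metric rows, mirroring the usual benchmark tables."""

    rows: dict  # name -> {precision, recall, f_measure, roc_area, accuracy, confusion}
    protocol: str = ""
    subset_size: int = 0
    seed: int = 0
    notes: str = "k-fold metrics pool out-of-fold predictions into one confusion matrix"

    def to_tsv(self) -> str:
        header = "Classifier\tPrecision\tRecall\tF-Measure\tROC Area\tAccuracy"
        lines = [header]
        for name, m in self.rows.items():
            lines.append(
                f"{name}\t{m['precision']:.3f}\t{m['recall']:.3f}\t"
                f"{m['f_measure']:.3f}\t{m['roc_area']:.3f}\t{100 * m['accuracy']:.1f}%"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        payload = {
            "protocol": self.protocol,
            "subset_size": self.subset_size,
            "seed": self.seed,
            "notes": self.notes,
            "rows": {
                name: {
                    **{k: v for k, v in m.items() if k != "confusion"},
                    "confusion": m["confusion"].as_dict(),
                }
                for name, m in self.rows.items()
            },
        }
        return json.dumps(payload, indent=2)


def _scores_for_auc(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return np.asarray(proba[:, pos_col], dtype=float)


def evaluate_classifiers(
    ds: ExpressionDataset,
    subset: FeatureSubset | np.ndarray,
    classifiers=("svm", "nb", "dt", "rf", "knn", "mlp"),
    plan: SplitPlan | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Fit each classifier on the subset's genes and score held-out samples.

    Holdout plans score the test partition; k-fold plans pool the
    out-of-fold predictions over all folds.  One report row per
    requested classifier.
    """
    indices = subset.indices if isinstance(subset, FeatureSubset) else np.asarray(subset, dtype=int)
    if indices.size == 0:
        raise ValueError("cannot evaluate an empty gene subset")
    plan = plan or SplitPlan(kind="holdout", train_fraction=0.7, seed=seed)
    X = ds.matrix[:, indices]
    y = ds.labels
    folds = list(iter_folds(ds, plan))

    rows: dict[str, dict] = {}
    for name in classifiers:
        template = make_classifier(name, seed=seed)  # validates the name
        y_true_all, y_pred_all, score_all = [], [], []
        for train, test in folds:
            model = make_classifier(template, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter on tiny folds
                model.fit(X[train], y[train])
            y_pred_all.append(model.predict(X[test]))
            score_all.append(_scores_for_auc(model, X[test]))
            y_true_all.append(y[test])
        y_true = np.concatenate(y_true_all)
        y_pred = np.concatenate(y_pred_all)
        s = np.concatenate(score_all)
        cm = confusion(y_true, y_pred)
        rows[name] = {
            "precision": precision(cm),
            "recall": recall(cm),
            "f_measure": f1(cm),
            "roc_area": roc_auc(y_true, s),
            "accuracy": accuracy(cm),
            "confusion": cm,
        }
    descr = (
        f"holdout {plan.train_fraction:.0%} train" if plan.kind == "holdout" else f"{plan.k}-fold CV"
    )
    return EvaluationReport(
        rows=rows, protocol=descr, subset_size=int(indices.size), seed=seed
    )
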