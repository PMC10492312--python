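"""Metrics for classifier quality and adjustment recovery.

Two questions are scored separately: how well the trusted-subset model
predicts true categories (ordinary multiclass metrics), and how close
adjusted responses land to the pre-corruption truth (the recovery
question). The headline recovery statistic is the *average accuracy
rate* — the macro mean of per-class recall of truth vs adjusted labels —
alongside overall accuracy and an exact bookkeeping of what happened to
each untrusted row (restored, partially restored, overshot, untouched,
or never corrupted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.tree import DecisionTreeClassifier

from .error_adjust import TrainedResponseModel

__all__ = [
    "MetricsReport",
    "AdjustmentEvaluation",
    "score_classifier",
    "score_adjustment",
    "compare_models",
    "plot_reports",
]

RECOVERY_OUTCOMES = (
    "restored",
    "partial",
    "overshot",
    "untouched",
    "uncorrupted_unchanged",
    "uncorrupted_changed",
)


@dataclass
class MetricsReport:
    """Multiclass metrics with a fixed category order.

    ``confusion`` is an L×L count matrix indexed truth × predicted over
    ``categories``; ``accuracy`` equals its trace over n. Precision,
    recall and F1 are reported under the stated ``averaging``
    (per-class scores with zero denominators count as 0, with a
    warning). ``per_class_recall`` is indexed by category; classes
    absent from the truth get NaN and are excluded from macro recall.
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    categories: np.ndarray
    per_class_recall: pd.Series
    confusion: pd.DataFrame
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "averaging": self.averaging,
            "n": self.n,
            "per_class_recall": {
                str(k): (None if np.isnan(v) else float(v))
                for k, v in self.per_class_recall.items()
            },
            "confusion": self.confusion.to_numpy().tolist(),
            "categories": [int(c) for c in self.categories],
        }


def _validate_labels(*vectors, categories: np.ndarray | None):
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"label vectors have mismatched lengths {sorted(lengths)}")
    arrays = [np.asarray(v, dtype=int) for v in vectors]
    if categories is None:
        categories = np.unique(np.concatenate(arrays))
    else:
        categories = np.asarray(categories, dtype=int)
        for arr in arrays:
            bad = np.setdiff1d(arr, categories)
            if bad.size:
                raise ValueError(f"labels outside the category set: {bad.tolist()}")
    return arrays, categories


def score_classifier(
    truth,
    predicted,
    averaging: str = "macro",
    categories: np.ndarray | None = None,
) -> MetricsReport:
    """Standard multiclass accuracy/precision/recall/F1 plus confusion matrix."""
    if averaging not in ("macro", "weighted"):
        raise ValueError(f"averaging must be 'macro' or 'weighted', got {averaging!r}")
    (truth, predicted), categories = _validate_labels(
        truth, predicted, categories=categories
    )
    cm = confusion_matrix(truth, predicted, labels=categories)
    present = np.isin(categories, np.unique(truth))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division handled explicitly below
        precision, recall, f1, _ = precision_recall_fscore_support(
            truth,
            predicted,
            labels=categories[present],
            average=averaging,
            zero_division=0,
        )
        per_class = precision_recall_fscore_support(
            truth, predicted, labels=categories, average=None, zero_division=0
        )
    prec_per_class = per_class[0]
    if np.any((prec_per_class == 0) & ~np.isin(categories, np.unique(predicted)) & present):
        warnings.warn(
            "a category was never predicted; its precision counts as 0",
            UserWarning,
            stacklevel=2,
        )
    recall_per_class = per_class[1].astype(float)
    recall_per_class[~present] = np.nan
    return MetricsReport(
        accuracy=float(accuracy_score(truth, predicted)),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        averaging=averaging,
        categories=categories,
        per_class_recall=pd.Series(recall_per_class, index=categories),
        confusion=pd.DataFrame(cm, index=categories, columns=categories),
        n=len(truth),
    )


@dataclass
class AdjustmentEvaluation:
    """Before/after picture of one adjustment run on untrusted rows.

    ``average_accuracy_rate`` is the macro mean of per-class recall of
    truth vs adjusted labels — the headline recovery statistic.
    ``recovery_counts`` partitions the untrusted rows exactly:
    corrupted rows end up restored (adjusted == true), partial (moved
    toward but short of true), overshot (moved past true), or untouched;
    uncorrupted rows are either left alone or spuriously changed.
    """

    pre: MetricsReport
    post: MetricsReport
    average_accuracy_rate: float
    post_accuracy: float
    recovery_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "average_accuracy_rate": self.average_accuracy_rate,
            "post_accuracy": self.post_accuracy,
            "recovery_counts": self.recovery_counts,
            "pre": self.pre.to_dict(),
            "post": self.post.to_dict(),
        }


def score_adjustment(
    true_labels,
    reported_labels,
    adjusted_labels,
    categories: np.ndarray | None = None,
    averaging: str = "macro",
) -> AdjustmentEvaluation:
    """Score recovery of pre-corruption labels on the untrusted subset."""
    (true_labels, reported_labels, adjusted_labels), categories = _validate_labels(
        true_labels, reported_labels, adjusted_labels, categories=categories
    )
    pre = score_classifier(true_labels, reported_labels, averaging, categories)
    post = score_classifier(true_labels, adjusted_labels, averaging, categories)
    avg_rate = float(np.nanmean(post.per_class_recall.to_numpy()))

    corrupted = reported_labels != true_labels
    toward = np.abs(adjusted_labels - true_labels) < np.abs(reported_labels - true_labels)
    past = (adjusted_labels - true_labels) * np.sign(true_labels - reported_labels) > 0
    counts = {
        "restored": int(np.sum(corrupted & (adjusted_labels == true_labels))),
        "partial": int(
            np.sum(corrupted & toward & (adjusted_labels != true_labels) & ~past)
        ),
        "overshot": int(np.sum(corrupted & past)),
        "untouched": int(np.sum(corrupted & (adjusted_labels == reported_labels))),
        "uncorrupted_unchanged": int(
            np.sum(~corrupted & (adjusted_labels == reported_labels))
        ),
        "uncorrupted_changed": int(
            np.sum(~corrupted & (adjusted_labels != reported_labels))
        ),
    }
    # Rows that moved away from truth without passing it (possible only
    # against the corruption direction) land in none of the first three
    # corrupted bins; count them as untouched-equivalent failures.
    accounted = sum(counts.values())
    if accounted != len(true_labels):
        counts["other"] = int(len(true_labels) - accounted)
    return AdjustmentEvaluation(
        pre=pre,
        post=post,
        average_accuracy_rate=avg_rate,
        post_accuracy=post.accuracy,
        recovery_counts=counts,
    )


def compare_models(
    train_features,
    train_labels,
    test_features,
    test_labels,
    seed: int = 0,
    rf_model: TrainedResponseModel | None = None,
    averaging: str = "macro",
) -> pd.DataFrame:
    """Benchmark multinomial logistic regression, a single decision tree
    and the random forest on identical train/test rows.

    The baselines use library-default settings with the shared seed; the
    forest is either a supplied tuned model or a default-configured one
    fit here. Returns one row per model with accuracy/precision/recall/F1
    on the test rows.
    """
    X_train = np.asarray(train_features, dtype=float)
    y_train = np.asarray(train_labels, dtype=int)
    X_test = np.asarray(test_features, dtype=float)
    y_test = np.asarray(test_labels, dtype=int)

    models: dict[str, object] = {
        "multinomial_logistic_regression": LogisticRegression(max_iter=2000),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
    }
    rows = []
    for name, est in models.items():
        est.fit(X_train, y_train)
        pred = est.predict(X_test)
        report = score_classifier(y_test, pred, averaging=averaging)
        rows.append((name, report))
    if rf_model is not None:
        pred = rf_model.classifier.predict(X_test)
    else:
        rf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
        rf.fit(X_train, y_train)
        pred = rf.predict(X_test)
    rows.append(("random_forest", score_classifier(y_test, pred, averaging=averaging)))

    return pd.DataFrame(
        [
            {
                "model": name,
                "accuracy": r.accuracy,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
            }
            for name, r in rows
        ]
    )


def plot_reports(
    reports: dict[str, MetricsReport],
    out_dir: str | Path,
    normalize: bool = False,
) -> list[Path]:
    """Render one confusion-matrix heatmap per named report.

    Purely presentational; returns the written file paths. An empty
    report mapping writes nothing and warns.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if not reports:
        warnings.warn("no reports to plot", UserWarning, stacklevel=2)
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, report in reports.items():
        cm = report.confusion.astype(float)
        fmt = "g"
        if normalize:
            row_sums = cm.sum(axis=1).replace(0, np.nan)
            cm = cm.div(row_sums, axis=0).fillna(0.0)
            fmt = ".2f"
        fig, ax = plt.subplots(figsize=(1.0 + 0.7 * len(cm), 1.0 + 0.6 * len(cm)))
        sns.heatmap(cm, annot=True, fmt=fmt, cmap="Blues", cbar=False, ax=ax)
        ax.set_xlabel("predicted category")
        ax.set_ylabel("true category")
        ax.set_title(name)
        path = out_dir / f"confusion_{name}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
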