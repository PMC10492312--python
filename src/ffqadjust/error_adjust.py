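"""Train the trusted-subset response model and apply directional adjustment.

The method's two steps live here. Step one fits a random-forest
classifier to the trusted ("healthy") subset, treating an ordinal FFQ
response as the class and the objective covariates as features; tree
depth is tuned by cross-validation. Step two revises each untrusted
reported category ``C_R`` using the model's class probabilities,
sorted descending as ``(C_(1), P_(1)), ..., (C_(L), P_(L))``.

Two replacement rules are provided:

``conservative`` (default)
    Replace ``C_R`` with the top-probability category ``C_(1)`` only when
    it lies beyond ``C_R`` in the suspected direction (above for
    underreporting, below for overreporting); otherwise keep ``C_R``.

``directional-argmax``
    Replace ``C_R`` with the highest-probability category strictly beyond
    it in the suspected direction whenever one exists (optionally
    requiring its probability to clear a floor), unless the model's top
    category already agrees with the report.

Both rules are monotone (an underreport adjustment never lowers a
response) and the conservative rule is idempotent.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "UNDERREPORT",
    "OVERREPORT",
    "CONSERVATIVE",
    "DIRECTIONAL_ARGMAX",
    "AdjustmentPolicy",
    "CategoryProbabilities",
    "TrainedResponseModel",
    "tune_and_train",
    "predict_probabilities",
    "adjust_response",
    "adjust_dataset",
]

UNDERREPORT = "underreport"
OVERREPORT = "overreport"
CONSERVATIVE = "conservative"
DIRECTIONAL_ARGMAX = "directional-argmax"

DEFAULT_DEPTH_GRID = tuple(range(2, 21))
DEFAULT_N_ESTIMATORS = 500


@dataclass(frozen=True)
class AdjustmentPolicy:
    """Direction of suspected misreporting plus the replacement rule.

    ``direction`` fixes the inequality qualifying a replacement category
    (strictly above the report for underreporting, strictly below for
    overreporting). ``probability_floor`` applies to the
    directional-argmax mode only: the qualifying category must carry at
    least this much probability, the default 0 meaning any qualifying
    category is accepted.
    """

    direction: str = UNDERREPORT
    mode: str = CONSERVATIVE
    probability_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in (UNDERREPORT, OVERREPORT):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.mode not in (CONSERVATIVE, DIRECTIONAL_ARGMAX):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.probability_floor <= 1.0:
            raise ValueError("probability_floor must be in [0, 1]")


@dataclass
class CategoryProbabilities:
    """One row's class probabilities, sorted by descending probability.

    ``categories[i]`` is the category with the (i+1)-th largest
    probability ``probabilities[i]``; probability ties are broken by
    ascending category code for a stable order (direction-aware
    tie-breaking happens at adjustment time). ``reported`` holds the
    participant's reported category ``C_R`` once attached.
    """

    categories: np.ndarray
    probabilities: np.ndarray
    reported: int | None = None

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=int)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.categories.shape != self.probabilities.shape:
            raise ValueError("categories and probabilities must align")
        if np.any(np.diff(self.probabilities) > 1e-12):
            raise ValueError("probabilities must be sorted descending")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def from_vector(
        cls,
        categories: np.ndarray,
        probabilities: np.ndarray,
        reported: int | None = None,
    ) -> "CategoryProbabilities":
        """Build from an unsorted (category, probability) vector."""
        categories = np.asarray(categories, dtype=int)
        probabilities = np.asarray(probabilities, dtype=float)
        order = np.lexsort((categories, -probabilities))
        return cls(categories[order], probabilities[order], reported=reported)

    @property
    def top_category(self) -> int:
        return int(self.categories[0])

    def probability_of(self, category: int) -> float:
        idx = np.flatnonzero(self.categories == category)
        return float(self.probabilities[idx[0]]) if idx.size else 0.0


@dataclass
class TrainedResponseModel:
    """A fitted per-response classifier with its tuning record.

    ``categories`` is the ordered category set seen in training (a
    subset of 1..L); probability vectors are reported over exactly this
    set. ``cv_table`` records mean cross-validated accuracy per
    candidate depth; ``best_depth`` maximised it.
    """

    classifier: RandomForestClassifier
    categories: np.ndarray
    best_depth: int
    cv_folds: int
    n_estimators: int
    cv_table: pd.DataFrame
    training_accuracy: float
    feature_names: list[str] | None = None

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def save(self, path: str | Path) -> None:
        """Persist to ``path`` (binary) with a JSON metadata sidecar."""
        path = Path(path)
        joblib.dump(self.classifier, path)
        meta = {
            "categories": [int(c) for c in self.categories],
            "best_depth": int(self.best_depth),
            "cv_folds": int(self.cv_folds),
            "n_estimators": int(self.n_estimators),
            "training_accuracy": float(self.training_accuracy),
            "cv_table": {
                str(int(d)): float(a)
                for d, a in zip(self.cv_table["depth"], self.cv_table["cv_accuracy"])
            },
            "feature_names": self.feature_names,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedResponseModel":
        path = Path(path)
        classifier = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cv_table = pd.DataFrame(
            {
                "depth": [int(d) for d in meta["cv_table"]],
                "cv_accuracy": list(meta["cv_table"].values()),
            }
        )
        return cls(
            classifier=classifier,
            categories=np.asarray(meta["categories"], dtype=int),
            best_depth=meta["best_depth"],
            cv_folds=meta["cv_folds"],
            n_estimators=meta["n_estimators"],
            cv_table=cv_table,
            training_accuracy=meta["training_accuracy"],
            feature_names=meta.get("feature_names"),
        )


def _as_matrix(rows, feature_names: list[str] | None) -> np.ndarray:
    """Coerce rows to a float matrix, checking the training schema."""
    if isinstance(rows, pd.DataFrame):
        if feature_names is not None:
            missing = [c for c in feature_names if c not in rows.columns]
            extra = [c for c in rows.columns if c not in feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature schema mismatch: missing columns {missing}, "
                    f"unexpected columns {extra}"
                )
            rows = rows[feature_names]
        return rows.to_numpy(dtype=float)
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2:
        raise ValueError("feature rows must be 2-dimensional")
    return mat


def tune_and_train(
    features,
    labels,
    depth_grid: tuple[int, ...] | list[int] = DEFAULT_DEPTH_GRID,
    cv_folds: int = 5,
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    tuning_n_estimators: int | None = None,
) -> TrainedResponseModel:
    """Depth-tune a random forest by cross-validation and refit on all rows.

    For every depth in ``depth_grid``, mean held-out accuracy over a
    stratified ``cv_folds``-fold split is recorded; the depth with the
    highest mean wins (ties go to the shallower tree) and the forest is
    refit on the full trusted set at that depth. ``tuning_n_estimators``
    lets the grid search run with a smaller forest than the final refit,
    which matters for large trusted sets.

    Raises on an empty training set; a category rarer than the fold
    count triggers a warning and a reduced fold count rather than an
    error.
    """
    feature_names = list(features.columns) if isinstance(features, pd.DataFrame) else None
    X = _as_matrix(features, None)
    y = np.asarray(labels, dtype=int)
    if len(X) == 0:
        raise ValueError("trusted training set is empty")
    if len(X) != len(y):
        raise ValueError("features and labels must have equal length")
    depth_grid = sorted(set(int(d) for d in depth_grid))
    if any(d < 1 for d in depth_grid):
        raise ValueError("all depths in depth_grid must be >= 1")

    categories, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    folds = cv_folds
    if len(categories) > 1 and min_count < cv_folds:
        folds = max(2, min_count)
        warnings.warn(
            f"rarest category has {min_count} rows < cv_folds={cv_folds}; "
            f"reducing to {folds} folds",
            UserWarning,
            stacklevel=2,
        )

    def forest(depth: int, n_trees: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees,
            max_depth=depth,
            random_state=seed,
            n_jobs=1,
        )

    n_tune = tuning_n_estimators or n_estimators
    if len(categories) == 1 or min_count < 2:
        # Cross-validation is undefined; score every depth by training
        # accuracy and fall back to the shallowest tree on ties.
        cv_rows = []
        for depth in depth_grid:
            clf = forest(depth, n_tune).fit(X, y)
            cv_rows.append((depth, float(clf.score(X, y))))
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
        cv_rows = []
        for depth in depth_grid:
            accs = []
            for train_idx, test_idx in splits:
                clf = forest(depth, n_tune).fit(X[train_idx], y[train_idx])
                accs.append(clf.score(X[test_idx], y[test_idx]))
            cv_rows.append((depth, float(np.mean(accs))))

    cv_table = pd.DataFrame(cv_rows, columns=["depth", "cv_accuracy"])
    best_depth = int(cv_table.loc[cv_table["cv_accuracy"].idxmax(), "depth"])
    final = forest(best_depth, n_estimators).fit(X, y)
    return TrainedResponseModel(
        classifier=final,
        categories=categories,
        best_depth=best_depth,
        cv_folds=folds,
        n_estimators=n_estimators,
        cv_table=cv_table,
        training_accuracy=float(final.score(X, y)),
        feature_names=feature_names,
    )


def predict_probabilities(
    model: TrainedResponseModel,
    rows,
    reported: np.ndarray | None = None,
) -> list[CategoryProbabilities]:
    """Per-row class probabilities over the model's category set.

    Each row yields a :class:`CategoryProbabilities` sorted by
    descending probability (ties by ascending category code). If
    ``reported`` is given, the i-th reported category is attached as
    ``C_R``.
    """
    X = _as_matrix(rows, model.feature_names)
    proba = model.classifier.predict_proba(X)
    cats = np.asarray(model.classifier.classes_, dtype=int)
    out = []
    for i in range(len(X)):
        rep = int(reported[i]) if reported is not None else None
        out.append(CategoryProbabilities.from_vector(cats, proba[i], reported=rep))
    return out


def _pick_nearest(categories: np.ndarray, reported: int) -> int:
    """Among equal-probability candidates, prefer the category nearest
    the report; exact distance ties go to the lower category."""
    dist = np.abs(categories - reported)
    order = np.lexsort((categories, dist))
    return int(categories[order[0]])


@dataclass(frozen=True)
class AdjustmentRecord:
    """What happened to one response: kept or replaced, and why."""

    reported: int
    adjusted: int
    mode: str
    direction: str
    qualifying_probability: float

    @property
    def changed(self) -> bool:
        return self.adjusted != self.reported


def adjust_response(
    probs: CategoryProbabilities, policy: AdjustmentPolicy
) -> AdjustmentRecord:
    """Apply the replacement rule to one reported category.

    See the module docstring for the two modes. Probability ties among
    qualifying categories break toward the category nearest the report
    (minimal-revision principle), and the response is always kept when
    the model's top category agrees with it.
    """
    if probs.reported is None:
        raise ValueError("CategoryProbabilities.reported (C_R) is not set")
    reported = int(probs.reported)
    cats = probs.categories
    p = probs.probabilities

    top_p = p[0]
    top_candidates = cats[np.isclose(p, top_p, rtol=0.0, atol=1e-12)]
    top = _pick_nearest(top_candidates, reported)

    def keep() -> AdjustmentRecord:
        return AdjustmentRecord(
            reported, reported, policy.mode, policy.direction, float(top_p)
        )

    beyond = (cats > reported) if policy.direction == UNDERREPORT else (cats < reported)

    if policy.mode == CONSERVATIVE:
        qualifies = top > reported if policy.direction == UNDERREPORT else top < reported
        if qualifies:
            return AdjustmentRecord(
                reported, top, policy.mode, policy.direction, float(top_p)
            )
        return keep()

    # directional-argmax
    if top == reported or not beyond.any():
        return keep()
    q_cats, q_p = cats[beyond], p[beyond]
    best_p = q_p.max()
    best = _pick_nearest(q_cats[np.isclose(q_p, best_p, rtol=0.0, atol=1e-12)], reported)
    if policy.probability_floor == 0.0 or best_p > policy.probability_floor:
        return AdjustmentRecord(
            reported, best, policy.mode, policy.direction, float(best_p)
        )
    return keep()


def adjust_dataset(
    model: TrainedResponseModel,
    rows,
    reported: np.ndarray,
    policy: AdjustmentPolicy = AdjustmentPolicy(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Adjust every reported category in ``rows``; preserve row order.

    Returns the adjusted label vector and a change log with one row per
    input row: reported, adjusted, the model's top category and its
    probability, the qualifying probability used by the rule, and the
    mode.
    """
    reported = np.asarray(reported, dtype=int)
    prob_rows = predict_probabilities(model, rows, reported=reported)
    adjusted = np.empty(len(prob_rows), dtype=int)
    log_rows = []
    for i, probs in enumerate(prob_rows):
        rec = adjust_response(probs, policy)
        adjusted[i] = rec.adjusted
        log_rows.append(
            {
                "row": i,
                "reported": rec.reported,
                "adjusted": rec.adjusted,
                "top_category": probs.top_category,
                "top_probability": float(probs.probabilities[0]),
                "qualifying_probability": rec.qualifying_probability,
                "mode": rec.mode,
                "changed": rec.changed,
            }
        )
    log = pd.DataFrame(
        log_rows,
        columns=[
            "row",
            "reported",
            "adjusted",
            "top_category",
            "top_probability",
            "qualifying_probability",
            "mode",
            "changed",
        ],
    )
    return adjusted, log
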