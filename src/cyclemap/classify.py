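"""Random-forest endocycle classifier and condition-level frequency comparison.

Given a z-scored marker table and binary endocycle labels (either the
annotated endocycle cluster from the cell cycle map or, on synthetic data,
the planted truth), :class:`EndocycleRandomForest` fits a random forest on a
stratified train split, evaluates AUC/accuracy on the held-out set, and
ranks markers by impurity importance — the molecular factors distinguishing
endocycling from canonically cycling cells.  :func:`endocycle_frequency`
scores each tissue sample for its percent of endocycle cells, and
:func:`compare_conditions` tests whether diseased samples carry more
endocycling than healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .synthetic import feature_columns

__all__ = [
    "EndocycleReport",
    "EndocycleRandomForest",
    "train_classifier",
    "endocycle_frequency",
    "compare_conditions",
]


@dataclass
class EndocycleReport:
    """Classifier evaluation plus cohort-level endocycle frequency analysis."""

    train_fraction: float
    seed: int
    auc: float
    accuracy: float
    importances: dict = field(default_factory=dict)  # marker -> importance, descending
    frequencies: dict = field(default_factory=dict)  # sample_id -> percent
    comparison: dict = field(default_factory=dict)   # statistic, p_value, direction

    def to_dict(self) -> dict:
        return asdict(self)


class EndocycleRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest discriminating endocycle from non-endocycle cells.

    ``fit`` takes the full labeled table, holds out ``1 - train_fraction`` of
    cells by stratified split, fits the forest on the rest and stores
    held-out AUC and accuracy plus normalized impurity importances in
    ``report_``.  Deterministic given ``random_state``.

    Hyperparameters follow common random-forest practice: 500 trees,
    sqrt-features per split, unlimited depth.
    """

    def __init__(self, n_estimators: int = 500, train_fraction: float = 0.7,
                 random_state: int = 0, n_jobs: int = 1):
        self.n_estimators = n_estimators
        self.train_fraction = train_fraction
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, table: pd.DataFrame, y) -> "EndocycleRandomForest":
        y = np.asarray(y, dtype=bool)
        if y.shape[0] != len(table):
            raise ValueError("labels must align with table rows")
        if len(np.unique(y)) < 2:
            raise ValueError("both endocycle and non-endocycle cells are required")
        feats = feature_columns(table)
        X = table[feats].to_numpy(dtype=float)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y,
            train_size=self.train_fraction,
            stratify=y,
            random_state=self.random_state,
        )
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features="sqrt",
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        ).fit(X_tr, y_tr)
        self.feature_names_in_ = feats
        imp = self.forest_.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        order = np.argsort(imp)[::-1]
        prob = self.forest_.predict_proba(X_te)[:, 1]
        self.report_ = EndocycleReport(
            train_fraction=self.train_fraction,
            seed=self.random_state,
            auc=float(roc_auc_score(y_te, prob)),
            accuracy=float(accuracy_score(y_te, prob > 0.5)),
            importances={feats[i]: float(imp[i]) for i in order},
        )
        return self

    def _check_features(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names_in_ if f not in table.columns]
        if missing:
            raise ValueError(f"table lacks features the model was trained on: {missing}")
        return table[self.feature_names_in_].to_numpy(dtype=float)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Boolean endocycle call per cell."""
        return self.forest_.predict(self._check_features(table)).astype(bool)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict_proba(self._check_features(table))


def train_classifier(table: pd.DataFrame, labels, train_fraction: float = 0.7,
                     seed: int = 0, n_jobs: int = 1) -> tuple[EndocycleRandomForest, EndocycleReport]:
    """Fit the endocycle random forest; returns ``(model, report)``."""
    model = EndocycleRandomForest(
        train_fraction=train_fraction, random_state=seed, n_jobs=n_jobs
    ).fit(table, labels)
    return model, model.report_


def endocycle_frequency(model: EndocycleRandomForest, table: pd.DataFrame) -> pd.Series:
    """Percent of cells called endocycle, per sample.

    The table must be normalized the same way as the training data and
    contain only proliferative (gated) cells, so the denominator is the
    proliferative pool.
    """
    pred = model.predict(table)
    return (
        pd.Series(pred, index=table.index)
        .groupby(table["sample_id"].to_numpy())
        .mean()
        .mul(100.0)
        .rename("endocycle_percent")
    )


def compare_conditions(frequencies: pd.Series, conditions: pd.Series,
                       test: str = "ranksum") -> dict:
    """Two-sample location test on per-sample endocycle frequencies.

    ``frequencies`` is indexed by sample id; ``conditions`` maps the same
    sample ids to exactly two condition labels.  The default is the
    Mann-Whitney rank-sum test (robust to the skewed, small-n per-sample
    percentages); ``test="welch"`` switches to Welch's t-test.  Returns the
    statistic, two-sided p-value, and the direction of effect (based on the
    difference of condition means; ``"none"`` when equal).
    """
    conditions = conditions.loc[frequencies.index]
    groups = sorted(conditions.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 conditions, got {groups}")
    a = frequencies[conditions == groups[0]]
    b = frequencies[conditions == groups[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("need at least 2 samples per condition")
    if test == "ranksum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    elif test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    diff = a.mean() - b.mean()
    if diff > 0:
        direction = f"{groups[0]} > {groups[1]}"
    elif diff < 0:
        direction = f"{groups[1]} > {groups[0]}"
    else:
        direction = "none"
    return {
        "test": test,
        "groups": groups,
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": direction,
        "mean_difference": float(diff),
    }
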