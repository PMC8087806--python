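"""Random-forest discrimination of suicide attempters from controls.

The discriminator combines the significant editing sites and co-editing
patterns into a bagged decision-tree ensemble (default 1000 trees, 2
candidate features per split), trained on a stratified 2/3 split and
evaluated on the held-out third with a ROC curve, AUC with bootstrap CI,
and sensitivity/specificity at an operating point.

Feature selection (BH-adjusted p < 0.05 in the chosen comparison) is
computed on the training subjects only, so test labels never leak into the
model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .stats import differential_table

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "split_train_test",
    "select_features",
    "train_random_forest",
    "evaluate",
    "run_classifier",
]


@dataclass
class ClassifierConfig:
    trees: int = 1000
    mtry: int = 2  # candidate features per split
    cv_folds: int = 10
    train_fraction: float = 2 / 3
    stratified: bool = True
    seed: int = 0
    positive_class: str = "SA"
    negative_class: str = "Ctrl"

    def validate(self, n_features: int | None = None) -> None:
        if self.trees < 1:
            raise ValueError("trees must be >= 1")
        if self.mtry < 1 or (n_features is not None and self.mtry > n_features):
            raise ValueError("mtry must be in [1, n_features]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class ClassifierReport:
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    importances: dict[str, float]
    n_train: int
    n_test: int
    features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "importances": self.importances,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "features": self.features,
        }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(
    records: pd.DataFrame, cfg: ClassifierConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split at the configured fraction.

    Per-class training counts are round-half-up of fraction × class size; the
    largest class is then adjusted so the total training size equals
    round-half-up of fraction × n.  Disjoint, exhaustive, deterministic given
    the seed.
    """
    cfg.validate()
    classes = records["group"].value_counts()
    if (classes < 2).any():
        small = classes[classes < 2].index.tolist()
        raise ValueError(f"class(es) with < 2 members: {small}")
    rng = np.random.default_rng(cfg.seed)
    per_class = {g: _round_half_up(cfg.train_fraction * n) for g, n in classes.items()}
    target_total = _round_half_up(cfg.train_fraction * len(records))
    largest = classes.idxmax()
    per_class[largest] += target_total - sum(per_class.values())
    per_class[largest] = min(max(per_class[largest], 1), classes[largest] - 1)

    train_idx: list = []
    for g, n_train in per_class.items():
        idx = records.index[records["group"] == g].to_numpy()
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_idx.extend(chosen.tolist())
    in_train = records.index.isin(train_idx)
    train = records.loc[in_train]
    test = records.loc[~in_train]
    return train, test


def select_features(diff_table: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Features with BH-adjusted p below alpha; falls back to all features
    (with a warning) when nothing is significant."""
    sig = diff_table.loc[diff_table["p_wilcoxon_adj"] < alpha, "feature"].tolist()
    if not sig:
        warnings.warn("no significant feature; falling back to all features")
        return diff_table["feature"].tolist()
    return sig


def train_random_forest(
    train: pd.DataFrame,
    features: Sequence[str],
    cfg: ClassifierConfig,
    tune: bool = False,
) -> RandomForestClassifier:
    """Fit the bagged-tree ensemble (bootstrap per tree, `mtry` candidate
    features per node).  With `tune=True`, mtry is chosen by stratified
    10-fold cross-validated grid search on the training set."""
    cfg.validate()
    y = train["group"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    X = train[list(features)].to_numpy(float)
    model = RandomForestClassifier(
        n_estimators=cfg.trees,
        max_features=min(cfg.mtry, len(features)),
        bootstrap=True,
        random_state=cfg.seed,
    )
    if tune:
        grid = {"max_features": list(range(1, len(features) + 1))}
        cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        search = GridSearchCV(model, grid, cv=cv, scoring="roc_auc")
        search.fit(X, y)
        model = search.best_estimator_
    else:
        model.fit(X, y)
    return model


def _youden_point(fpr: np.ndarray, tpr: np.ndarray, thresholds: np.ndarray):
    j = tpr - fpr
    k = int(np.argmax(j))
    return float(tpr[k]), float(1.0 - fpr[k]), float(thresholds[k])


def evaluate(
    model: RandomForestClassifier,
    test: pd.DataFrame,
    features: Sequence[str],
    cfg: ClassifierConfig,
    n_boot: int = 2000,
    fixed_specificity: float | None = None,
    n_train: int = 0,
) -> ClassifierReport:
    """Held-out ROC/AUC with stratified-bootstrap CI and an operating point.

    The operating point is the maximum Youden index (sensitivity +
    specificity − 1) on the test ROC; `fixed_specificity` instead reports the
    sensitivity achievable at that specificity.
    """
    y = (test["group"] == cfg.positive_class).to_numpy()
    if y.all() or not y.any():
        raise ValueError("test set contains a single class; AUC undefined")
    X = test[list(features)].to_numpy(float)
    pos_col = list(model.classes_).index(cfg.positive_class)
    scores = model.predict_proba(X)[:, pos_col]

    fpr, tpr, thresholds = roc_curve(y, scores)
    auc_value = float(_auc(fpr, tpr))

    rng = np.random.default_rng(cfg.seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        yy = np.concatenate([np.ones(len(pi), bool), np.zeros(len(ni), bool)])
        ss = np.concatenate([scores[pi], scores[ni]])
        f, t, _ = roc_curve(yy, ss)
        boot[b] = _auc(f, t)
    ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))

    if fixed_specificity is None:
        sens, spec, thr = _youden_point(fpr, tpr, thresholds)
    else:
        ok = 1.0 - fpr >= fixed_specificity
        k = int(np.flatnonzero(ok)[-1]) if ok.any() else 0
        sens, spec, thr = float(tpr[k]), float(1.0 - fpr[k]), float(thresholds[k])

    importances = dict(zip(features, model.feature_importances_.astype(float)))
    return ClassifierReport(
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        auc=auc_value,
        auc_ci=ci,
        sensitivity=sens,
        specificity=spec,
        threshold=thr,
        importances=importances,
        n_train=n_train,
        n_test=len(test),
        features=list(features),
    )


def run_classifier(
    records: pd.DataFrame,
    candidate_features: Sequence[str],
    cfg: ClassifierConfig | None = None,
    comparison: str = "Ctrl_vs_SA",
    n_boot: int = 2000,
    tune: bool = False,
) -> ClassifierReport:
    """Full discriminator pipeline on a two-class subset of the cohort.

    Splits Ctrl/positive-class subjects, selects significant features on the
    training set only, fits the forest and evaluates on the held-out set.
    """
    cfg = cfg or ClassifierConfig()
    sub = records[records["group"].isin([cfg.negative_class, cfg.positive_class])]
    train, test = split_train_test(sub, cfg)
    diff = differential_table(train, candidate_features, comparisons=[comparison])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = select_features(diff)
    model = train_random_forest(train, features, cfg, tune=tune)
    return evaluate(
        model, test, features, cfg, n_boot=n_boot, n_train=len(train)
    )
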