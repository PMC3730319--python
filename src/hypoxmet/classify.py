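"""Per-time-point linear SVM evaluation of the metabolite panel.

Protocol: stratified 2/3 random split (6+6 train, 3+3 test) within each
time point; leave-one-out cross validation on the 12 training samples tunes
the linear-kernel cost from a fixed grid by balanced accuracy (ties toward
the smaller cost); metrics are reported with hypoxia as the positive class.
Features are standardized using training-fold statistics only, so no test
information leaks into scaling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import DegenerateClassError, WrongDesignError
from .spectra import HYPOXIA, NORMOXIA
from .tables import ConcentrationTable

#: Cost grid: powers of four from 2^-5 to 2^15.
COST_GRID = tuple(float(2.0**k) for k in range(-5, 16, 2))


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    time_point: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


@dataclasses.dataclass(frozen=True)
class ClassMetrics:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def accuracy(self) -> float:
        return (self.TN + self.TP) / (self.TP + self.FP + self.FN + self.TN)

    @property
    def specificity(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def bac(self) -> float:
        return (self.specificity + self.sensitivity) / 2.0


def _features(table: ConcentrationTable, ids) -> np.ndarray:
    # below-detection concentrations enter the classifier as zero
    return table.data.loc[list(ids)].fillna(0.0).to_numpy(dtype=float)


def _labels(table: ConcentrationTable, ids) -> np.ndarray:
    return (table.meta.loc[list(ids), "condition"] == HYPOXIA).to_numpy(dtype=int)


def make_split(table: ConcentrationTable, time_point: int, seed: int = 0) -> SplitPlan:
    """Stratified 2/3 split at one time point: 6+6 training, 3+3 testing."""
    sub = table.subset(time_point=time_point)
    hyp = list(sub.meta.index[sub.meta["condition"] == HYPOXIA])
    nor = list(sub.meta.index[sub.meta["condition"] == NORMOXIA])
    if len(hyp) != 9 or len(nor) != 9:
        raise WrongDesignError(
            f"expected 9+9 samples at {time_point} h, got {len(hyp)}+{len(nor)}"
        )
    rng = np.random.default_rng(seed)
    train = sorted(rng.choice(hyp, 6, replace=False)) + sorted(
        rng.choice(nor, 6, replace=False)
    )
    test = sorted(set(hyp + nor) - set(train))
    return SplitPlan(time_point, tuple(train), tuple(test), seed)


@dataclasses.dataclass
class TrainedRule:
    """A standardizing linear SVM refit on the full training set."""

    cost: float
    mean: np.ndarray
    scale: np.ndarray
    svm: SVC
    loocv_bac: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict((X - self.mean) / self.scale)


def _standardize_stats(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return mean, scale


def _loocv_bac(X: np.ndarray, y: np.ndarray, cost: float, standardize: bool) -> float:
    preds = np.empty_like(y)
    for i in range(y.size):
        mask = np.ones(y.size, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        if len(np.unique(ytr)) < 2:
            raise DegenerateClassError("a LOOCV fold lost an entire class")
        if standardize:
            mean, scale = _standardize_stats(Xtr)
        else:
            mean, scale = np.zeros(X.shape[1]), np.ones(X.shape[1])
        clf = SVC(kernel="linear", C=cost)
        clf.fit((Xtr - mean) / scale, ytr)
        preds[i] = clf.predict(((X[i] - mean) / scale)[None, :])[0]
    return confusion(y, preds).bac


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    costs: tuple[float, ...] = COST_GRID,
    standardize: bool = True,
) -> TrainedRule:
    """LOOCV cost tuning by balanced accuracy, then refit on all rows.

    Ties are broken toward the smaller cost, so perfectly separable data
    selects the smallest cost on the grid.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateClassError("training data must contain both classes")
    best_cost, best_bac = None, -np.inf
    for c in sorted(costs):
        bac = _loocv_bac(X, y, c, standardize)
        if bac > best_bac + 1e-12:
            best_cost, best_bac = c, bac
    if standardize:
        mean, scale = _standardize_stats(X)
    else:
        mean, scale = np.zeros(X.shape[1]), np.ones(X.shape[1])
    clf = SVC(kernel="linear", C=best_cost)
    clf.fit((X - mean) / scale, y)
    return TrainedRule(best_cost, mean, scale, clf, float(best_bac))


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ClassMetrics:
    """Confusion counts with hypoxia (label 1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ClassMetrics(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def evaluate(rule: TrainedRule, X: np.ndarray, y: np.ndarray) -> ClassMetrics:
    return confusion(y, rule.predict(np.asarray(X, dtype=float)))


@dataclasses.dataclass
class TimePointResult:
    time_point: int
    plan: SplitPlan
    rule: TrainedRule
    train_metrics: ClassMetrics  # LOOCV-equivalent refit performance on train
    test_metrics: ClassMetrics
    loocv_bac: float


def evaluate_time_point(
    table: ConcentrationTable, time_point: int, seed: int = 0, standardize: bool = True
) -> TimePointResult:
    """Full protocol at one time point: split, tune, train, test."""
    plan = make_split(table, time_point, seed)
    Xtr, ytr = _features(table, plan.train_ids), _labels(table, plan.train_ids)
    Xte, yte = _features(table, plan.test_ids), _labels(table, plan.test_ids)
    rule = tune_and_train(Xtr, ytr, standardize=standardize)
    return TimePointResult(
        time_point=time_point,
        plan=plan,
        rule=rule,
        train_metrics=evaluate(rule, Xtr, ytr),
        test_metrics=evaluate(rule, Xte, yte),
        loocv_bac=rule.loocv_bac,
    )


def metrics_table(results: list[TimePointResult]) -> pd.DataFrame:
    """Report mirroring the per-time-point training/testing metric layout."""
    rows = []
    for which in ("training", "testing"):
        for r in sorted(results, key=lambda r: r.time_point):
            m = r.train_metrics if which == "training" else r.test_metrics
            rows.append(
                {
                    "set": which,
                    "time_point": f"{r.time_point} h",
                    "BAC": m.bac,
                    "accuracy": m.accuracy,
                    "specificity": m.specificity,
                    "sensitivity": m.sensitivity,
                }
            )
    return pd.DataFrame(rows)
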