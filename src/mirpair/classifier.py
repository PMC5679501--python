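"""Multi-pair classifiers: forward-stepwise logistic regression and validation.

Selected delta-Ct pairs are combined by a logistic model with no
interaction terms.  Pairs enter by forward selection on training AUC
(the first entrant is the best single pair) until the gain drops below
``min_gain`` or ``max_pairs`` is reached.  Overfitting is probed with a
bootstrap-aggregated random forest whose out-of-bag AUC is compared with
the in-sample AUC.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .exceptions import InsufficientDataError, MirpairError
from .pairs import Pair, PairStat, best_accuracy_cutoff, rank_auc

#: ridge strength applied only when the unpenalized fit is degenerate
SEPARATION_RIDGE = 1e-4
#: training-minus-out-of-bag AUC gap that flags overfitting
OVERFIT_GAP = 0.10


@dataclasses.dataclass
class LogisticFit:
    intercept: float
    coef: np.ndarray
    separation: bool  # True when a ridge fallback was needed

    @property
    def coefficients(self) -> np.ndarray:
        """Intercept followed by one weight per feature."""
        return np.concatenate([[self.intercept], self.coef])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.intercept + np.asarray(x, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-z))


@dataclasses.dataclass
class ClassifierMetrics:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    cutoff: float  # probability-scale cutoff (case called at prob >= cutoff)
    n_case: int
    n_control: int


@dataclasses.dataclass
class Classifier:
    """Ordered pair set plus logistic coefficients and per-dataset metrics."""

    pairs: list[Pair]
    fit: LogisticFit
    metrics: dict[str, ClassifierMetrics] = dataclasses.field(default_factory=dict)
    acceptance_threshold: float = 0.9

    def to_dict(self) -> dict:
        return {
            "pairs": [p.label for p in self.pairs],
            "coefficients": [float(c) for c in self.fit.coefficients],
            "separation_ridge": self.fit.separation,
            "acceptance_threshold": self.acceptance_threshold,
            "metrics": {
                tag: dataclasses.asdict(m) for tag, m in self.metrics.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


@dataclasses.dataclass
class ValidationReport:
    training_auc: float
    out_of_bag_auc: float
    n_trees: int
    n_bootstrap: int
    overfit_flag: bool


def _check_xy(features, labels) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=bool)
    keep = np.isfinite(x).all(axis=1)
    x, y = x[keep], y[keep]
    if y.all() or not y.any():
        raise InsufficientDataError("labels contain a single class")
    return x, y


def fit_logistic(features, labels) -> LogisticFit:
    """Maximum-likelihood logistic regression (linear, no interactions).

    On perfect separation or a degenerate design (the MLE does not exist or
    is not unique) the model is refitted with a mild ridge penalty and the
    fit is flagged.
    """
    x, y = _check_xy(features, labels)

    degenerate = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, solver="lbfgs",
                                       max_iter=2000, tol=1e-10)
            model.fit(x, y)
        except ConvergenceWarning:
            degenerate = True
    if not degenerate:
        # a diverging MLE shows up as a perfectly classified training set
        # with vanishing log loss
        p = np.clip(model.predict_proba(x)[:, 1], 1e-15, 1 - 1e-15)
        perfectly_classified = ((p >= 0.5) == y).all()
        mean_logloss = -float(np.mean(y * np.log(p) + (~y) * np.log(1 - p)))
        degenerate = perfectly_classified and mean_logloss < 1e-4
    if degenerate:
        model = LogisticRegression(C=1.0 / SEPARATION_RIDGE, solver="lbfgs",
                                   max_iter=5000, tol=1e-10)
        model.fit(x, y)
    return LogisticFit(
        intercept=float(model.intercept_[0]),
        coef=model.coef_[0].astype(float),
        separation=bool(degenerate),
    )


def classifier_metrics(fit: LogisticFit, features, labels) -> ClassifierMetrics:
    """AUC of fitted probabilities plus metrics at the best-accuracy cutoff."""
    x, y = _check_xy(features, labels)
    prob = fit.predict_proba(x)
    auc = rank_auc(prob, y)
    cm = best_accuracy_cutoff(prob, y)
    return ClassifierMetrics(
        auc=auc,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        cutoff=cm.cutoff,
        n_case=int(y.sum()),
        n_control=int((~y).sum()),
    )


def _lr_pvalue(x_small: np.ndarray, x_big: np.ndarray, y: np.ndarray) -> float:
    """Likelihood-ratio p for nested logistic models (1 df per added column)."""

    def loglik(x):
        fit = fit_logistic(x, y)
        p = np.clip(fit.predict_proba(x), 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(p) + (~y) * np.log(1 - p)))

    lr = 2.0 * (loglik(x_big) - loglik(x_small))
    df = x_big.shape[1] - x_small.shape[1]
    return float(sps.chi2.sf(max(lr, 0.0), df))


def stepwise_select(
    candidates: Sequence[PairStat],
    features: pd.DataFrame,
    labels,
    max_pairs: int = 3,
    min_gain: float = 0.005,
    criterion: str = "auc",
    acceptance_threshold: float = 0.9,
) -> Classifier:
    """Forward-stepwise pair combination into a logistic classifier.

    ``features`` holds one column per candidate pair label with the
    oriented score (-delta Ct).  Step 1 takes the highest-AUC candidate;
    each later step adds the candidate that maximizes the refitted training
    AUC, stopping at ``max_pairs`` or when the AUC gain falls below
    ``min_gain``.  ``criterion="lrt"`` instead enters the candidate with
    the smallest likelihood-ratio p, stopping when it exceeds 0.05.
    """
    if not candidates:
        raise InsufficientDataError("stepwise selection needs at least 1 candidate")
    if criterion not in ("auc", "lrt"):
        raise MirpairError(f"unknown stepwise criterion '{criterion}'")
    y = np.asarray(labels, dtype=bool)
    pool = sorted(candidates, key=lambda s: (-s.auc, s.pair.label))

    chosen = [pool[0].pair]
    remaining = [s.pair for s in pool[1:]]

    def train_auc(pairs: list[Pair]) -> float:
        cols = features[[p.label for p in pairs]].to_numpy(dtype=float)
        fit = fit_logistic(cols, y)
        keep = np.isfinite(cols).all(axis=1)
        return rank_auc(fit.predict_proba(cols[keep]), y[keep])

    current_auc = train_auc(chosen)
    while remaining and len(chosen) < max_pairs:
        if criterion == "auc":
            scored = [(train_auc(chosen + [p]), p) for p in remaining]
            best_auc, best_pair = max(scored, key=lambda t: (t[0], t[1].label))
            if best_auc - current_auc < min_gain:
                break
            chosen.append(best_pair)
            remaining.remove(best_pair)
            current_auc = best_auc
        else:
            xs = features[[p.label for p in chosen]].to_numpy(dtype=float)
            scored = [
                (_lr_pvalue(xs, features[[q.label for q in chosen + [p]]]
                            .to_numpy(dtype=float), y), p)
                for p in remaining
            ]
            best_p, best_pair = min(scored, key=lambda t: (t[0], t[1].label))
            if best_p >= 0.05:
                break
            chosen.append(best_pair)
            remaining.remove(best_pair)

    cols = features[[p.label for p in chosen]].to_numpy(dtype=float)
    fit = fit_logistic(cols, y)
    clf = Classifier(pairs=chosen, fit=fit,
                     acceptance_threshold=acceptance_threshold)
    clf.metrics["training"] = classifier_metrics(fit, cols, y)
    return clf


def accept_classifier(clf: Classifier, dataset_tag: str,
                      auc_threshold: float) -> bool:
    """True iff the classifier's AUC on the given dataset meets the gate (>=)."""
    if dataset_tag not in clf.metrics:
        raise MirpairError(f"no metrics computed for dataset '{dataset_tag}'")
    return bool(clf.metrics[dataset_tag].auc >= auc_threshold)


def bootstrap_rf_validate(features, labels, n_trees: int = 500,
                          seed: int = 0,
                          gap_threshold: float = OVERFIT_GAP) -> ValidationReport:
    """Random-forest bootstrap check for overfitting.

    Fits a bagged tree ensemble (each tree on a bootstrap resample) and
    compares the in-sample AUC with the out-of-bag AUC; a gap above
    ``gap_threshold`` raises the overfit flag.  Deterministic given seed.
    """
    x, y = _check_xy(features, labels)
    if y.sum() < 10 or (~y).sum() < 10:
        raise InsufficientDataError("need at least 10 samples per class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        forest = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, bootstrap=True,
            random_state=int(seed) % (2**31),
        )
        forest.fit(x, y)
    train_auc = rank_auc(forest.predict_proba(x)[:, 1], y)
    oob = forest.oob_decision_function_[:, 1]
    seen = np.isfinite(oob)
    oob_auc = rank_auc(oob[seen], y[seen])
    return ValidationReport(
        training_auc=train_auc,
        out_of_bag_auc=oob_auc,
        n_trees=n_trees,
        n_bootstrap=n_trees,
        overfit_flag=bool(train_auc - oob_auc > gap_threshold),
    )
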