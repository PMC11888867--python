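"""Classical baseline harness: 5 algorithms x 5 descriptors, plus deep
ablations.

Mirrors the benchmark table layout: k-NN, logistic regression, random
forest, SVM and gradient boosting (XGBoost), each trained on AAC, APAAC,
CTDC, CTDD and DDE features (25 models), alongside RNN/GRU recurrent
variants with and without attention.  Hyperparameters are picked on the
validation split by AUROC; all rows share one fixed train/val/test split.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .descriptors import DESCRIPTOR_NAMES, featurize_records
from .network import ModelConfig, build_model
from .training import (
    EvalReport, TrainConfig, compute_metrics, evaluate, train,
)

logger = logging.getLogger("amylstm")

ALGORITHMS = ("knn", "logistic_regression", "random_forest", "svm",
              "gradient_boosting")

#: Small documented hyperparameter grids searched on the validation split.
DEFAULT_GRIDS = {
    "knn": {"n_neighbors": [3, 5, 7, 9]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
    "random_forest": {"n_estimators": [100, 500]},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "gradient_boosting": {"max_depth": [3, 6]},
}


class FeatureError(ValueError):
    """Feature matrix unusable (e.g. zero variance in every column)."""


@dataclass
class BaselineSpec:
    """One (algorithm, descriptor) cell of the classical benchmark grid."""

    algorithm: str
    descriptor: str
    hyperparameter_grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        alias = {"xgb": "gradient_boosting"}
        self.algorithm = alias.get(self.algorithm, self.algorithm)
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.descriptor not in DESCRIPTOR_NAMES:
            raise ValueError(f"unknown descriptor {self.descriptor!r}")
        if not self.hyperparameter_grid:
            self.hyperparameter_grid = {
                k: list(v) for k, v in DEFAULT_GRIDS[self.algorithm].items()
            }


def default_baseline_specs() -> list[BaselineSpec]:
    """The full 5 x 5 = 25-model grid."""
    return [
        BaselineSpec(algorithm=a, descriptor=d)
        for a in ALGORITHMS
        for d in DESCRIPTOR_NAMES
    ]


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "knn":
        return KNeighborsClassifier(**params)
    if algorithm == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if algorithm == "svm":
        # decision-function scores are used for AUROC (monotone in
        # probability; avoids Platt calibration refits)
        return SVC(kernel="rbf", gamma="scale", random_state=seed, **params)
    if algorithm == "gradient_boosting":
        return XGBClassifier(
            n_estimators=100, learning_rate=0.1, random_state=seed,
            n_jobs=1, eval_metric="logloss", **params)
    raise ValueError(algorithm)


def _scores(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function") and isinstance(estimator, SVC):
        return estimator.decision_function(X)
    return estimator.predict_proba(X)[:, 1]


def fit_baseline(
    spec: BaselineSpec,
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    seed: int = 0,
):
    """Grid-search one baseline on validation AUROC.

    Every grid point is fitted on the training features and scored on the
    validation features; the first maximizer in declared grid order wins.
    Returns ``(fitted_estimator, chosen_params, val_auroc)``.
    """
    if np.allclose(X_train.var(axis=0), 0):
        raise FeatureError(
            f"{spec.algorithm}/{spec.descriptor}: all feature columns have "
            "zero variance"
        )
    keys = list(spec.hyperparameter_grid)
    best = None
    for combo in itertools.product(*(spec.hyperparameter_grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        est = _make_estimator(spec.algorithm, params, seed)
        est.fit(X_train, y_train)
        auroc = compute_metrics(y_val, _scores(est, X_val)).auroc
        if best is None or auroc > best[2]:
            best = (est, params, auroc)
    return best


def _membership_digest(records) -> str:
    h = hashlib.sha256()
    for r in sorted(records, key=lambda r: r.id):
        h.update(r.id.encode())
        h.update(r.sequence.encode())
    return h.hexdigest()[:16]


#: Deep ablation variants benchmarked alongside the classical grid.
def default_deep_variants(seed: int = 0) -> list[tuple[str, ModelConfig]]:
    return [
        ("RNN", ModelConfig(cell="rnn", attention=False, seed=seed)),
        ("RNN-Att", ModelConfig(cell="rnn", attention=True, seed=seed)),
        ("GRU", ModelConfig(cell="gru", attention=False, seed=seed)),
        ("GRU-Att", ModelConfig(cell="gru", attention=True, seed=seed)),
        ("Bi-LSTM-Att", ModelConfig(cell="lstm", attention=True, seed=seed)),
    ]


def benchmark_grid(
    train_records, val_records, test_records,
    specs: Optional[Sequence[BaselineSpec]] = None,
    deep_variants: Optional[Sequence[tuple[str, ModelConfig]]] = None,
    train_config: Optional[TrainConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark every classical spec and deep variant on one shared split.

    Returns a table with one row per model (model, features, auroc,
    balanced_accuracy, mcc, f1, plus chosen hyperparameters or an error
    annotation).  Per-model failures become annotated rows; they never abort
    the grid.  The test set is scored exactly once per model and never
    refitted on.
    """
    if specs is None:
        specs = default_baseline_specs()
    if train_config is None:
        train_config = TrainConfig(seed=seed)
    test_digest = _membership_digest(test_records)
    logger.info("benchmark: test membership digest %s", test_digest)
    y_train = np.array([r.label for r in train_records])
    y_val = np.array([r.label for r in val_records])
    y_test = np.array([r.label for r in test_records])

    features: dict[str, tuple] = {}
    rows = []
    for spec in specs:
        try:
            if spec.descriptor not in features:
                features[spec.descriptor] = (
                    featurize_records(train_records, spec.descriptor)[0],
                    featurize_records(val_records, spec.descriptor)[0],
                    featurize_records(test_records, spec.descriptor)[0],
                )
            Xtr, Xval, Xte = features[spec.descriptor]
            est, params, _ = fit_baseline(
                spec, Xtr, y_train, Xval, y_val, seed=seed)
            report = compute_metrics(y_test, _scores(est, Xte))
            rows.append({
                "model": spec.algorithm, "features": spec.descriptor,
                "auroc": report.auroc,
                "balanced_accuracy": report.balanced_accuracy,
                "mcc": report.mcc, "f1": report.f1,
                "hyperparameters": str(params), "error": "",
            })
        except Exception as exc:  # annotated row, grid continues
            logger.warning("baseline %s/%s failed: %s",
                           spec.algorithm, spec.descriptor, exc)
            rows.append({
                "model": spec.algorithm, "features": spec.descriptor,
                "auroc": np.nan, "balanced_accuracy": np.nan,
                "mcc": np.nan, "f1": np.nan,
                "hyperparameters": "", "error": str(exc),
            })

    if deep_variants is None:
        deep_variants = default_deep_variants(seed=seed)
    for name, mc in deep_variants:
        try:
            model = build_model(mc)
            model, _, _ = train(model, train_records, val_records,
                                train_config)
            report = evaluate(model, test_records,
                              max_len=train_config.max_len)
            rows.append({
                "model": name, "features": "sequence",
                "auroc": report.auroc,
                "balanced_accuracy": report.balanced_accuracy,
                "mcc": report.mcc, "f1": report.f1,
                "hyperparameters": "", "error": "",
            })
        except Exception as exc:
            logger.warning("deep variant %s failed: %s", name, exc)
            rows.append({
                "model": name, "features": "sequence",
                "auroc": np.nan, "balanced_accuracy": np.nan,
                "mcc": np.nan, "f1": np.nan,
                "hyperparameters": "", "error": str(exc),
            })
    table = pd.DataFrame(rows)
    table.attrs["test_membership_digest"] = test_digest
    assert _membership_digest(test_records) == test_digest
    return table
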