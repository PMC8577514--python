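"""Gradient-boosted multiclass base learner with per-gene importances.

This module is the contract boundary around the concrete boosting library:
training takes a samples × genes table and per-sample class labels, applies
accuracy-based early stopping on a monitor split carved out of the training
data, and exposes per-gene importance scores (average split gain across
trees).  The default backend is XGBoost; a reference backend built on
scikit-learn's ``GradientBoostingClassifier`` is registered under ``"gbm"``
so the contract can be exercised against a second implementation.

Protocol constants (defaults of :class:`BoosterConfig`): up to 1,000 trees,
maximum depth 50, 80% of genes subsampled per tree, training stopped when
monitor accuracy fails to improve for 50 rounds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import train_test_split

from .dataset import derive_seed
from .errors import ValidationError

BACKENDS = ("xgboost", "gbm")


@dataclass
class BoosterConfig:
    """Boosting protocol constants.

    ``monitor_fraction`` is the share of the training partition held out
    (stratified by class) to drive early stopping; monitoring the CV
    validation fold instead would leak into reported CV accuracy, so that
    mode exists only behind an explicit argument to :func:`train`.
    """

    n_trees: int = 1000
    max_depth: int = 50
    column_subsample: float = 0.8
    early_stopping_patience: int = 50
    monitor_fraction: float = 0.1
    learning_rate: float = 0.3
    seed: int = 0
    backend: str = "xgboost"
    # Histogram resolution for the xgboost backend; 64 bins lose nothing at
    # cohort sizes of a few hundred samples and fit markedly faster.
    max_bin: int = 64

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")
        if not 0 < self.column_subsample <= 1:
            raise ValidationError("column_subsample must be in (0, 1]")
        if self.early_stopping_patience < 1:
            raise ValidationError("early_stopping_patience must be >= 1")
        if not 0 <= self.monitor_fraction < 1:
            raise ValidationError("monitor_fraction must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.backend not in BACKENDS:
            raise ValidationError(f"unknown backend {self.backend!r}")


@dataclass
class TrainedModel:
    """A fitted ensemble plus the metadata needed to apply and audit it."""

    backend: str
    model: object
    class_label_order: list[str]
    genes: list[str]
    importances: dict[str, float]
    n_trees_used: int
    config: BoosterConfig


def _validate_training_inputs(features: pd.DataFrame, labels: pd.Series) -> list[str]:
    if features.shape[0] != len(labels):
        raise ValidationError(
            f"feature rows ({features.shape[0]}) and labels ({len(labels)}) "
            "differ in length"
        )
    if features.shape[1] < 1:
        raise ValidationError("at least one feature is required")
    if features.isna().to_numpy().any():
        raise ValidationError("features contain missing values")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError(
            f"training labels contain a single class ({classes[0]!r})"
        )
    return classes


def _monitor_split(
    y: np.ndarray, n_classes: int, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Stratified train/monitor index split, or None when infeasible."""
    n = len(y)
    n_monitor = int(np.ceil(fraction * n))
    counts = np.bincount(y, minlength=n_classes)
    if (
        fraction <= 0
        or n_monitor < n_classes
        or n - n_monitor < n_classes
        or counts.min() < 2
    ):
        return None
    idx_train, idx_mon = train_test_split(
        np.arange(n),
        test_size=n_monitor,
        stratify=y,
        random_state=seed,
    )
    return np.sort(idx_train), np.sort(idx_mon)


def train(
    features: pd.DataFrame,
    labels: pd.Series,
    config: BoosterConfig | None = None,
    monitor: tuple[pd.DataFrame, pd.Series] | None = None,
) -> TrainedModel:
    """Fit the boosted ensemble with accuracy-based early stopping.

    Parameters
    ----------
    features
        Samples × genes table of expression values (no missing entries).
    labels
        Per-sample class labels; classes are encoded in lexicographic
        order so the model is independent of input row order.
    config
        Protocol constants; defaults follow the module docstring.
    monitor
        Explicit (features, labels) monitor set.  When omitted, a
        stratified ``monitor_fraction`` share of the training data is
        carved out; passing the CV validation fold here is the (leaky)
        alternative and is deliberately opt-in.
    """
    config = config or BoosterConfig()
    config.validate()
    classes = _validate_training_inputs(features, labels)
    class_index = {c: k for k, c in enumerate(classes)}
    y = np.asarray([class_index[v] for v in labels])
    X = features.to_numpy(dtype=np.float64)
    genes = [str(g) for g in features.columns]

    if monitor is not None:
        X_fit, y_fit = X, y
        X_mon = monitor[0].to_numpy(dtype=np.float64)
        y_mon = np.asarray([class_index[v] for v in monitor[1]])
    else:
        split = _monitor_split(
            y, len(classes), config.monitor_fraction, derive_seed(config.seed, 7)
        )
        if split is None:
            X_fit, y_fit, X_mon, y_mon = X, y, None, None
        else:
            idx_fit, idx_mon = split
            X_fit, y_fit = X[idx_fit], y[idx_fit]
            X_mon, y_mon = X[idx_mon], y[idx_mon]
        if X_mon is not None and len(set(y_fit)) < len(classes):
            # degenerate carve-out; fall back to no early stopping
            X_fit, y_fit, X_mon, y_mon = X, y, None, None

    if config.backend == "xgboost":
        model, n_used, scores = _fit_xgboost(
            X_fit, y_fit, X_mon, y_mon, len(classes), config
        )
    else:
        model, n_used, scores = _fit_sklearn_gbm(
            X_fit, y_fit, X_mon, y_mon, config
        )

    importances = {g: 0.0 for g in genes}
    for j, s in scores.items():
        importances[genes[j]] = float(s)
    return TrainedModel(
        backend=config.backend,
        model=model,
        class_label_order=classes,
        genes=genes,
        importances=importances,
        n_trees_used=n_used,
        config=config,
    )


def _fit_xgboost(X_fit, y_fit, X_mon, y_mon, n_classes, config):
    params = {
        "objective": "multi:softmax",
        "num_class": n_classes,
        "max_depth": config.max_depth,
        "colsample_bytree": config.column_subsample,
        "eta": config.learning_rate,
        "tree_method": "hist",
        "max_bin": config.max_bin,
        "nthread": 1,
        "seed": config.seed,
        "eval_metric": "merror",
        "verbosity": 0,
    }
    dtrain = xgb.DMatrix(X_fit, label=y_fit)
    if X_mon is not None:
        dmon = xgb.DMatrix(X_mon, label=y_mon)
        bst = xgb.train(
            params,
            dtrain,
            num_boost_round=config.n_trees,
            evals=[(dmon, "monitor")],
            early_stopping_rounds=config.early_stopping_patience,
            verbose_eval=False,
        )
        n_used = bst.best_iteration + 1
        bst = bst[: n_used]
    else:
        bst = xgb.train(params, dtrain, num_boost_round=config.n_trees)
        n_used = config.n_trees
    raw = bst.get_score(importance_type="gain")
    scores = {int(k[1:]): v for k, v in raw.items()}
    return bst, n_used, scores


def _fit_sklearn_gbm(X_fit, y_fit, X_mon, y_mon, config):
    # Reference backend: subsampling granularity is per split rather than
    # per tree, and early stopping uses log-loss; adequate for contract
    # conformance, not a drop-in replica of the default backend.
    if X_mon is not None:
        X_all = np.vstack([X_fit, X_mon])
        y_all = np.concatenate([y_fit, y_mon])
        est = GradientBoostingClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features=config.column_subsample,
            learning_rate=config.learning_rate,
            random_state=config.seed,
            validation_fraction=len(y_mon) / len(y_all),
            n_iter_no_change=config.early_stopping_patience,
        )
        est.fit(X_all, y_all)
    else:
        est = GradientBoostingClassifier(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features=config.column_subsample,
            learning_rate=config.learning_rate,
            random_state=config.seed,
        )
        est.fit(X_fit, y_fit)
    scores = {
        j: s for j, s in enumerate(est.feature_importances_) if s > 0
    }
    return est, int(est.n_estimators_), scores


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.Series:
    """Hard class label per sample; feature columns must match exactly."""
    cols = [str(c) for c in features.columns]
    if cols != model.genes:
        missing = [g for g in model.genes if g not in cols]
        extra = [c for c in cols if c not in model.genes]
        detail = []
        if missing:
            detail.append(f"missing: {missing[:10]}")
        if extra:
            detail.append(f"unexpected: {extra[:10]}")
        if not detail:
            detail.append("column order differs from the training gene order")
        raise ValidationError(
            "query features do not match the model's training genes — "
            + "; ".join(detail)
        )
    if features.shape[0] == 0:
        return pd.Series([], index=features.index, dtype=object, name="call")
    X = features.to_numpy(dtype=np.float64)
    if model.backend == "xgboost":
        codes = model.model.predict(xgb.DMatrix(X)).astype(int)
    else:
        codes = model.model.predict(X).astype(int)
    labels = [model.class_label_order[c] for c in codes]
    return pd.Series(labels, index=features.index, name="call")


# ---------------------------------------------------------------------------
# Serialization: one JSON file embedding the backend's native model dump
# plus the manifest (config, class order, gene list, importances).
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    if model.backend != "xgboost":
        raise ValidationError(
            f"serialization is supported for the xgboost backend only, "
            f"not {model.backend!r}"
        )
    raw = bytes(model.model.save_raw("json")).decode("utf-8")
    doc = {
        "format": "gbmpanel-model/1",
        "backend": model.backend,
        "config": asdict(model.config),
        "class_label_order": model.class_label_order,
        "genes": model.genes,
        "importances": model.importances,
        "n_trees_used": model.n_trees_used,
        "booster": raw,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "gbmpanel-model/1":
        raise ValidationError(f"{path} is not a gbmpanel model file")
    bst = xgb.Booster()
    bst.load_model(bytearray(doc["booster"].encode("utf-8")))
    return TrainedModel(
        backend=doc["backend"],
        model=bst,
        class_label_order=list(doc["class_label_order"]),
        genes=list(doc["genes"]),
        importances={k: float(v) for k, v in doc["importances"].items()},
        n_trees_used=int(doc["n_trees_used"]),
        config=BoosterConfig(**doc["config"]),
    )
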