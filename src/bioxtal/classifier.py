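"""Training, selection and application of the bio/xtal interface classifier.

The central object is :class:`InterfaceClassifier`, a scikit-learn
compatible estimator wrapping one of five algorithm families (bagging,
random forest, adaptive boosting, gradient boosting, neural network).  On
top of it sit the protocol functions used to build the final model:

* :func:`cross_validate` -- stratified 10-fold cross-validation repeated 10
  times, accuracy per fold computed exactly from the confusion counts,
* :func:`grid_search` -- exhaustive hyperparameter search with ties broken
  toward the simplest model,
* :func:`recursive_feature_elimination` -- iterative pruning driven by the
  Gini importance of a 500-tree random forest,
* :func:`train_final` -- the production model: a 250-tree random forest
  with max-features = log2 on the 22-feature set that survives selection.

Every path is deterministic under a fixed seed.  ``bio`` is the positive
class throughout: sensitivity is the recall on biological interfaces and
specificity the recall on crystallographic ones.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import __version__ as _pkg_version
from .features import FEATURE_SETS, FeatureVector

__all__ = [
    "ALGORITHMS",
    "DEFAULT_GRIDS",
    "TrainingConfig",
    "CVReport",
    "RFEResult",
    "ClassifierModel",
    "Prediction",
    "InterfaceClassifier",
    "compute_accuracy",
    "cross_validate",
    "grid_search",
    "recursive_feature_elimination",
    "train_final",
    "predict",
    "save_model",
    "load_model",
]

ALGORITHMS = ("bagging", "random_forest", "adaboost", "gradient_boosting", "neural_network")

POSITIVE_LABEL = "bio"
NEGATIVE_LABEL = "xtal"

MODEL_FORMAT = "bioxtal-model-1"

#: default candidate grids covering the tuned axes: ensemble size for the
#: four ensembles, split features for bagging/forest, learning rate for the
#: boosters, tree depth for gradient boosting, architecture for the network
DEFAULT_GRIDS = {
    "bagging": {"n_estimators": [10, 50, 100, 250, 500], "max_features": [0.5, 0.75, 1.0]},
    "random_forest": {"n_estimators": [10, 50, 100, 250, 500],
                      "max_features": ["sqrt", "log2", None]},
    "adaboost": {"n_estimators": [10, 50, 100, 250, 500],
                 "learning_rate": [0.01, 0.1, 0.5, 1.0]},
    "gradient_boosting": {"n_estimators": [10, 50, 100, 250, 500],
                          "learning_rate": [0.01, 0.1, 0.5], "max_depth": [1, 2, 3, 5]},
    "neural_network": {"hidden_layer_sizes": [(10,), (50,), (100,)],
                       "activation": ["relu", "tanh", "logistic"]},
}

#: hyperparameter names each algorithm accepts in :class:`InterfaceClassifier`
_VALID_PARAMS = {
    "bagging": {"n_estimators", "max_features"},
    "random_forest": {"n_estimators", "max_features", "max_depth"},
    "adaboost": {"n_estimators", "learning_rate"},
    "gradient_boosting": {"n_estimators", "learning_rate", "max_depth"},
    "neural_network": {"hidden_layer_sizes", "activation"},
}


def compute_accuracy(tp: int, tn: int, p: int, n: int) -> float:
    """Classification accuracy (TP + TN) / (P + N), exact on the counts.

    The ratio is formed in rational arithmetic before conversion to float,
    so confusion matrices with an exactly representable accuracy (e.g.
    184/200 = 0.92) suffer no intermediate rounding.
    """
    if p + n == 0:
        raise ValueError("accuracy is undefined when P + N = 0")
    if not (0 <= tp <= p and 0 <= tn <= n):
        raise ValueError(f"inconsistent confusion counts tp={tp}, tn={tn}, p={p}, n={n}")
    return float(Fraction(tp + tn, p + n))


@dataclass
class TrainingConfig:
    """How to train and evaluate: algorithm, hyperparameters, CV layout, seed."""

    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        bad = set(self.hyperparameters) - _VALID_PARAMS[self.algorithm]
        if bad:
            raise ValueError(
                f"hyperparameters {sorted(bad)} are not valid for {self.algorithm} "
                f"(valid: {sorted(_VALID_PARAMS[self.algorithm])})"
            )


@dataclass
class CVReport:
    """Per-fold accuracies and aggregated confusion counts of a repeated CV."""

    fold_accuracies: list[float]
    mean_accuracy: float
    std: float
    confusion_totals: dict[str, int]
    fold_confusions: list[dict[str, int]] = field(default_factory=list)
    seed: int = 0
    _exact_mean: Fraction | None = None

    @property
    def sensitivity(self) -> float:
        c = self.confusion_totals
        return c["tp"] / (c["tp"] + c["fn"]) if c["tp"] + c["fn"] else float("nan")

    @property
    def specificity(self) -> float:
        c = self.confusion_totals
        return c["tn"] / (c["tn"] + c["fp"]) if c["tn"] + c["fp"] else float("nan")

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": self.fold_accuracies,
            "fold_confusions": self.fold_confusions,
            "mean_accuracy": self.mean_accuracy,
            "std": self.std,
            "confusion_totals": self.confusion_totals,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "seed": self.seed,
        }


class InterfaceClassifier(ClassifierMixin, BaseEstimator):
    """Bio-vs-xtal interface classifier with a named-feature manifest.

    A thin scikit-learn estimator over one of five algorithm families.
    When fitted on a DataFrame (or :class:`FeatureVector` list), the column
    names become the feature manifest and prediction inputs are validated
    and re-ordered by name, never by position.

    Parameters
    ----------
    algorithm : one of ``bagging``, ``random_forest``, ``adaboost``,
        ``gradient_boosting``, ``neural_network``.
    n_estimators : ensemble size (ignored by the neural network).
    max_features : split candidate features for bagging/random forest
        (default ``log2`` for the random forest, all features for bagging).
    learning_rate, max_depth : boosting controls (algorithm defaults when
        None).
    hidden_layer_sizes, activation : network architecture.  The network
    path standardizes features with statistics learned on the training
    data only.
    threshold : posterior probability of ``bio`` above which the label is
        ``bio`` (default 0.5, suited to a balanced training set).
    random_state : seed controlling every stochastic component.
    """

    def __init__(
        self,
        algorithm: str = "random_forest",
        n_estimators: int = 250,
        max_features=None,
        learning_rate: float | None = None,
        max_depth: int | None = None,
        hidden_layer_sizes: tuple = (100,),
        activation: str = "relu",
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.threshold = threshold
        self.random_state = random_state

    # -- construction -------------------------------------------------
    def _build(self):
        seed = self.random_state
        if self.algorithm == "bagging":
            return BaggingClassifier(
                n_estimators=self.n_estimators,
                max_features=self.max_features if self.max_features is not None else 1.0,
                random_state=seed,
            )
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=self.max_features if self.max_features is not None else "log2",
                max_depth=self.max_depth,
                random_state=seed,
            )
        if self.algorithm == "adaboost":
            return AdaBoostClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate if self.learning_rate is not None else 1.0,
                random_state=seed,
            )
        if self.algorithm == "gradient_boosting":
            return GradientBoostingClassifier(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate if self.learning_rate is not None else 0.1,
                max_depth=self.max_depth if self.max_depth is not None else 3,
                random_state=seed,
            )
        if self.algorithm == "neural_network":
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "mlp",
                        MLPClassifier(
                            hidden_layer_sizes=self.hidden_layer_sizes,
                            activation=self.activation,
                            max_iter=1000,
                            random_state=seed,
                        ),
                    ),
                ]
            )
        raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    # -- data marshalling ---------------------------------------------
    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        if isinstance(X, (list, tuple)) and X and isinstance(X[0], FeatureVector):
            sets = {v.feature_set for v in X}
            if len(sets) != 1:
                raise ValueError(f"mixed feature sets: {sorted(sets)}")
            return pd.DataFrame(
                np.vstack([v.values for v in X]), columns=list(X[0].names)
            )
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])

    def _validated(self, X) -> np.ndarray:
        frame = self._as_frame(X)
        manifest = list(self.feature_manifest_)
        if set(frame.columns) != set(manifest):
            if all(c.startswith("x") for c in frame.columns) and len(frame.columns) == len(
                manifest
            ):
                raise ValueError(
                    "unnamed input cannot be validated against the feature manifest; "
                    "pass a DataFrame or FeatureVector list with named features"
                )
            extra = sorted(set(frame.columns) - set(manifest))
            missing = sorted(set(manifest) - set(frame.columns))
            raise ValueError(
                f"feature mismatch with the trained manifest (missing {missing}, extra {extra})"
            )
        return frame[manifest].to_numpy(dtype=float)

    # -- estimator API -------------------------------------------------
    def fit(self, X, y):
        frame = self._as_frame(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.feature_manifest_ = tuple(frame.columns)
        self.estimator_ = self._build()
        self.estimator_.fit(frame.to_numpy(dtype=float), y)
        self.classes_ = self.estimator_.classes_ if not isinstance(
            self.estimator_, Pipeline
        ) else self.estimator_[-1].classes_
        self.n_features_in_ = frame.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._validated(X))

    def p_bio(self, X) -> np.ndarray:
        """Posterior probability of the biological class for each row."""
        proba = self.predict_proba(X)
        idx = list(self.classes_).index(POSITIVE_LABEL)
        return proba[:, idx]

    def predict(self, X) -> np.ndarray:
        p = self.p_bio(X)
        return np.where(p >= self.threshold, POSITIVE_LABEL, NEGATIVE_LABEL)

    @property
    def feature_importances_(self) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        return self.estimator_.feature_importances_


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    pos = y_true == POSITIVE_LABEL
    tp = int(np.sum(pos & (y_pred == POSITIVE_LABEL)))
    tn = int(np.sum(~pos & (y_pred == NEGATIVE_LABEL)))
    return tp, tn, int(pos.sum()), int((~pos).sum())


def _estimator_from_config(config: TrainingConfig) -> InterfaceClassifier:
    return InterfaceClassifier(
        algorithm=config.algorithm, random_state=config.seed, **config.hyperparameters
    )


def cross_validate(X, y, config: TrainingConfig | None = None) -> CVReport:
    """Stratified k-fold cross-validation, repeated with re-drawn splits.

    Accuracy on each held-out fold is computed exactly from the fold's
    confusion counts; the report aggregates all ``n_folds * n_repeats``
    folds and the summed confusion matrix.
    """
    config = config or TrainingConfig()
    base = _estimator_from_config(config)
    frame = InterfaceClassifier._as_frame(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    if counts.min() < config.n_folds:
        raise ValueError(
            f"need at least n_folds={config.n_folds} samples per class, got {counts.min()}"
        )

    splitter = (
        RepeatedStratifiedKFold(
            n_splits=config.n_folds, n_repeats=config.n_repeats, random_state=config.seed
        )
        if config.n_repeats > 1
        else StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    )
    fold_fracs: list[Fraction] = []
    fold_confusions: list[dict[str, int]] = []
    totals = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for train_idx, test_idx in splitter.split(frame, y):
        model = clone(base).fit(frame.iloc[train_idx], y[train_idx])
        y_pred = model.predict(frame.iloc[test_idx])
        tp, tn, p, n = _confusion(y[test_idx], y_pred)
        fold_fracs.append(Fraction(tp + tn, p + n))
        fold_confusions.append({"tp": tp, "tn": tn, "p": p, "n": n})
        totals["tp"] += tp
        totals["tn"] += tn
        totals["fp"] += n - tn
        totals["fn"] += p - tp
    exact_mean = sum(fold_fracs, Fraction(0)) / len(fold_fracs)
    accs = [float(f) for f in fold_fracs]
    return CVReport(
        fold_accuracies=accs,
        mean_accuracy=float(exact_mean),
        std=float(np.std(accs)),
        confusion_totals=totals,
        fold_confusions=fold_confusions,
        seed=config.seed,
        _exact_mean=exact_mean,
    )


def _complexity(params: dict) -> tuple:
    """Simplicity key for tie-breaking: fewest estimators, then smallest depth."""
    size = params.get("hidden_layer_sizes")
    hidden = sum(size) if isinstance(size, (tuple, list)) else (size or 0)
    return (
        params.get("n_estimators", 0),
        params.get("max_depth") or 0,
        hidden,
    )


def grid_search(X, y, algorithm: str, grid: dict, config: TrainingConfig | None = None):
    """Exhaustive grid search; returns ``(best_params, best_report, all_results)``.

    Ties on the exact mean CV accuracy are broken toward the simplest
    model: fewest base estimators, then smallest tree depth / hidden layer.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    config = config or TrainingConfig(algorithm=algorithm)
    keys = sorted(grid)
    results = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        combo_config = TrainingConfig(
            algorithm=algorithm,
            hyperparameters=params,
            n_folds=config.n_folds,
            n_repeats=config.n_repeats,
            seed=config.seed,
        )
        report = cross_validate(X, y, combo_config)
        results.append((params, report))
    best_params, best_report = min(
        results, key=lambda pr: (-(pr[1]._exact_mean), _complexity(pr[0]))
    )
    return best_params, best_report, results


@dataclass
class RFEResult:
    """Outcome of recursive feature elimination."""

    ranking: list[str]  # most important first (reverse order of elimination)
    selected: tuple[str, ...]
    history: list[dict]  # one entry per elimination round


def recursive_feature_elimination(
    X,
    y,
    config: TrainingConfig | None = None,
    n_trees: int = 500,
) -> RFEResult:
    """Rank features by Gini importance and prune until accuracy stops gaining.

    At each round a ``n_trees``-tree random forest is fitted on the current
    feature subset; its mean-decrease-in-Gini importances identify the
    least important feature, which is removed after recording the subset's
    cross-validated accuracy.  The retained subset is the smallest one
    whose accuracy is within one standard deviation of the best round.
    """
    config = config or TrainingConfig(n_repeats=1)
    frame = InterfaceClassifier._as_frame(X)
    if frame.shape[1] < 2:
        raise ValueError("feature elimination needs at least two features")
    y = np.asarray(y)

    current = list(frame.columns)
    history: list[dict] = []
    elimination_order: list[str] = []
    while current:
        forest = InterfaceClassifier(
            algorithm="random_forest",
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=config.seed,
        ).fit(frame[current], y)
        importances = dict(zip(current, forest.feature_importances_))
        cv_config = TrainingConfig(
            algorithm="random_forest",
            hyperparameters={"n_estimators": n_trees, "max_features": "sqrt"},
            n_folds=config.n_folds,
            n_repeats=config.n_repeats,
            seed=config.seed,
        )
        report = cross_validate(frame[current], y, cv_config)
        history.append(
            {
                "features": tuple(current),
                "mean_accuracy": report.mean_accuracy,
                "std": report.std,
                "importances": importances,
            }
        )
        if len(current) == 1:
            elimination_order.append(current.pop())
            break
        weakest = min(current, key=lambda f: (importances[f], current.index(f)))
        elimination_order.append(weakest)
        current.remove(weakest)

    best = max(history, key=lambda h: h["mean_accuracy"])
    floor = best["mean_accuracy"] - best["std"]
    eligible = [h for h in history if h["mean_accuracy"] >= floor]
    selected = min(eligible, key=lambda h: len(h["features"]))["features"]
    ranking = list(reversed(elimination_order))
    return RFEResult(ranking=ranking, selected=selected, history=history)


@dataclass
class ClassifierModel:
    """A trained classifier with its feature manifest and training metadata."""

    estimator: InterfaceClassifier
    feature_manifest: tuple[str, ...]
    metadata: dict

    def predict(self, vectors):
        return predict(self, vectors)


def _training_hash(frame: pd.DataFrame, y) -> str:
    digest = hashlib.sha256()
    digest.update(frame.to_csv(index=False).encode())
    digest.update(",".join(map(str, y)).encode())
    return digest.hexdigest()[:16]


def train_final(X, y, seed: int = 0) -> ClassifierModel:
    """Train the production model: 250-tree random forest, max-features log2.

    ``X`` must carry the 22-feature manifest that survives feature
    selection (the full contact/LD set minus K, CC, W, N and PP).
    """
    frame = InterfaceClassifier._as_frame(X)
    manifest = FEATURE_SETS["FINAL22"]
    if set(frame.columns) != set(manifest):
        raise ValueError(
            f"training table does not carry the FINAL22 manifest "
            f"(got {sorted(frame.columns)})"
        )
    frame = frame[list(manifest)]
    model = InterfaceClassifier(
        algorithm="random_forest", n_estimators=250, max_features="log2", random_state=seed
    ).fit(frame, y)
    return ClassifierModel(
        estimator=model,
        feature_manifest=manifest,
        metadata={
            "format": MODEL_FORMAT,
            "package_version": _pkg_version,
            "algorithm": "random_forest",
            "hyperparameters": {"n_estimators": 250, "max_features": "log2"},
            "seed": seed,
            "training_hash": _training_hash(frame, y),
            "n_training": len(frame),
        },
    )


@dataclass
class Prediction:
    """Classification outcome for one entry."""

    entry_id: str
    label: str  # "bio", "xtal" or "error"
    p_bio: float
    error: str | None = None


def predict(model: ClassifierModel, vectors) -> list[Prediction]:
    """Apply a trained model; entries with invalid features fail individually."""
    if not vectors:
        return []
    if isinstance(vectors, FeatureVector):
        vectors = [vectors]
    predictions: list[Prediction] = []
    for vec in vectors:
        entry = vec.entry_id or ""
        try:
            if set(vec.names) != set(model.feature_manifest):
                raise ValueError(
                    f"feature names do not match the model manifest "
                    f"({vec.feature_set} vs {len(model.feature_manifest)} features)"
                )
            if not np.all(np.isfinite(vec.values)):
                bad = [n for n, v in zip(vec.names, vec.values) if not np.isfinite(v)]
                raise ValueError(f"non-finite feature value(s): {bad}")
            frame = pd.DataFrame([vec.as_dict()])
            p = float(model.estimator.p_bio(frame)[0])
            label = POSITIVE_LABEL if p >= model.estimator.threshold else NEGATIVE_LABEL
            predictions.append(Prediction(entry_id=entry, label=label, p_bio=p))
        except ValueError as exc:
            predictions.append(
                Prediction(entry_id=entry, label="error", p_bio=float("nan"), error=str(exc))
            )
    return predictions


def save_model(model: ClassifierModel, path) -> None:
    """Persist a trained model (versioned archive with embedded manifest)."""
    joblib.dump(
        {
            "format": MODEL_FORMAT,
            "estimator": model.estimator,
            "feature_manifest": model.feature_manifest,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path) -> ClassifierModel:
    """Load a model saved by :func:`save_model`; wrong formats fail loudly."""
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
        raise ValueError(
            f"{path} is not a {MODEL_FORMAT} archive; refusing to load "
            f"(found format {payload.get('format') if isinstance(payload, dict) else type(payload)})"
        )
    return ClassifierModel(
        estimator=payload["estimator"],
        feature_manifest=tuple(payload["feature_manifest"]),
        metadata=payload["metadata"],
    )
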