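"""RUS-boosted decision-tree classification of tumor grade and tissue type.

The cohort is heavily imbalanced (e.g. 22 high-grade-glioma samples versus 7
low-grade ones after excluding non-pathological tissue), so plain boosting
would maximize accuracy by ignoring the smallest class.  RUSBoost combines
AdaBoost.M2-style boosting on the pseudo-loss with random under-sampling
(RUS): at every boosting iteration each non-minority class is randomly
down-sampled to (a multiple of) the minority-class size before the weak
learner — a depth-limited decision tree — is fitted.  Observation weights
are maintained on the full training set, so examples dropped in one
iteration still steer later ones.

:class:`RUSBoostClassifier` follows the scikit-learn estimator protocol
(``fit`` / ``predict`` / ``predict_proba``, ``get_params`` / ``set_params``)
and composes with scikit-learn model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "ClassifierConfig",
    "CVResult",
    "RUSBoostClassifier",
    "build_datasets",
    "rusboost_train",
    "cross_validate",
]

logger = logging.getLogger(__name__)

FEATURES = {"ppix_only": ["tau_ppix_ns"], "nadh_ppix": ["tau_nadh_ns", "tau_ppix_ns"]}
TASK_LABELS = {"grade": "grade", "tissue": "tissue"}


@dataclass
class ClassifierConfig:
    """Classification hyper-parameters and evaluation settings."""

    n_learners: int = 30
    learning_rate: float = 0.1
    max_tree_splits: int = 20
    undersample_ratio: float = 1.0  # x minority size per class per iteration
    n_folds: int = 5
    seed: int = 0
    feature_set: str = "nadh_ppix"  # "ppix_only" | "nadh_ppix"
    patient_grouped_cv: bool = False

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.feature_set not in FEATURES:
            raise ValueError(f"feature_set must be one of {sorted(FEATURES)}")


@dataclass
class CVResult:
    """Pooled cross-validation outcome for one task and feature set."""

    task: str
    feature_set: str
    overall_accuracy: float
    classes: list[str]
    confusion_counts: np.ndarray  # (true, predicted)
    confusion_rates: np.ndarray  # row-normalized, percent
    fold_assignments: np.ndarray
    n_observations: int

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "feature_set": self.feature_set,
            "overall_accuracy": self.overall_accuracy,
            "classes": self.classes,
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_rates_percent": self.confusion_rates.tolist(),
            "n_observations": self.n_observations,
        }


class RUSBoostClassifier(ClassifierMixin, BaseEstimator):
    """Random-under-sampling boosted decision trees (AdaBoost.M2 pseudo-loss).

    Parameters
    ----------
    n_estimators : int
        Number of boosting iterations.
    learning_rate : float in (0, 1]
        Shrinkage applied in the weight-update exponent.
    max_tree_splits : int
        Split budget of each weak tree (``max_leaf_nodes = splits + 1``).
    undersample_ratio : float or None
        Each non-minority class is down-sampled to ``ratio * minority size``
        per iteration; ``None`` disables under-sampling (plain boosting).
    random_state : int or None

    Attributes
    ----------
    classes_ : ndarray of class labels
    estimators_ : list of fitted weak trees
    estimator_log_weights_ : ndarray of ``ln(1/beta_t)`` vote weights
    """

    def __init__(
        self,
        n_estimators: int = 30,
        learning_rate: float = 0.1,
        max_tree_splits: int = 20,
        undersample_ratio: float | None = 1.0,
        random_state: int | None = None,
    ) -> None:
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_tree_splits = max_tree_splits
        self.undersample_ratio = undersample_ratio
        self.random_state = random_state

    def _undersample(
        self, y_idx: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Indices of a class-rebalanced subset (all minority, RUS majority)."""
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        minority = counts[counts > 0].min()
        target = max(1, int(round(self.undersample_ratio * minority)))
        keep: list[np.ndarray] = []
        for c in range(len(self.classes_)):
            members = np.flatnonzero(y_idx == c)
            if members.size <= target:
                keep.append(members)
            else:
                keep.append(rng.choice(members, size=target, replace=False))
        return np.concatenate(keep)

    def fit(self, X, y) -> "RUSBoostClassifier":
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least two classes")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)

        # AdaBoost.M2 weight matrix over (observation, wrong label)
        w = np.full((n, n_classes), 1.0 / (n * (n_classes - 1)))
        w[np.arange(n), y_idx] = 0.0

        self.estimators_: list[DecisionTreeClassifier] = []
        self.estimator_log_weights_: list[float] = []
        self.n_discarded_ = 0

        base = DecisionTreeClassifier(
            max_leaf_nodes=self.max_tree_splits + 1,
        )

        t = 0
        attempts = 0
        max_attempts = 4 * self.n_estimators
        while t < self.n_estimators and attempts < max_attempts:
            attempts += 1
            w_row = w.sum(axis=1)
            d = w_row / w_row.sum()  # observation weights
            with np.errstate(invalid="ignore", divide="ignore"):
                q = np.where(w_row[:, None] > 0, w / np.maximum(w_row[:, None], 1e-300), 0.0)

            if self.undersample_ratio is None:
                sel = np.arange(n)
            else:
                sel = self._undersample(y_idx, rng)
            tree = clone(base)
            tree.set_params(random_state=int(rng.integers(2**31 - 1)))
            sw = d[sel]
            if sw.sum() <= 0:
                sw = None
            tree.fit(X[sel], y_idx[sel], sample_weight=sw)

            # per-class confidence h(x, y) in [0, 1] on the full training set
            h = np.zeros((n, n_classes))
            h[:, tree.classes_] = tree.predict_proba(X)

            h_true = h[np.arange(n), y_idx]
            pseudo_loss = 0.5 * float(
                np.sum(d * (1.0 - h_true + np.sum(q * h, axis=1)))
            )
            if pseudo_loss >= 0.5:
                # weak learner no better than chance on the weighted problem:
                # discard it and restart from uniform weights
                self.n_discarded_ += 1
                logger.info(
                    "discarding learner with pseudo-loss %.3f; resetting weights",
                    pseudo_loss,
                )
                w = np.full((n, n_classes), 1.0 / (n * (n_classes - 1)))
                w[np.arange(n), y_idx] = 0.0
                continue
            pseudo_loss = max(pseudo_loss, 1e-10)
            beta = pseudo_loss / (1.0 - pseudo_loss)
            exponent = self.learning_rate * 0.5 * (1.0 + h_true[:, None] - h)
            w = w * beta**exponent
            w[np.arange(n), y_idx] = 0.0

            self.estimators_.append(tree)
            self.estimator_log_weights_.append(float(np.log(1.0 / beta)))
            t += 1

        if not self.estimators_:
            raise RuntimeError("boosting failed: every weak learner was discarded")
        self.estimator_log_weights_ = np.asarray(self.estimator_log_weights_)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = check_array(X, dtype=float)
        n_classes = len(self.classes_)
        scores = np.zeros((X.shape[0], n_classes))
        for tree, lw in zip(self.estimators_, self.estimator_log_weights_):
            h = np.zeros_like(scores)
            h[:, tree.classes_] = tree.predict_proba(X)
            scores += lw * h
        return scores

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        total = scores.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return scores / total

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def build_datasets(
    cohort_table: pd.DataFrame, feature_set: str = "nadh_ppix"
) -> dict[str, tuple[pd.DataFrame, pd.Series, pd.Series]]:
    """Grade and tissue classification datasets from the cohort table.

    Non-pathological rows are removed from both tasks (too few samples to
    form a class).  Returns per task a ``(X, y, patient)`` triple where ``X``
    holds the configured lifetime features.
    """
    if feature_set not in FEATURES:
        raise ValueError(f"feature_set must be one of {sorted(FEATURES)}")
    df = cohort_table[cohort_table["tissue"] != "NPL"].reset_index(drop=True)
    datasets = {}
    for task, label_col in TASK_LABELS.items():
        labels = df[label_col]
        counts = labels.value_counts()
        empty = counts[counts == 0]
        if len(empty):
            raise ValueError(f"empty class in task {task}: {list(empty.index)}")
        datasets[task] = (df[FEATURES[feature_set]], labels, df["patient_id"])
    return datasets


def rusboost_train(
    X, y, config: ClassifierConfig | None = None
) -> RUSBoostClassifier:
    """Fit one RUSBoost ensemble with the configured hyper-parameters."""
    config = ClassifierConfig() if config is None else config
    model = RUSBoostClassifier(
        n_estimators=config.n_learners,
        learning_rate=config.learning_rate,
        max_tree_splits=config.max_tree_splits,
        undersample_ratio=config.undersample_ratio,
        random_state=config.seed,
    )
    return model.fit(np.asarray(X, dtype=float), np.asarray(y))


def cross_validate(
    X,
    y,
    config: ClassifierConfig | None = None,
    *,
    task: str = "tissue",
    groups: np.ndarray | None = None,
) -> CVResult:
    """Fivefold cross-validation with pooled confusion matrix.

    Folds are drawn uniformly over observations, ignoring patient and sample
    grouping (multiple samples of one patient may straddle the train/test
    split — an acknowledged over-fit-prone but class-preserving choice for
    tiny minority classes).  If a random split leaves a training fold without
    some class, the partition is redrawn stratified.  Optionally
    ``patient_grouped_cv`` leaves whole patients out instead.
    """
    config = ClassifierConfig() if config is None else config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)

    if config.patient_grouped_cv:
        if groups is None:
            raise ValueError("patient_grouped_cv requires groups")
        from sklearn.model_selection import GroupKFold

        splitter = GroupKFold(n_splits=config.n_folds)
        splits = list(splitter.split(X, y, groups))
    else:
        kf = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        splits = list(kf.split(X))
        if any(len(np.unique(y[tr])) < len(classes) for tr, _ in splits):
            logger.info("plain KFold left a fold without a class; re-drawing stratified")
            skf = StratifiedKFold(
                n_splits=config.n_folds, shuffle=True, random_state=config.seed
            )
            splits = list(skf.split(X, y))

    y_pred = np.empty(y.shape, dtype=y.dtype)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splits):
        model = RUSBoostClassifier(
            n_estimators=config.n_learners,
            learning_rate=config.learning_rate,
            max_tree_splits=config.max_tree_splits,
            undersample_ratio=config.undersample_ratio,
            random_state=config.seed + 1000 * (fold + 1),
        )
        model.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = model.predict(X[test_idx])
        fold_of[test_idx] = fold

    counts = _sk_confusion(y, y_pred, labels=classes)
    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    rates = 100.0 * counts / np.where(row_sums == 0, 1.0, row_sums)
    accuracy = float(np.trace(counts) / counts.sum())
    return CVResult(
        task=task,
        feature_set=config.feature_set,
        overall_accuracy=accuracy,
        classes=[str(c) for c in classes],
        confusion_counts=counts,
        confusion_rates=rates,
        fold_assignments=fold_of,
        n_observations=len(y),
    )
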