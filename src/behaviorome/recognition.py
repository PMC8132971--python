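"""Activity recognition: window features -> activity labels.

Both the home recognizer (ambient events, 30-event sliding windows) and the
mobile recognizer (watch samples, 5 s windows) are 100-tree random forests
over the extracted window features.  Specialized context categories
(airplane ... sport) get dedicated one-vs-rest detectors whose training
points are weighted inversely to their binary class's relative frequency, to
counter heavy imbalance.

Evaluation follows the deployment protocol: leave one home (or one subject)
out entirely, train on the rest, and pool held-out predictions across folds
into macro-averaged precision / recall / f1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_recall_fscore_support

from .vocab import HOME_ACTIVITIES, MOBILE_ACTIVITIES, ONE_CLASS_CATEGORIES

N_TREES = 100

_VOCABULARIES = {"home": HOME_ACTIVITIES, "mobile": MOBILE_ACTIVITIES}


@dataclass
class ActivityModel:
    forest: RandomForestClassifier
    modality: str  # "home" | "mobile"
    vocabulary: tuple[str, ...]
    feature_names: tuple[str, ...]
    seed: int


def train_activity_model(
    features: pd.DataFrame,
    labels: np.ndarray,
    modality: str,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> ActivityModel:
    """Fit a random-forest activity recognizer on labeled windows."""
    if modality not in _VOCABULARIES:
        raise ValueError(f"unknown modality {modality!r}")
    vocab = _VOCABULARIES[modality]
    labels = np.asarray(labels, dtype=object)
    unknown = sorted(set(labels) - set(vocab))
    if unknown:
        raise ValueError(f"labels {unknown} not in the {modality} vocabulary")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least two activity classes")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(features.to_numpy(dtype=float), labels)
    return ActivityModel(forest, modality, vocab, tuple(features.columns), seed)


def predict_activities(model: ActivityModel, features: pd.DataFrame) -> np.ndarray:
    """One label per window row; labels always come from the model's
    vocabulary, and the feature ordering must match training."""
    if tuple(features.columns) != model.feature_names:
        raise ValueError("feature columns do not match the model's training ordering")
    if len(features) == 0:
        return np.empty(0, dtype=object)
    return model.forest.predict(features.to_numpy(dtype=float)).astype(object)


# ---------------------------------------------------------------------------
# one-class detectors
# ---------------------------------------------------------------------------


@dataclass
class OneClassModel:
    category: str
    forest: RandomForestClassifier
    feature_names: tuple[str, ...]


def inverse_frequency_weights(binary: np.ndarray) -> np.ndarray:
    """Instance weights inversely proportional to the binary class's relative
    frequency (a class covering 10% of the data gets 10x weight)."""
    binary = np.asarray(binary, dtype=bool)
    freq_pos = binary.mean()
    freq_neg = 1.0 - freq_pos
    w = np.where(binary, 1.0 / max(freq_pos, 1e-12), 1.0 / max(freq_neg, 1e-12))
    return w


def train_one_class_models(
    features: pd.DataFrame,
    categories: np.ndarray,
    which: tuple[str, ...] | None = None,
    seed: int = 0,
    n_trees: int = N_TREES,
) -> dict[str, OneClassModel]:
    """One weighted in-category-vs-rest forest per specialized category.

    ``categories`` holds the per-window ground-truth category ("" = none).
    Only categories with at least one positive window are fitted.
    """
    cats = np.asarray(categories, dtype=object)
    wanted = ONE_CLASS_CATEGORIES if which is None else which
    unknown = sorted(set(wanted) - set(ONE_CLASS_CATEGORIES))
    if unknown:
        raise ValueError(f"unknown one-class categories {unknown}")
    X = features.to_numpy(dtype=float)
    models: dict[str, OneClassModel] = {}
    for cat in wanted:
        positive = cats == cat
        if not positive.any() or positive.all():
            continue
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        forest.fit(X, positive, sample_weight=inverse_frequency_weights(positive))
        models[cat] = OneClassModel(cat, forest, tuple(features.columns))
    return models


def predict_one_class(models: dict[str, OneClassModel], features: pd.DataFrame) -> pd.DataFrame:
    """Boolean frame (windows x categories) of detector outputs."""
    out = {}
    X = features.to_numpy(dtype=float)
    for cat, model in models.items():
        if tuple(features.columns) != model.feature_names:
            raise ValueError("feature columns do not match the detector's training ordering")
        out[cat] = model.forest.predict(X).astype(bool)
    return pd.DataFrame(out, index=features.index)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class GroupEvalResult:
    precision: float
    recall: float
    f1: float
    per_fold: pd.DataFrame  # group, n_windows columns
    y_true: np.ndarray
    y_pred: np.ndarray


def evaluate_leave_one_group_out(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    modality: str,
    seed: int = 0,
    n_trees: int = N_TREES,
    max_train_windows: int | None = None,
) -> GroupEvalResult:
    """Leave-one-group-out evaluation (group = home or subject).

    Per fold, one group is held out, a fresh recognizer is trained on the
    rest, and held-out predictions are pooled over folds into macro-averaged
    precision, recall, and f1.  ``max_train_windows`` optionally subsamples
    each fold's training windows (deterministically) to bound runtime.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("leave-one-group-out needs at least two groups")
    labels = np.asarray(labels, dtype=object)
    y_true: list[np.ndarray] = []
    y_pred: list[np.ndarray] = []
    fold_rows = []
    for fold, g in enumerate(uniq):
        test = groups == g
        train = ~test
        idx = np.flatnonzero(train)
        if max_train_windows is not None and len(idx) > max_train_windows:
            rng = np.random.default_rng([seed, fold])
            idx = np.sort(rng.choice(idx, size=max_train_windows, replace=False))
        model = train_activity_model(features.iloc[idx], labels[idx], modality, seed=seed, n_trees=n_trees)
        pred = predict_activities(model, features.loc[test])
        y_true.append(labels[test])
        y_pred.append(pred)
        fold_rows.append({"group": g, "n_windows": int(test.sum())})
    yt = np.concatenate(y_true)
    yp = np.concatenate(y_pred)
    precision, recall, f1, _ = precision_recall_fscore_support(
        yt, yp, average="macro", zero_division=0
    )
    return GroupEvalResult(
        float(precision), float(recall), float(f1), pd.DataFrame(fold_rows), yt, yp
    )
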