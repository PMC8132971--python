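"""Two-stage prediction of clinical scores from demographics + behaviorome.

Stage one ("independent") fits one boosted-tree regressor per clinical score
— target and supplemental alike — on demographics and behaviorome features
only; no clinical variable ever predicts another at this stage.  Stage two
("joint", pseudo-independent) refits one regressor per *target* score whose
inputs additionally include all other clinical scores: ground-truth values
during training, stage-one inferred values at prediction time.  When scores
are mutually correlated, an easy score's stage-one estimate can lift a hard
score's stage-two prediction.

Evaluation is leave-one-subject-out: per fold, score normalization statistics
and both stages are fit on the training subjects only, so the held-out
subject leaks into nothing.  Per-score Pearson correlations between pooled
held-out predictions and actual values are reported for each modality
configuration (home / watch / fusion) and stage.

Boosting uses 100 estimators, learning rate 0.1, and least-squares stagewise
fits; tree depth 3 with sqrt-of-p feature subsampling per split (the
high-dimensional feature table makes exhaustive split search wasteful).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingRegressor

from .assemble import subset_features
from .vocab import TARGET_SCORES

N_ESTIMATORS = 100
LEARNING_RATE = 0.1
MAX_DEPTH = 3
MAX_FEATURES = "sqrt"

CONFIG_LABELS = {"home": "SmartHome", "watch": "Smartwatch", "fusion": "Fusion"}


def make_regressor(seed: int, tag: str = "") -> GradientBoostingRegressor:
    """Boosted-tree regressor with a per-fit random state.

    ``tag`` (score name + stage) decorrelates the column-subsampling noise of
    the many regressors trained from one base seed; sharing one random state
    across fits would make their sampling noise perfectly correlated and
    inflate the variance of any across-score average.
    """
    state = (int(seed) ^ zlib.crc32(tag.encode())) % (2**31)
    return GradientBoostingRegressor(
        n_estimators=N_ESTIMATORS,
        learning_rate=LEARNING_RATE,
        max_depth=MAX_DEPTH,
        max_features=MAX_FEATURES,
        loss="squared_error",
        random_state=state,
    )


# ---------------------------------------------------------------------------
# score normalization and selection
# ---------------------------------------------------------------------------


@dataclass
class ScoreScaler:
    """Per-score min-max map onto [0, 1], fit on training subjects only."""

    mins: pd.Series
    maxs: pd.Series

    def transform(self, scores: pd.DataFrame) -> pd.DataFrame:
        z = (scores - self.mins) / (self.maxs - self.mins)
        return z.clip(0.0, 1.0)

    def inverse(self, normalized: pd.DataFrame) -> pd.DataFrame:
        return normalized * (self.maxs - self.mins) + self.mins


def normalize_scores(train_scores: pd.DataFrame) -> ScoreScaler:
    mins = train_scores.min()
    maxs = train_scores.max()
    constant = mins.index[(maxs - mins) <= 0].tolist()
    if constant:
        raise ValueError(f"scores {constant} are constant on the training data; cannot normalize")
    return ScoreScaler(mins, maxs)


def filter_targets_by_variance(
    normalized: pd.DataFrame,
    threshold: float = 0.1,
    overrides: tuple[str, ...] = ("DEX", "ADLC"),
) -> list[str]:
    """Target scores with variance above ``threshold`` on the [0, 1] scale.

    ``overrides`` are retained regardless of variance (low-variance
    functional measures can still be of interest)."""
    keep = []
    for name in normalized.columns:
        if name in overrides or float(normalized[name].var()) > threshold:
            keep.append(name)
    return keep


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


@dataclass
class Predictor:
    score: str
    stage: str  # "independent" | "joint"
    model: GradientBoostingRegressor
    feature_names: tuple[str, ...]


def train_independent(X: pd.DataFrame, scores: pd.DataFrame, seed: int = 0) -> dict[str, Predictor]:
    """One regressor per clinical score from sensor/demographic features only."""
    if len(X) != len(scores):
        raise ValueError("feature matrix and score table have different numbers of subjects")
    Xv = X.to_numpy(dtype=float)
    out = {}
    for name in scores.columns:
        model = make_regressor(seed, f"independent:{name}")
        model.fit(Xv, scores[name].to_numpy(dtype=float))
        out[name] = Predictor(name, "independent", model, tuple(X.columns))
    return out


def _joint_features(X: pd.DataFrame, scores: pd.DataFrame, target: str) -> pd.DataFrame:
    others = [c for c in scores.columns if c != target]
    return pd.concat([X, scores[others]], axis=1)


def train_joint(
    X: pd.DataFrame,
    scores: pd.DataFrame,
    targets: tuple[str, ...] = TARGET_SCORES,
    independent: dict[str, Predictor] | None = None,
    seed: int = 0,
    stacked: bool = False,
    stacked_folds: int = 5,
) -> dict[str, Predictor]:
    """Stage-two regressors for the target scores.

    By default the other-score features are **ground-truth** values during
    training (matching the inference wiring only approximately, since test
    time supplies stage-one estimates).  ``stacked=True`` instead uses
    out-of-fold stage-one predictions as training features, aligning the
    train and test feature distributions at extra cost.
    """
    if independent is None:
        raise ValueError("joint training requires the fitted independent stage")
    if stacked:
        oof = pd.DataFrame(index=X.index, columns=scores.columns, dtype=float)
        folds = np.arange(len(X)) % stacked_folds
        for k in range(stacked_folds):
            tr = folds != k
            inner = train_independent(X.loc[tr], scores.loc[tr], seed=seed)
            for name, pred in inner.items():
                oof.loc[~tr, name] = pred.model.predict(X.loc[~tr].to_numpy(dtype=float))
        score_feats = oof.clip(0.0, 1.0)
    else:
        score_feats = scores
    out = {}
    for target in targets:
        if target not in scores.columns:
            raise ValueError(f"target {target!r} missing from the score table")
        feats = _joint_features(X, score_feats, target)
        model = make_regressor(seed, f"joint:{target}")
        model.fit(feats.to_numpy(dtype=float), scores[target].to_numpy(dtype=float))
        out[target] = Predictor(target, "joint", model, tuple(feats.columns))
    return out


def predict_independent(predictors: dict[str, Predictor], X: pd.DataFrame) -> pd.DataFrame:
    preds = {}
    Xv = X.to_numpy(dtype=float)
    for name, p in predictors.items():
        if tuple(X.columns) != p.feature_names:
            raise ValueError("feature columns do not match the predictor's training ordering")
        preds[name] = np.clip(p.model.predict(Xv), 0.0, 1.0)
    return pd.DataFrame(preds, index=X.index)


def predict_two_stage(
    independent: dict[str, Predictor],
    joint: dict[str, Predictor],
    X: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage-one predictions for every score, then stage-two target
    predictions consuming the stage-one estimates of all *other* scores.
    Both are clipped to the normalized [0, 1] score scale."""
    stage1 = predict_independent(independent, X)
    stage2 = {}
    for target, p in joint.items():
        feats = _joint_features(X, stage1, target)
        if tuple(feats.columns) != p.feature_names:
            raise ValueError("joint feature wiring does not match training")
        stage2[target] = np.clip(p.model.predict(feats.to_numpy(dtype=float)), 0.0, 1.0)
    return stage1, pd.DataFrame(stage2, index=X.index)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def pearson_r(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Product-moment correlation; NaN sentinel (with a warning) when either
    input is constant, so one degenerate score cannot abort an evaluation."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual have different lengths")
    if predicted.size < 3:
        raise ValueError("pearson_r requires at least 3 pairs")
    if np.std(predicted) == 0 or np.std(actual) == 0:
        warnings.warn("constant input to pearson_r; returning NaN sentinel")
        return float("nan")
    return float(sps.pearsonr(predicted, actual).statistic)


@dataclass
class EvalResult:
    """Per-score LOSO correlations for each modality x stage configuration."""

    table: pd.DataFrame  # rows: targets + "Average"; columns: e.g. SmartHome-I
    predictions: pd.DataFrame  # long format: subject, config, stage, score, pred, actual


def loso_evaluate(
    demographics: pd.DataFrame,
    behaviorome: pd.DataFrame,
    scores: pd.DataFrame,
    configs: tuple[str, ...] = ("home", "watch", "fusion"),
    targets: tuple[str, ...] = TARGET_SCORES,
    seed: int = 0,
    stages: tuple[str, ...] = ("independent", "joint"),
    stacked: bool = False,
) -> EvalResult:
    """Leave-one-subject-out evaluation of both stages.

    For every held-out subject, score normalization and all predictors are
    refit on the remaining subjects (per modality configuration); pooled
    held-out predictions yield one Pearson r per target score and
    configuration, plus across-target averages.
    """
    if len(demographics) < 3:
        raise ValueError("LOSO evaluation needs at least 3 subjects")
    if not set(targets) <= set(scores.columns):
        raise ValueError("score table lacks some target scores")
    subjects = demographics.index
    rows = []
    for config in configs:
        X_all = pd.concat([demographics, subset_features(behaviorome, config)], axis=1)
        for subject in subjects:
            train_ids = subjects[subjects != subject]
            scaler = normalize_scores(scores.loc[train_ids])
            y_train = scaler.transform(scores.loc[train_ids])
            y_test = scaler.transform(scores.loc[[subject]])
            X_train, X_test = X_all.loc[train_ids], X_all.loc[[subject]]
            ind = train_independent(X_train, y_train, seed=seed)
            if "joint" in stages:
                joint = train_joint(
                    X_train, y_train, targets=targets, independent=ind, seed=seed, stacked=stacked
                )
                stage1, stage2 = predict_two_stage(ind, joint, X_test)
            else:
                stage1 = predict_independent(ind, X_test)
                stage2 = None
            for t in targets:
                if "independent" in stages:
                    rows.append(
                        dict(subject=subject, config=config, stage="independent", score=t,
                             pred=float(stage1[t].iloc[0]), actual=float(y_test[t].iloc[0]))
                    )
                if stage2 is not None:
                    rows.append(
                        dict(subject=subject, config=config, stage="joint", score=t,
                             pred=float(stage2[t].iloc[0]), actual=float(y_test[t].iloc[0]))
                    )
    preds = pd.DataFrame(rows)

    columns = {}
    for config in configs:
        for stage, suffix in (("independent", "I"), ("joint", "J")):
            if stage not in stages:
                continue
            col = f"{CONFIG_LABELS[config]}-{suffix}"
            vals = {}
            for t in targets:
                sel = preds.query("config == @config and stage == @stage and score == @t")
                vals[t] = pearson_r(sel["pred"].to_numpy(), sel["actual"].to_numpy())
            vals["Average"] = float(np.nanmean([vals[t] for t in targets]))
            columns[col] = vals
    table = pd.DataFrame(columns)
    table = table.reindex([*targets, "Average"])
    return EvalResult(table=table, predictions=preds)
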