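"""Classification harness: scaling, SMOTE balancing, model grid with
cross-validation, F2 scoring, precision-recall curves, and normalized
feature-importance reports.

The evaluation criterion throughout is the F-beta score with beta = 2,

    F2 = 5 * precision * recall / (4 * precision + recall),

which weights recall four times as heavily as precision; the *low*
cognitive state (non-engaged, low attention, low skill) is the positive
class everywhere, so by default metrics are computed with ``pos_label=0``.
The reference point for imbalanced targets is the always-positive
classifier, whose precision is the positive prevalence and recall is 1.

Classifier fitting itself is delegated to scikit-learn; this module owns
the protocol around it (split hygiene, balancing of the training split
only, grid selection by mean CV F2, held-out reporting).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    fbeta_score,
    precision_recall_curve,
    precision_score,
    recall_score,
)
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import RobustScaler, StandardScaler
from sklearn.svm import SVC

from .errors import RangeError, UnsupportedModelError


def fbeta(precision: float, recall: float, beta: float = 2.0) -> float:
    """F-beta from precision and recall; (0, 0) -> 0 by convention."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise RangeError("precision and recall must lie in [0, 1]")
    b2 = beta * beta
    denom = b2 * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + b2) * precision * recall / denom


def baseline_f2(n_positive: int, n_negative: int) -> float:
    """F2 of the trivial always-positive classifier.

    Its precision is the positive prevalence and its recall is 1; with the
    published 60-s attention counts (202 low / 1158 high) this is 0.4659.
    """
    if n_positive < 0 or n_negative < 0:
        raise RangeError("counts must be non-negative")
    total = n_positive + n_negative
    if total == 0:
        raise RangeError("cannot compute a baseline with no samples")
    return fbeta(n_positive / total, 1.0)


# ---------------------------------------------------------------------------
# scaling and balancing
# ---------------------------------------------------------------------------

def scale_features(train: pd.DataFrame, method: str = "standard",
                   test: pd.DataFrame | None = None):
    """Fit a scaler on the training rows only and reuse it on the test rows.

    ``standard``: (x - mean)/sd; ``robust``: (x - median)/IQR.  Constant
    features pass through centered (unit divisor).
    Returns ``(scaled_train, scaled_test_or_None, scaler)``.
    """
    if method == "standard":
        scaler = StandardScaler()
    elif method == "robust":
        scaler = RobustScaler()
    else:
        raise RangeError(f"unknown scaling method {method!r}")
    scaled_train = pd.DataFrame(scaler.fit_transform(train),
                                index=train.index, columns=train.columns)
    scaled_test = None
    if test is not None:
        scaled_test = pd.DataFrame(scaler.transform(test),
                                   index=test.index, columns=test.columns)
    return scaled_train, scaled_test, scaler


def smote_balance(X, y, k: int = 5, seed: int = 0):
    """Synthetic minority oversampling to class parity.

    Each synthetic point lies on the segment between a minority point and
    one of its k nearest minority neighbors, at a uniform position.  Applies
    to the training split only -- callers must never pass test rows here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise RangeError("smote_balance expects a binary target")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    need = int(n_maj - n_min)
    if need == 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    if n_min == 1:
        synth = np.repeat(Xm, need, axis=0)  # duplication fallback
    else:
        if n_min <= k:
            warnings.warn(
                f"minority count {n_min} <= k={k}; reducing k to {n_min - 1}")
            k = int(n_min - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]
        base = rng.integers(0, n_min, size=need)
        partner = neigh[base, rng.integers(0, k, size=need)]
        gaps = rng.uniform(size=(need, 1))
        synth = Xm[base] + gaps * (Xm[partner] - Xm[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(need, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

def make_model(name: str, seed: int = 0, **params):
    """Instantiate a classifier family by short name."""
    registry = {
        "rf": lambda: RandomForestClassifier(
            criterion="gini", n_estimators=100, random_state=seed, n_jobs=1),
        "extra_trees": lambda: ExtraTreesClassifier(
            criterion="gini", n_estimators=100, random_state=seed, n_jobs=1),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(50,), activation="logistic",
            max_iter=500, random_state=seed),
        "knn": lambda: KNeighborsClassifier(n_neighbors=5),
        "svc_linear": lambda: SVC(kernel="linear", probability=True,
                                  random_state=seed),
        "svc_rbf": lambda: SVC(kernel="rbf", probability=True,
                               random_state=seed),
        "logreg": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "qda": lambda: QuadraticDiscriminantAnalysis(),
    }
    if name not in registry:
        raise RangeError(f"unknown model family {name!r}")
    model = registry[name]()
    if params:
        model.set_params(**params)
    return model


#: Published best settings, available as presets.
PRESETS = {
    "engagement_60s": ("rf", {"n_estimators": 1000}),
    "attention_60s": ("rf", {"n_estimators": 100}),
    "focused_attention": ("mlp", {"hidden_layer_sizes": (50,),
                                  "activation": "logistic"}),
    "planning": ("extra_trees", {"n_estimators": 400}),
    "shifting": ("extra_trees", {"n_estimators": 100}),
}

#: Small neighborhoods around the published presets.
DEFAULT_GRID = {
    "rf": [{"n_estimators": n} for n in (100, 400, 1000)],
    "extra_trees": [{"n_estimators": n} for n in (100, 400)],
    "mlp": [{"hidden_layer_sizes": (50,)}],
    "knn": [{"n_neighbors": k} for k in (3, 5, 11)],
}


@dataclass
class ExperimentConfig:
    """Protocol knobs for one modeling experiment."""

    target: str = "engagement"
    modality: str = "eeg"
    window_len: int = 10
    test_size: float = 0.2            # 0.2 for states, 0.3 for skills
    cv_folds: int = 10
    scaling: str = "standard"
    balance: str = "none"             # "none" | "smote"
    models: dict = field(default_factory=lambda: {"rf": [{"n_estimators": 100}]})
    positive_label: int = 0           # the low state is the positive class
    seed: int = 0
    group_by_subject: bool = False

    def __post_init__(self):
        if not 0.0 < self.test_size < 1.0:
            raise RangeError("test_size must be in (0, 1)")
        if self.cv_folds < 2:
            raise RangeError("cv_folds must be >= 2")


@dataclass
class EvaluationMetrics:
    precision: float
    recall: float
    f2: float
    accuracy: float
    pr_curve: list
    average_precision: float
    cv_mean: float
    cv_sd: float


@dataclass
class ModelReport:
    model_name: str
    params: dict
    metrics: EvaluationMetrics
    importances: pd.Series | None
    n_train: int
    n_test: int

    def to_dict(self) -> dict:
        d = {
            "model": self.model_name, "params": self.params,
            "precision": self.metrics.precision, "recall": self.metrics.recall,
            "f2": self.metrics.f2, "accuracy": self.metrics.accuracy,
            "average_precision": self.metrics.average_precision,
            "cv_mean": self.metrics.cv_mean, "cv_sd": self.metrics.cv_sd,
            "n_train": self.n_train, "n_test": self.n_test,
        }
        if self.importances is not None:
            d["importances"] = self.importances.to_dict()
        return d


def pr_curve(y_true, scores, pos_label: int = 0):
    """Precision-recall points over all thresholds plus average precision."""
    y_true = np.asarray(y_true)
    if np.unique(y_true).size < 2:
        raise RangeError("PR curve undefined for a single-class target")
    prec, rec, _ = precision_recall_curve(y_true, scores, pos_label=pos_label)
    ap = float(average_precision_score(y_true, scores, pos_label=pos_label))
    return list(zip(rec.tolist(), prec.tolist())), ap


def _positive_scores(model, X, pos_label):
    if hasattr(model, "predict_proba"):
        idx = list(model.classes_).index(pos_label)
        return model.predict_proba(X)[:, idx]
    if hasattr(model, "decision_function"):
        margin = model.decision_function(X)
        return margin if model.classes_[1] == pos_label else -margin
    return None


def _cv_f2(model, X, y, folds, seed, pos_label, balance="none"):
    """Mean/sd of F2 over stratified folds (shuffled each split).

    When balancing is requested it is applied *inside* each fold, to the
    fold-training portion only, so validation scores are measured on
    untouched, naturally unbalanced data.  Balancing before the fold split
    would leak the synthetic points into validation and inflate CV scores
    of models that can recognize them.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for i, (tr, va) in enumerate(skf.split(X, y)):
        if np.unique(y[tr]).size < 2:
            continue
        Xt, yt = X[tr], y[tr]
        if balance == "smote":
            Xt, yt = smote_balance(Xt, yt, seed=seed + i)
        m = clone(model).fit(Xt, yt)
        scores.append(fbeta_score(y[va], m.predict(X[va]), beta=2.0,
                                  pos_label=pos_label, zero_division=0))
    if not scores:
        return float("nan"), float("nan")
    return float(np.mean(scores)), float(np.std(scores))


def _split(X, y, groups, config: ExperimentConfig):
    for attempt in range(5):
        seed = config.seed + attempt
        if config.group_by_subject and groups is not None:
            gss = GroupShuffleSplit(n_splits=1, test_size=config.test_size,
                                    random_state=seed)
            tr, te = next(gss.split(X, y, groups))
        else:
            tr, te = train_test_split(np.arange(len(y)),
                                      test_size=config.test_size,
                                      random_state=seed, shuffle=True,
                                      stratify=None if config.group_by_subject
                                      else y)
        if np.unique(y[tr]).size >= 2 and np.unique(y[te]).size >= 1:
            return tr, te
    raise RangeError("could not produce a two-class training split in 5 attempts")


def train_eval(config: ExperimentConfig, features: pd.DataFrame, labels,
               groups=None) -> ModelReport:
    """Full protocol: stratified split, train-only scaling and balancing,
    grid selection by mean CV F2, final fit, held-out metrics.

    ``labels`` must be row-aligned with ``features``; rows with any NaN
    feature (QC-flagged windows) are dropped before splitting.
    """
    y = np.asarray(labels)
    X_df = features.reset_index(drop=True)
    keep = ~X_df.isna().any(axis=1).to_numpy()
    X_df, y = X_df.loc[keep].reset_index(drop=True), y[keep]
    groups = np.asarray(groups)[keep] if groups is not None else None
    if np.unique(y).size < 2:
        raise RangeError("need at least two classes to train")

    tr, te = _split(X_df.to_numpy(), y, groups, config)
    X_train, X_test = X_df.iloc[tr], X_df.iloc[te]
    y_train, y_test = y[tr], y[te]

    X_train_s, X_test_s, _ = scale_features(X_train, config.scaling, X_test)
    Xraw, yraw = X_train_s.to_numpy(), y_train

    best = None  # (cv_mean, cv_sd, name, params, model)
    for name, param_grid in config.models.items():
        for params in (param_grid or [{}]):
            model = make_model(name, seed=config.seed, **params)
            cv_mean, cv_sd = _cv_f2(model, Xraw, yraw, config.cv_folds,
                                    config.seed, config.positive_label,
                                    config.balance)
            if best is None or cv_mean > best[0]:
                best = (cv_mean, cv_sd, name, params, model)
    cv_mean, cv_sd, name, params, model = best
    Xt, yt = Xraw, yraw
    if config.balance == "smote":
        Xt, yt = smote_balance(Xt, yt, seed=config.seed)
    model.fit(Xt, yt)

    y_pred = model.predict(X_test_s.to_numpy())
    pos = config.positive_label
    prec = float(precision_score(y_test, y_pred, pos_label=pos, zero_division=0))
    rec = float(recall_score(y_test, y_pred, pos_label=pos, zero_division=0))
    f2 = float(fbeta_score(y_test, y_pred, beta=2.0, pos_label=pos,
                           zero_division=0))
    acc = float(accuracy_score(y_test, y_pred))
    scores = _positive_scores(model, X_test_s.to_numpy(), pos)
    if scores is not None and np.unique(y_test).size > 1:
        curve, ap = pr_curve(y_test, scores, pos)
    else:
        curve, ap = [], float("nan")

    importances = None
    if hasattr(model, "feature_importances_"):
        importances = importance_report(model, X_df.columns,
                                        k=len(X_df.columns))

    metrics = EvaluationMetrics(prec, rec, f2, acc, curve, ap, cv_mean, cv_sd)
    return ModelReport(name, params, metrics, importances,
                       n_train=len(tr), n_test=len(te))


def importance_report(model, feature_names, k: int = 5) -> pd.Series:
    """Top-k per-feature importances, normalized to sum to 1 over all
    features and sorted descending."""
    if not hasattr(model, "feature_importances_"):
        raise UnsupportedModelError(
            f"{type(model).__name__} exposes no feature importances")
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    series = pd.Series(imp, index=list(feature_names)).sort_values(
        ascending=False)
    return series.iloc[: min(k, len(series))]
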