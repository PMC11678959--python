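"""Sleep-stage classification from the 22-feature epoch table.

:class:`SleepStageClassifier` is a scikit-learn compatible estimator with two
schemes. ``one_step`` fits a single 5-class model (W/N1/N2/N3/REM).
``two_step`` first separates W / NREM / REM, then splits rows predicted NREM
into N1/N2/N3 with a second model trained on NREM epochs only; class
probabilities compose multiplicatively, p(N_i) = p(NREM) * p2(N_i).

Class imbalance is handled by per-class sample weights proportional to
(target proportion) / (empirical proportion), with target proportions taken
from typical healthy-adult sleep architecture: N1 5%, N2 45%, N3 25%, REM 25%
(within NREM: N1 20%, N2 66%, N3 14%). Wake has no published target
proportion and gets a neutral weight.

Evaluation follows subject-wise k-fold cross-validation: all recordings of a
subject travel together, and metrics (accuracy, macro-F1, Cohen's kappa,
per-class sensitivity/precision/specificity, row-normalized confusion) are
aggregated across folds.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, cohen_kappa_score, confusion_matrix, f1_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_COLUMNS

__all__ = [
    "STAGES",
    "SleepStageClassifier",
    "StagingMetrics",
    "make_subject_folds",
    "evaluate_stager",
    "restrict_validation_window",
]

STAGES = ("W", "N1", "N2", "N3", "REM")
NREM = ("N1", "N2", "N3")

# typical healthy-adult stage proportions used for re-weighting
ONE_STEP_TARGETS = {"N1": 0.05, "N2": 0.45, "N3": 0.25, "REM": 0.25}
STEP1_TARGETS = {"NREM": 0.75, "REM": 0.25}
STEP2_TARGETS = {"N1": 0.20, "N2": 0.66, "N3": 0.14}


def _make_backend(name: str, seed: int):
    if name == "logreg":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=5000, random_state=seed),
        )
    if name == "linear_svm":
        from sklearn.svm import SVC

        return make_pipeline(
            StandardScaler(),
            SVC(kernel="linear", probability=True, random_state=seed),
        )
    if name == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=300, max_depth=6, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0,
        )
    if name == "lgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(
            n_estimators=300, random_state=seed, n_jobs=1, verbose=-1,
        )
    raise ValueError(f"unknown classifier backend {name!r}")


def _class_weights(y: np.ndarray, targets: dict[str, float]) -> np.ndarray:
    """Per-sample weights proportional to target/empirical class proportion.

    Classes without a target proportion (Wake) keep weight 1. Target classes
    absent from the training data trigger a warning and are dropped from the
    renormalization.
    """
    classes, counts = np.unique(y, return_counts=True)
    emp = dict(zip(classes, counts / len(y)))
    missing = [c for c in targets if c not in emp]
    if missing:
        warnings.warn(f"classes {missing} absent from training data; reweighting "
                      "over present classes only")
    present_targets = {c: p for c, p in targets.items() if c in emp}
    norm = sum(present_targets.values()) or 1.0
    w = {c: 1.0 for c in classes}
    for c, p in present_targets.items():
        w[c] = (p / norm) / emp[c]
    return np.array([w[c] for c in y])


class SleepStageClassifier(ClassifierMixin, BaseEstimator):
    """One-step or two-step sleep stager over the 22-feature epoch vectors.

    Parameters
    ----------
    scheme : {"two_step", "one_step"}
    classifier_name : {"logreg", "linear_svm", "xgboost", "lgbm"}
        Backend for each step; boosted backends are imported lazily.
    class_weights_step1, class_weights_step2 : dict or None
        Target stage proportions; defaults follow typical sleep architecture.
    seed : int
        Random state passed to the backends.
    """

    def __init__(
        self,
        scheme: str = "two_step",
        classifier_name: str = "logreg",
        class_weights_step1: dict | None = None,
        class_weights_step2: dict | None = None,
        seed: int = 0,
    ):
        self.scheme = scheme
        self.classifier_name = classifier_name
        self.class_weights_step1 = class_weights_step1
        self.class_weights_step2 = class_weights_step2
        self.seed = seed

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(FEATURE_COLUMNS)]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_COLUMNS):
            raise ValueError(f"expected {len(FEATURE_COLUMNS)} feature columns")
        return X

    def fit(self, X, y):
        if self.scheme not in ("one_step", "two_step"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        X = self._as_matrix(X)
        y = np.asarray(y, dtype=object)
        bad = set(y) - set(STAGES)
        if bad:
            raise ValueError(f"labels outside the stage set: {sorted(bad)}")
        self.classes_ = np.array([s for s in STAGES if s in set(y)], dtype=object)
        if self.scheme == "one_step":
            targets = self.class_weights_step1 or ONE_STEP_TARGETS
            w = _class_weights(y, targets)
            self.model_ = _make_backend(self.classifier_name, self.seed)
            _fit_weighted(self.model_, X, y, w)
        else:
            y1 = np.where(np.isin(y, NREM), "NREM", y)
            if len(set(y1)) < 2:
                raise ValueError("step-1 training needs at least 2 of W/NREM/REM")
            nrem_mask = np.isin(y, NREM)
            if not nrem_mask.any():
                raise ValueError("two-step scheme requires NREM rows in training data")
            targets1 = self.class_weights_step1 or STEP1_TARGETS
            targets2 = self.class_weights_step2 or STEP2_TARGETS
            self.step1_model_ = _make_backend(self.classifier_name, self.seed)
            _fit_weighted(self.step1_model_, X, y1, _class_weights(y1, targets1))
            y2 = y[nrem_mask]
            if len(set(y2)) < 2:
                raise ValueError("step-2 training needs at least 2 NREM classes")
            self.step2_model_ = _make_backend(self.classifier_name, self.seed)
            _fit_weighted(
                self.step2_model_, X[nrem_mask], y2, _class_weights(y2, targets2)
            )
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-class probabilities over ``classes_`` (rows sum to 1)."""
        check_is_fitted(self, "classes_")
        X = self._as_matrix(X)
        if self.scheme == "one_step":
            proba = self.model_.predict_proba(X)
            cols = {c: j for j, c in enumerate(self.model_.classes_)}
        else:
            p1 = self.step1_model_.predict_proba(X)
            c1 = {c: j for j, c in enumerate(self.step1_model_.classes_)}
            p2 = self.step2_model_.predict_proba(X)
            c2 = {c: j for j, c in enumerate(self.step2_model_.classes_)}
            proba = np.zeros((len(X), len(self.classes_)))
            cols = {c: j for j, c in enumerate(self.classes_)}
            for stage in self.classes_:
                if stage in NREM:
                    if "NREM" in c1 and stage in c2:
                        proba[:, cols[stage]] = p1[:, c1["NREM"]] * p2[:, c2[stage]]
                elif stage in c1:
                    proba[:, cols[stage]] = p1[:, c1[stage]]
            return proba / proba.sum(axis=1, keepdims=True)
        out = np.zeros((len(X), len(self.classes_)))
        for j, c in enumerate(self.classes_):
            if c in cols:
                out[:, j] = proba[:, cols[c]]
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        """Predicted stage labels; two-step composes the step decisions
        (a row predicted W or REM by step 1 keeps that label)."""
        check_is_fitted(self, "classes_")
        X = self._as_matrix(X)
        if self.scheme == "one_step":
            return self.model_.predict(X).astype(object)
        y1 = self.step1_model_.predict(X)
        out = y1.astype(object)
        nrem = y1 == "NREM"
        if nrem.any():
            out[nrem] = self.step2_model_.predict(X[nrem])
        return out


def _fit_weighted(model, X, y, w):
    """Fit with per-sample weights, routing them to the final pipeline step."""
    if hasattr(model, "steps"):
        name = model.steps[-1][0]
        model.fit(X, y, **{f"{name}__sample_weight": w})
    else:
        model.fit(X, y, sample_weight=w)


def make_subject_folds(subject_ids, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Split subjects into k near-equal test folds (sizes differ by <= 1).

    Every subject appears in exactly one test fold, so all of a subject's
    recordings stay on one side of each train/test split.
    """
    subjects = np.unique(np.asarray(list(subject_ids), dtype=object))
    if len(subjects) < k:
        raise ValueError(f"need at least {k} subjects, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    perm = subjects[rng.permutation(len(subjects))]
    return [np.sort(fold) for fold in np.array_split(perm, k)]


@dataclasses.dataclass
class StagingMetrics:
    """Cross-validated staging performance.

    ``confusion_mean``/``confusion_std`` are row-normalized 5x5 matrices
    aggregated across folds (rows = true stage, in ``stages`` order); scalar
    metrics carry fold mean and std; per-class sensitivity (recall),
    precision (PPV) and specificity (TNR) come from the pooled confusion.
    """

    stages: tuple
    accuracy_mean: float
    accuracy_std: float
    macro_f1_mean: float
    macro_f1_std: float
    kappa_mean: float
    kappa_std: float
    confusion_mean: np.ndarray
    confusion_std: np.ndarray
    confusion_pooled: np.ndarray
    sensitivity: dict
    precision: dict
    specificity: dict
    per_fold: pd.DataFrame

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_fold"] = self.per_fold.to_dict(orient="list")
        return d


def evaluate_stager(y_true, y_pred, fold_ids) -> StagingMetrics:
    """Aggregate staging metrics across cross-validation folds."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    fold_ids = np.asarray(fold_ids)
    if not (len(y_true) == len(y_pred) == len(fold_ids)):
        raise ValueError("y_true, y_pred and fold_ids must have equal length")
    bad = (set(y_true) | set(y_pred)) - set(STAGES)
    if bad:
        raise ValueError(f"labels outside the stage set: {sorted(bad)}")

    rows = []
    norm_mats = []
    pooled = np.zeros((len(STAGES), len(STAGES)), dtype=float)
    for fold in np.unique(fold_ids):
        m = fold_ids == fold
        cm = confusion_matrix(y_true[m], y_pred[m], labels=list(STAGES)).astype(float)
        pooled += cm
        with np.errstate(invalid="ignore"):
            norm = cm / cm.sum(axis=1, keepdims=True)
        norm_mats.append(norm)
        # macro-F1 averages over the stages present in this fold (true or
        # predicted), so an absent rare stage does not contribute a zero
        present = [s for s in STAGES if s in set(y_true[m]) | set(y_pred[m])]
        rows.append(
            {
                "fold": fold,
                "accuracy": accuracy_score(y_true[m], y_pred[m]),
                "macro_f1": f1_score(
                    y_true[m], y_pred[m], labels=present, average="macro",
                    zero_division=0,
                ),
                "kappa": cohen_kappa_score(y_true[m], y_pred[m], labels=list(STAGES)),
            }
        )
    per_fold = pd.DataFrame(rows)
    stack = np.array(norm_mats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        conf_mean = np.nanmean(stack, axis=0)
        conf_std = np.nanstd(stack, axis=0)

    tp = np.diag(pooled)
    fn = pooled.sum(axis=1) - tp
    fp = pooled.sum(axis=0) - tp
    tn = pooled.sum() - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = tp / (tp + fn)
        prec = tp / (tp + fp)
        spec = tn / (tn + fp)
    return StagingMetrics(
        stages=STAGES,
        accuracy_mean=float(per_fold["accuracy"].mean()),
        accuracy_std=float(per_fold["accuracy"].std(ddof=0)),
        macro_f1_mean=float(per_fold["macro_f1"].mean()),
        macro_f1_std=float(per_fold["macro_f1"].std(ddof=0)),
        kappa_mean=float(per_fold["kappa"].mean()),
        kappa_std=float(per_fold["kappa"].std(ddof=0)),
        confusion_mean=conf_mean,
        confusion_std=conf_std,
        confusion_pooled=pooled,
        sensitivity={s: float(v) for s, v in zip(STAGES, sens)},
        precision={s: float(v) for s, v in zip(STAGES, prec)},
        specificity={s: float(v) for s, v in zip(STAGES, spec)},
        per_fold=per_fold,
    )


def restrict_validation_window(
    table: pd.DataFrame,
    start: _dt.time = _dt.time(22, 0),
    end: _dt.time = _dt.time(8, 0),
) -> pd.DataFrame:
    """Keep epochs whose start clock time falls in [start, end).

    The default 22:00-08:00 window crosses midnight; an epoch starting at
    21:59:30 is excluded, one at 22:00:00 included.
    """
    t = pd.to_datetime(table["epoch_start_time"]).dt.time
    if start <= end:
        keep = (t >= start) & (t < end)
    else:
        keep = (t >= start) | (t < end)
    return table.loc[keep.to_numpy()].reset_index(drop=True)
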