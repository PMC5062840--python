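"""RBF-SVM reliability classification and five-case subcategorization.

A soft-margin SVM with RBF kernel exp(-gamma * ||u - v||^2), gamma = 0.4
and cost C = 1 by default, is trained on standardized feature vectors
(S_peak, l, v, sigma) labeled reliable/unreliable. Standardization by the
training mean/sd is essential: l and v reach hundreds while S_peak and
sigma are O(1), and gamma = 0.4 is only meaningful on a common scale.

Predicted labels come from the sign of the decision function; a Platt
sigmoid fitted on the training decision values supplies
P(unreliable). The trained model is serialized as a self-contained JSON
document (kernel parameters, scaled support vectors, dual coefficients,
scaling statistics, training minima, thresholds), so prediction needs no
external object store.

Subcategorization (five cases) follows the dummy-sample scheme: for an
unreliable sample b = (S_peak, l, v, sigma), build
d1 = (S_peak, l, min_v, sigma) and d2 = (S_peak, l, v, min_sigma) with the
training-set minima. If d1 flips to reliable, b's trouble is wave-driven
hyper-segmentation: case 1 when S_peak > thr2 (accept with caution), else
case 3. Otherwise, if d2 flips, b has large DLRS: case 4. If neither
flips, both artefact axes contribute and the wave branch wins (d1 is
checked first). Reliable samples split on thr1: case 2 (many CNAs) above,
case 5 (control-like / few CNAs) at or below.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.spatial.distance
import scipy.stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureVector

__all__ = [
    "TrainingSet",
    "ReliabilityModel",
    "Assessment",
    "CASE_DESCRIPTIONS",
    "train_model",
    "cross_validate",
    "predict",
    "subcategorize",
    "roc_auc",
]

RELIABLE, UNRELIABLE = "reliable", "unreliable"

CASE_DESCRIPTIONS = {
    1: "hyper-segmented, discernible CNAs with some waves",
    2: "reliable, discernible CNAs with few waves",
    3: "unreliable, indiscernible CNAs with heavy waves",
    4: "unreliable, large DLRS, undetectable CNAs",
    5: "reliable, control sample or without many CNAs",
}

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingSet:
    """Labeled feature vectors; labels are 'reliable'/'unreliable'."""

    features: list[FeatureVector]
    labels: list[str]
    cases: list[int] | None = None

    def __post_init__(self):
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        bad = {l for l in self.labels if l not in (RELIABLE, UNRELIABLE)}
        if bad:
            raise ValueError(f"labels must be '{RELIABLE}' or '{UNRELIABLE}', got {sorted(bad)}")

    def X(self) -> np.ndarray:
        return np.vstack([fv.as_array() for fv in self.features])

    def y(self) -> np.ndarray:
        return np.asarray([1 if l == UNRELIABLE else 0 for l in self.labels])


@dataclass
class ReliabilityModel:
    """A trained, self-contained reliability classifier."""

    gamma: float
    C: float
    support_vectors: np.ndarray  # scaled feature space
    dual_coef: np.ndarray
    intercept: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    platt_a: float  # P(unreliable) = expit(a * f + b)
    platt_b: float
    min_v: float
    min_sigma: float
    thr1: float = 1.5
    thr2: float = 2.5
    format_version: int = MODEL_FORMAT_VERSION

    def __post_init__(self):
        if self.gamma <= 0 or self.C <= 0:
            raise ValueError("gamma and C must be > 0")
        if self.thr2 <= self.thr1:
            raise ValueError("thr2 must exceed thr1")
        if np.any(np.asarray(self.scale_sd) <= 0):
            raise ValueError("scaling sds must be > 0")

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scale_mean) / self.scale_sd

    def decision_function(self, X_raw: np.ndarray) -> np.ndarray:
        """Positive decision value => unreliable."""
        X = self._scale(np.atleast_2d(np.asarray(X_raw, dtype=float)))
        K = np.exp(-self.gamma * scipy.spatial.distance.cdist(X, self.support_vectors, "sqeuclidean"))
        return K @ self.dual_coef + self.intercept

    def predict_proba_unreliable(self, X_raw) -> np.ndarray:
        f = self.decision_function(X_raw)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * f + self.platt_b)))

    def predict_label(self, X_raw) -> np.ndarray:
        return np.where(self.decision_function(X_raw) > 0, UNRELIABLE, RELIABLE)

    def save(self, path) -> None:
        doc = {
            "format_version": self.format_version,
            "kernel": "rbf",
            "gamma": self.gamma,
            "C": self.C,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "scale_mean": self.scale_mean.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "min_v": self.min_v,
            "min_sigma": self.min_sigma,
            "thr1": self.thr1,
            "thr2": self.thr2,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ReliabilityModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {doc.get('format_version')}")
        return cls(
            gamma=doc["gamma"],
            C=doc["C"],
            support_vectors=np.asarray(doc["support_vectors"]),
            dual_coef=np.asarray(doc["dual_coef"]),
            intercept=doc["intercept"],
            scale_mean=np.asarray(doc["scale_mean"]),
            scale_sd=np.asarray(doc["scale_sd"]),
            platt_a=doc["platt_a"],
            platt_b=doc["platt_b"],
            min_v=doc["min_v"],
            min_sigma=doc["min_sigma"],
            thr1=doc["thr1"],
            thr2=doc["thr2"],
        )


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, gamma: float):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        raise ValueError("a feature is constant across the training set; cannot standardize")
    Xs = (X - mean) / sd
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(Xs, y)
    # sklearn orders classes_ ascending, so decision > 0 => class 1 (unreliable)
    return svc, Xs, mean, sd


def train_model(
    ts: TrainingSet,
    C: float = 1.0,
    gamma: float = 0.4,
    thr1: float = 1.5,
    thr2: float = 2.5,
) -> ReliabilityModel:
    """Standardize, fit the RBF SVM, calibrate the Platt sigmoid, and
    store the training minima and thresholds."""
    X, y = ts.X(), ts.y()
    if len(y) < 4:
        raise ValueError("need at least 4 training samples")
    if len(np.unique(y)) < 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
        raise ValueError("need at least 2 samples per class")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")
    svc, Xs, mean, sd = _fit_svc(X, y, C, gamma)
    f = svc.decision_function(Xs)
    lr = LogisticRegression(C=1e3, solver="lbfgs", max_iter=1000)
    lr.fit(f.reshape(-1, 1), y)
    return ReliabilityModel(
        gamma=gamma,
        C=C,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        scale_mean=mean,
        scale_sd=sd,
        platt_a=float(lr.coef_[0, 0]),
        platt_b=float(lr.intercept_[0]),
        min_v=float(X[:, 2].min()),
        min_sigma=float(X[:, 3].min()),
        thr1=thr1,
        thr2=thr2,
    )


def cross_validate(ts: TrainingSet, folds: int = 10, seed: int = 0):
    """Stratified k-fold accuracy of the label predictions.

    Returns (mean, sd) of per-fold accuracy (sd with ddof=1);
    deterministic given ``seed``.
    """
    X, y = ts.X(), ts.y()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > min(np.sum(y == 0), np.sum(y == 1)):
        raise ValueError("folds exceed the smallest class size")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        svc, _, mean, sd = _fit_svc(X[tr], y[tr], C=1.0, gamma=0.4)
        pred = svc.predict((X[te] - mean) / sd)
        accs.append(float(np.mean(pred == y[te])))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1))


def predict(model: ReliabilityModel, fv: FeatureVector):
    """(label, P(unreliable)) for one feature vector."""
    x = fv.as_array()
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite feature in {fv.sample_id}")
    label = str(model.predict_label(x)[0])
    prob = float(model.predict_proba_unreliable(x)[0])
    return label, prob


@dataclass
class Assessment:
    sample_id: str
    label: str
    prob_unreliable: float
    case: int
    case_description: str = field(default="")

    def __post_init__(self):
        if not self.case_description:
            self.case_description = CASE_DESCRIPTIONS[self.case]


def subcategorize(model: ReliabilityModel, fv: FeatureVector) -> Assessment:
    """Assign one of the five reliability cases (see module docstring)."""
    label, prob = predict(model, fv)
    if label == RELIABLE:
        case = 2 if fv.S_peak > model.thr1 else 5
    else:
        d1 = FeatureVector(fv.sample_id + ":d1", fv.S_peak, fv.l, model.min_v, fv.sigma)
        d2 = FeatureVector(fv.sample_id + ":d2", fv.S_peak, fv.l, fv.v, model.min_sigma)
        d1_label, _ = predict(model, d1)
        d2_label, _ = predict(model, d2)
        if d1_label == RELIABLE:
            case = 1 if fv.S_peak > model.thr2 else 3
        elif d2_label == RELIABLE:
            case = 4
        else:
            case = 1 if fv.S_peak > model.thr2 else 3
    return Assessment(sample_id=fv.sample_id, label=label, prob_unreliable=prob, case=case)


def roc_auc(scores, labels) -> float:
    """AUC by the rank statistic: P(score_pos > score_neg) with ties
    counted half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1, False, True}:
        raise ValueError("labels must be binary 0/1")
    y = y.astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
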