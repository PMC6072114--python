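"""Third-order polynomial-kernel SVM on technical-replicate vectors.

The classifier is a soft-margin SVM with kernel

    K(u, v) = (gamma * <u, v> + coef0)^3

trained on individual technical-replicate feature vectors.  A serum sample is
classified by majority vote over its replicates' predicted labels; ties (even
replicate counts) are broken by the sign of the summed SVM decision values.
Performance is summarized by a confusion matrix with MGUS as the positive
class, the derived accuracy / sensitivity / specificity, and a
continuity-corrected McNemar chi-square p-value on the discordant counts.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.svm import SVC

from .io import GROUPS, HC, MGUS, feature_columns, feature_values
from .peaks import FeatureSet, ReferencePeakSet

DEFAULT_GAMMA_GRID = (5e-5, 1e-4, 2e-4, 3e-4, 5e-4, 6e-4)
DEFAULT_COEF0_GRID = (0.08, 0.1, 0.15, 0.2, 0.4, 0.9, 1.1)
DEFAULT_COST_GRID = (90, 120, 150, 180, 210, 240)


@dataclass
class SVMConfig:
    """Kernel parameters and tuning grids (degree fixed at 3)."""

    gamma: float = 2e-4
    coef0: float = 0.1
    cost: float = 150.0
    scale: bool = True
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    coef0_grid: tuple = DEFAULT_COEF0_GRID
    cost_grid: tuple = DEFAULT_COST_GRID

    def validate(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be positive")
        if any(g <= 0 for g in self.gamma_grid) or any(c <= 0 for c in self.cost_grid):
            raise ValueError("grid values for gamma and cost must be positive")

    @property
    def grid(self) -> list:
        """All (gamma, coef0, cost) triples, in deterministic order."""
        return [(g, c0, c) for g in self.gamma_grid for c0 in self.coef0_grid
                for c in self.cost_grid]


def poly3_kernel(u, v, gamma: float, coef0: float) -> float:
    """The third-order polynomial kernel (gamma*<u,v> + coef0)^3."""
    return float((gamma * np.dot(np.asarray(u, float), np.asarray(v, float))
                  + coef0) ** 3)


class ReplicateVotingSVC:
    """scikit-learn-style classifier: replicate rows in, sample votes out.

    ``fit``/``predict``/``decision_function`` operate on replicate feature
    vectors like an ordinary binary classifier; :meth:`predict_sample` and
    :meth:`predict_samples` add the majority-voting aggregation.  With
    ``scale=True`` (default) features are standardized with statistics learned
    at fit time, which keeps the polynomial kernel well-conditioned for
    TIC-normalized intensities of order 1e-3.
    """

    def __init__(self, gamma: float = 2e-4, coef0: float = 0.1,
                 cost: float = 150.0, scale: bool = True):
        self.gamma = gamma
        self.coef0 = coef0
        self.cost = cost
        self.scale = scale

    def get_params(self, deep: bool = True) -> dict:
        return {"gamma": self.gamma, "coef0": self.coef0, "cost": self.cost,
                "scale": self.scale}

    def set_params(self, **params) -> "ReplicateVotingSVC":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "ReplicateVotingSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d replicate-by-feature array")
        classes = sorted(set(y))
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {classes}")
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be positive")
        if self.scale:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        self.svc_ = SVC(kernel="poly", degree=3, gamma=self.gamma,
                        coef0=self.coef0, C=self.cost)
        self.svc_.fit((X - self.mean_) / self.scale_, y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _check(self, X) -> np.ndarray:
        if not hasattr(self, "svc_"):
            raise RuntimeError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: model expects "
                f"{self.n_features_in_}, got {X.shape[1]}"
            )
        return (X - self.mean_) / self.scale_

    def decision_function(self, X) -> np.ndarray:
        """Signed distances; positive values vote for ``classes_[1]``."""
        return self.svc_.decision_function(self._check(X))

    def predict(self, X) -> np.ndarray:
        return self.svc_.predict(self._check(X))

    def predict_sample(self, X) -> tuple:
        """Majority-voted class of one sample's replicate rows.

        Returns ``(label, replicate_labels, decision_values)``.  Ties are
        broken by the sign of the summed decision values (positive ->
        ``classes_[1]``, the lexicographically larger label, i.e. MGUS for
        an MGUS/HC model).
        """
        labels = self.predict(X)
        decisions = self.decision_function(X)
        counts = Counter(labels)
        if len(counts) == 2 and len(set(counts.values())) == 1:
            label = self.classes_[1] if float(np.sum(decisions)) > 0 \
                else self.classes_[0]
        else:
            label = counts.most_common(1)[0][0]
        return label, labels, decisions

    def predict_samples(self, X, sample_ids) -> dict:
        """Majority-voted label per sample for a stacked replicate matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sample_ids = list(sample_ids)
        if len(sample_ids) != X.shape[0]:
            raise ValueError("one sample_id per replicate row required")
        out = {}
        order = list(dict.fromkeys(sample_ids))
        ids = np.array(sample_ids)
        for sid in order:
            out[sid], _, _ = self.predict_sample(X[ids == sid])
        return out

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass
class ConfusionMatrix:
    """Prediction counts with MGUS as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true, y_pred = list(y_true), list(y_pred)
        if not y_true or len(y_true) != len(y_pred):
            raise ValueError("label lists must be equal-length and non-empty")
        bad = (set(y_true) | set(y_pred)) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown class label(s): {sorted(bad)}")
        tp = sum(t == MGUS and p == MGUS for t, p in zip(y_true, y_pred))
        fn = sum(t == MGUS and p == HC for t, p in zip(y_true, y_pred))
        fp = sum(t == HC and p == MGUS for t, p in zip(y_true, y_pred))
        tn = sum(t == HC and p == HC for t, p in zip(y_true, y_pred))
        return cls(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class PerformanceEstimate:
    sensitivity: float
    specificity: float
    accuracy: float
    p_value: float
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "accuracy": self.accuracy, "p_value": self.p_value,
                "undefined": list(self.undefined)}


def mcnemar_p(cm: ConfusionMatrix) -> float:
    """Continuity-corrected McNemar chi-square p-value on the discordant
    prediction counts (FP vs FN); p = 1 when there is no discordance."""
    discordant = cm.fp + cm.fn
    if discordant == 0:
        return 1.0
    stat = (abs(cm.fp - cm.fn) - 1) ** 2 / discordant
    return float(chi2.sf(stat, df=1))


def confusion_and_performance(y_true, y_pred) -> tuple:
    """Confusion matrix and accuracy/sensitivity/specificity (MGUS positive).

    A rate whose denominator class is absent is returned as NaN and named in
    ``undefined`` rather than silently set to zero.
    """
    cm = ConfusionMatrix.from_labels(y_true, y_pred)
    undefined = []
    if cm.tp + cm.fn > 0:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    else:
        sensitivity = np.nan
        undefined.append("sensitivity")
    if cm.tn + cm.fp > 0:
        specificity = cm.tn / (cm.tn + cm.fp)
    else:
        specificity = np.nan
        undefined.append("specificity")
    accuracy = (cm.tp + cm.tn) / cm.total
    perf = PerformanceEstimate(sensitivity=float(sensitivity),
                               specificity=float(specificity),
                               accuracy=float(accuracy),
                               p_value=mcnemar_p(cm),
                               undefined=tuple(undefined))
    return cm, perf


def train_svm(matrix: pd.DataFrame, cfg: SVMConfig | None = None
              ) -> ReplicateVotingSVC:
    """Train the replicate-level SVM on a QC-filtered feature matrix."""
    cfg = cfg or SVMConfig()
    cfg.validate()
    if matrix["group"].isna().any():
        raise ValueError("feature matrix contains unlabeled rows")
    clf = ReplicateVotingSVC(gamma=cfg.gamma, coef0=cfg.coef0, cost=cfg.cost,
                             scale=cfg.scale)
    return clf.fit(feature_values(matrix), matrix["group"].to_numpy())


@dataclass
class PredictiveModel:
    """The deployable unit: trained SVM plus the frozen pipeline parameters
    (feature set, reference peaks, QC threshold) needed to classify raw
    replicate spectra of an unknown sample."""

    classifier: ReplicateVotingSVC
    features: FeatureSet
    reference_peaks: ReferencePeakSet
    r_th: float
    preprocess_params: dict = field(default_factory=dict)
    peak_params: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if hasattr(self.classifier, "n_features_in_") and \
                self.classifier.n_features_in_ != len(self.features):
            raise ValueError(
                f"feature set size {len(self.features)} does not match the "
                f"classifier input dimension {self.classifier.n_features_in_}"
            )

    def save(self, path) -> None:
        """Persist as a joblib bundle plus a human-readable JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path)
        sidecar = {
            "features": self.features.to_dict(),
            "reference_peaks": self.reference_peaks.to_dict(),
            "r_th": self.r_th,
            "preprocess_params": self.preprocess_params,
            "peak_params": self.peak_params,
            "svm_params": self.classifier.get_params(),
            "metadata": self.metadata,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PredictiveModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise TypeError(f"{path} is not a PredictiveModel bundle")
        return model
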