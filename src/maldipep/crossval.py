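"""Replicate-grouped cross-validation, nested (double) CV and deployment.

All resampling operates at the sample level: every technical replicate of a
serum sample is restricted to the same fold, so no sample contributes rows to
both a training and a validation split.  ``tune_20fold`` implements the
20-fold grid-search tuning scheme; ``double_cv`` wraps it in an outer loop
whose held-out folds are never seen by the inner tuning, yielding an unbiased
generalization estimate; ``classify_unknown`` runs the frozen end-to-end path
(preprocess -> align to stored reference peaks -> stored features -> frozen
QC threshold -> SVM -> majority vote) on raw replicate spectra of one sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortManifest, GROUPS, feature_values
from .peaks import PeakConfig, align_peaklist, build_feature_matrix, detect_peaks
from .preprocessing import PreprocessConfig, preprocess
from .qc import sample_avg_correlation
from .svm import (PerformanceEstimate, PredictiveModel, ReplicateVotingSVC,
                  SVMConfig, confusion_and_performance)

logger = logging.getLogger(__name__)

UNCLASSIFIABLE = "unclassifiable"


@dataclass
class FoldAssignment:
    """Sample-level partition into k folds (replicates stay together)."""

    mapping: dict                     # sample_id -> fold index
    k: int
    seed: int

    def fold_samples(self, fold: int) -> list:
        return [s for s, f in self.mapping.items() if f == fold]


def make_grouped_folds(samples, labels, k: int, seed: int) -> FoldAssignment:
    """Random, seed-reproducible, class-stratified sample partition.

    Fold sizes differ by at most one sample and every training split (all
    folds but one) contains both classes.  ``samples``/``labels`` are
    parallel sequences of sample ids and group labels.
    """
    samples, labels = list(samples), list(labels)
    if len(samples) != len(labels):
        raise ValueError("samples and labels must be parallel")
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(samples):
        raise ValueError(f"k={k} exceeds the number of samples ({len(samples)})")
    rng = np.random.default_rng(seed)
    mapping: dict = {}
    counter = 0
    for cls in sorted(set(labels)):
        members = [s for s, l in zip(samples, labels) if l == cls]
        rng.shuffle(members)
        for s in members:
            mapping[s] = counter % k
            counter += 1
    assignment = FoldAssignment(mapping=mapping, k=k, seed=seed)
    label_of = dict(zip(samples, labels))
    for fold in range(k):
        train_labels = {label_of[s] for s, f in mapping.items() if f != fold}
        if len(train_labels) < 2:
            raise ValueError(f"training split for fold {fold} is single-class")
    return assignment


@dataclass
class FoldRecord:
    fold: int
    gamma: float
    coef0: float
    cost: float
    performance: PerformanceEstimate

    def to_dict(self) -> dict:
        return {"fold": self.fold, "gamma": self.gamma, "coef0": self.coef0,
                "cost": self.cost, **self.performance.to_dict()}


@dataclass
class CVResult:
    folds: list                        # list of FoldRecord
    best_params: dict                  # gamma, coef0, cost
    aggregate: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"folds": [f.to_dict() for f in self.folds],
                "best_params": self.best_params,
                "aggregate": self.aggregate, "seed": self.seed}

    def to_frame(self) -> pd.DataFrame:
        """Per-fold table: fold, gamma, coef0, cost, sens, spec, acc, p."""
        return pd.DataFrame([f.to_dict() for f in self.folds])


def aggregate_performance(perfs) -> dict:
    """Arithmetic mean and sample (n-1) s.d. of per-fold metrics."""
    perfs = list(perfs)
    out = {}
    for name in ("sensitivity", "specificity", "accuracy"):
        values = np.array([getattr(p, name) for p in perfs], dtype=float)
        out[f"{name}_mean"] = float(np.nanmean(values))
        out[f"{name}_sd"] = float(np.nanstd(values, ddof=1)) \
            if values.size > 1 else 0.0
    return out


def _sample_table(matrix: pd.DataFrame):
    seen: dict = {}
    for sid, grp in zip(matrix["sample_id"], matrix["group"]):
        if sid in seen and seen[sid] != grp:
            raise ValueError(f"inconsistent group label for sample {sid!r}")
        seen[sid] = grp
    if not set(seen.values()) <= set(GROUPS):
        raise ValueError("feature matrix contains unlabeled or unknown groups")
    return list(seen.keys()), list(seen.values())


def _build_folds(matrix: pd.DataFrame, k: int, seed: int,
                 max_retries: int = 20) -> FoldAssignment:
    """Grouped stratified folds; regenerated with a seed offset (and logged)
    in the unlikely event a validation fold is single-class."""
    samples, labels = _sample_table(matrix)
    label_of = dict(zip(samples, labels))
    for attempt in range(max_retries):
        folds = make_grouped_folds(samples, labels, k, seed + attempt)
        bad = [f for f in range(k)
               if len({label_of[s] for s in folds.fold_samples(f)}) < 2
               and len(folds.fold_samples(f)) > 1]
        if not bad:
            return folds
        logger.info("fold set (seed %d) has single-class validation folds %s; "
                    "regenerating with seed offset", seed + attempt, bad)
    return folds


def _evaluate_split(matrix, values, groups, sample_ids, train_mask,
                    val_samples, label_of, params, scale) -> PerformanceEstimate:
    gamma, coef0, cost = params
    clf = ReplicateVotingSVC(gamma=gamma, coef0=coef0, cost=cost, scale=scale)
    clf.fit(values[train_mask], groups[train_mask])
    val_mask = ~train_mask
    predicted = clf.predict_samples(values[val_mask],
                                    [s for s, m in zip(sample_ids, val_mask) if m])
    y_true = [label_of[s] for s in val_samples]
    y_pred = [predicted[s] for s in val_samples]
    _, perf = confusion_and_performance(y_true, y_pred)
    return perf


def _pick_best(acc_by_triple: dict):
    """Highest accuracy; ties resolved by lowest cost, then gamma, then coef0."""
    return min(acc_by_triple.items(),
               key=lambda kv: (-kv[1], kv[0][2], kv[0][0], kv[0][1]))[0]


def tune_20fold(matrix: pd.DataFrame, cfg: SVMConfig | None = None,
                k: int = 20, seed: int = 0) -> CVResult:
    """Grid-search tuning under replicate-grouped k-fold cross-validation.

    For every fold, every (gamma, coef0, cost) triple is trained on the other
    k-1 folds and scored by majority-voted sample accuracy on the held-out
    fold; each fold records its best triple and metrics, and the overall best
    parameters are the triple with the highest mean validation accuracy
    (ties -> lowest cost, then lowest gamma).
    """
    cfg = cfg or SVMConfig()
    cfg.validate()
    folds = _build_folds(matrix, k, seed)
    samples, labels = _sample_table(matrix)
    label_of = dict(zip(samples, labels))
    values = feature_values(matrix)
    groups = matrix["group"].to_numpy()
    sample_ids = list(matrix["sample_id"])
    fold_of_row = np.array([folds.mapping[s] for s in sample_ids])

    triples = cfg.grid
    perf_table: dict = {}              # (triple, fold) -> PerformanceEstimate
    for fold in range(k):
        train_mask = fold_of_row != fold
        val_samples = folds.fold_samples(fold)
        for triple in triples:
            perf_table[(triple, fold)] = _evaluate_split(
                matrix, values, groups, sample_ids, train_mask, val_samples,
                label_of, triple, cfg.scale)

    records = []
    for fold in range(k):
        by_triple = {t: perf_table[(t, fold)].accuracy for t in triples}
        best = _pick_best(by_triple)
        records.append(FoldRecord(fold=fold + 1, gamma=best[0], coef0=best[1],
                                  cost=best[2],
                                  performance=perf_table[(best, fold)]))
    mean_acc = {t: float(np.mean([perf_table[(t, f)].accuracy
                                  for f in range(k)])) for t in triples}
    g, c0, c = _pick_best(mean_acc)
    aggregate = aggregate_performance([r.performance for r in records])
    return CVResult(folds=records, best_params={"gamma": g, "coef0": c0,
                                                "cost": c},
                    aggregate=aggregate, seed=seed)


def double_cv(matrix: pd.DataFrame, cfg: SVMConfig | None = None,
              outer_k: int = 10, inner_k: int = 20, seed: int = 0) -> CVResult:
    """Nested cross-validation generalization estimate.

    The outer loop holds out each of ``outer_k`` sample folds as a test set;
    the inner ``tune_20fold`` on the remaining samples selects parameters; a
    model trained on the full inner data predicts the outer test fold by
    majority vote.  Outer test samples are asserted never to enter the inner
    loop.  Returns the ``outer_k`` performance estimates with their mean and
    sample standard deviation.
    """
    cfg = cfg or SVMConfig()
    cfg.validate()
    outer = _build_folds(matrix, outer_k, seed)
    samples, labels = _sample_table(matrix)
    label_of = dict(zip(samples, labels))
    records = []
    for fold in range(outer_k):
        test_samples = set(outer.fold_samples(fold))
        inner_matrix = matrix[~matrix["sample_id"].isin(test_samples)]
        inner_matrix = inner_matrix.reset_index(drop=True)
        overlap = test_samples & set(inner_matrix["sample_id"])
        assert not overlap, f"leakage: outer test samples {overlap} in inner loop"
        inner_result = tune_20fold(inner_matrix, cfg,
                                   k=min(inner_k, len(set(inner_matrix["sample_id"]))),
                                   seed=seed + 1000 * (fold + 1))
        best = inner_result.best_params
        clf = ReplicateVotingSVC(gamma=best["gamma"], coef0=best["coef0"],
                                 cost=best["cost"], scale=cfg.scale)
        clf.fit(feature_values(inner_matrix), inner_matrix["group"].to_numpy())
        test_rows = matrix[matrix["sample_id"].isin(test_samples)]
        predicted = clf.predict_samples(feature_values(test_rows),
                                        list(test_rows["sample_id"]))
        ordered = [s for s in outer.fold_samples(fold)]
        _, perf = confusion_and_performance([label_of[s] for s in ordered],
                                            [predicted[s] for s in ordered])
        records.append(FoldRecord(fold=fold + 1, gamma=best["gamma"],
                                  coef0=best["coef0"], cost=best["cost"],
                                  performance=perf))
    aggregate = aggregate_performance([r.performance for r in records])
    mean_acc_by_triple = {}
    for r in records:
        t = (r.gamma, r.coef0, r.cost)
        mean_acc_by_triple.setdefault(t, []).append(r.performance.accuracy)
    g, c0, c = _pick_best({t: float(np.mean(v))
                           for t, v in mean_acc_by_triple.items()})
    return CVResult(folds=records, best_params={"gamma": g, "coef0": c0,
                                                "cost": c},
                    aggregate=aggregate, seed=seed)


@dataclass
class UnknownSampleReport:
    """Outcome of classifying one unknown sample's raw replicate spectra."""

    sample_id: str
    predicted_class: str | None
    replicate_labels: dict             # replicate_id -> predicted label
    removed_replicates: list
    r_avg: float | None
    r_th: float
    unclassifiable: bool = False

    def to_dict(self) -> dict:
        return {"sample_id": self.sample_id,
                "predicted_class": self.predicted_class,
                "replicate_labels": dict(self.replicate_labels),
                "removed_replicates": [list(t) for t in self.removed_replicates],
                "r_avg": self.r_avg, "r_th": self.r_th,
                "unclassifiable": self.unclassifiable}


def classify_unknown(model: PredictiveModel, spectra) -> UnknownSampleReport:
    """Classify an unknown serum sample from its raw technical replicates.

    Each replicate is preprocessed, aligned to the model's reference peaks and
    reduced to the model's feature set; the frozen QC threshold then removes
    poorly correlating replicates (at least two must survive, otherwise the
    sample is reported unclassifiable); the surviving replicates are
    SVM-classified and majority voting assigns the sample class.
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValueError("classification requires at least 2 technical replicates")
    sample_ids = {s.sample_id for s in spectra}
    if len(sample_ids) != 1:
        raise ValueError(f"spectra from multiple samples: {sorted(sample_ids)}")
    sample_id = sample_ids.pop()

    pre_cfg = PreprocessConfig(**model.preprocess_params) \
        if model.preprocess_params else PreprocessConfig()
    peak_cfg = PeakConfig(**model.peak_params) if model.peak_params else PeakConfig()
    processed = [preprocess(s, pre_cfg) for s in spectra]
    aligned = [align_peaklist(detect_peaks(s, peak_cfg), model.reference_peaks,
                              peak_cfg) for s in processed]
    manifest = CohortManifest(pd.DataFrame(
        {"sample_id": [s.sample_id for s in processed],
         "replicate_id": [s.replicate_id for s in processed]}))
    fm = build_feature_matrix(processed, aligned, model.features, manifest,
                              peak_cfg)
    values = feature_values(fm)
    replicate_ids = list(fm["replicate_id"])

    idx = list(range(len(replicate_ids)))
    removed: list = []
    r_avg = sample_avg_correlation(values[idx])
    while r_avg < model.r_th and len(idx) > 2:
        sub = values[idx]
        corr = np.corrcoef(sub)
        np.fill_diagonal(corr, np.nan)
        worst = int(np.argmin(np.nanmean(corr, axis=1)))
        removed.append((sample_id, replicate_ids[idx[worst]]))
        del idx[worst]
        r_avg = sample_avg_correlation(values[idx])
    if r_avg < model.r_th:
        removed.extend((sample_id, replicate_ids[i]) for i in idx)
        return UnknownSampleReport(sample_id=sample_id, predicted_class=None,
                                   replicate_labels={}, removed_replicates=removed,
                                   r_avg=float(r_avg), r_th=model.r_th,
                                   unclassifiable=True)
    label, rep_labels, _ = model.classifier.predict_sample(values[idx])
    return UnknownSampleReport(
        sample_id=sample_id, predicted_class=str(label),
        replicate_labels={replicate_ids[i]: str(l)
                          for i, l in zip(idx, rep_labels)},
        removed_replicates=removed, r_avg=float(r_avg), r_th=model.r_th)
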