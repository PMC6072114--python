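"""Replicate-correlation quality control.

Technical replicates of the same serum sample should give near-identical
feature vectors.  For every sample the mean pairwise Pearson correlation of
its replicate rows (r_avg) is computed; the cohort threshold is

    r_th = mu - 3 * sigma

where mu and sigma are the mean and (sample) standard deviation of the
per-sample r_avg values.  Samples below threshold have their worst-correlating
replicates removed one at a time until they recover or fall below two
replicates, in which case the whole sample is discarded (at least two
replicates are mandatory).  The mean r_avg of samples measured in several
acquisition batches quantifies inter-experimental reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import feature_values


class QCError(ValueError):
    """Raised for quality-control contract violations."""


@dataclass
class QCReport:
    r_avg: dict                       # sample_id -> mean pairwise replicate correlation
    mu: float
    sigma: float
    r_th: float
    removed_replicates: list = field(default_factory=list)   # (sample_id, replicate_id)
    removed_samples: list = field(default_factory=list)
    interexp_mean: float | None = None

    def to_dict(self) -> dict:
        return {
            "r_avg": {k: float(v) for k, v in self.r_avg.items()},
            "mu": float(self.mu),
            "sigma": float(self.sigma),
            "r_th": float(self.r_th),
            "removed_replicates": [list(t) for t in self.removed_replicates],
            "removed_samples": list(self.removed_samples),
            "interexp_mean": None if self.interexp_mean is None
            else float(self.interexp_mean),
        }


def _pairwise_correlations(rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[0] < 2:
        raise QCError("need at least 2 replicate rows to correlate")
    if np.any(np.std(rows, axis=1) == 0):
        raise QCError("zero-variance replicate row; correlation undefined")
    corr = np.corrcoef(rows)
    return corr[np.triu_indices(rows.shape[0], k=1)]


def sample_avg_correlation(rows) -> float:
    """Mean of all pairwise Pearson correlations among a sample's replicates."""
    return float(np.mean(_pairwise_correlations(rows)))


def compute_threshold(r_avgs) -> tuple:
    """Cohort statistics (mu, sigma, r_th) from per-sample r_avg values.

    sigma uses the n-1 (sample) convention; r_th = mu - 3*sigma.
    """
    values = np.asarray(list(r_avgs), dtype=float)
    if values.size < 2:
        raise QCError("need at least 2 samples to compute a threshold")
    mu = float(np.mean(values))
    sigma = float(np.std(values, ddof=1))
    return mu, sigma, threshold_from_moments(mu, sigma)


def threshold_from_moments(mu: float, sigma: float) -> float:
    """Quality threshold r_th = mu - 3*sigma."""
    return float(mu - 3.0 * sigma)


def _sample_blocks(matrix: pd.DataFrame) -> dict:
    """sample_id -> positional row indices, in first-appearance order."""
    blocks: dict = {}
    for i, sid in enumerate(matrix["sample_id"]):
        blocks.setdefault(sid, []).append(i)
    return blocks


def filter_replicates(matrix: pd.DataFrame, r_th: float | None = None):
    """Remove poorly correlating replicates and under-replicated samples.

    For each sample with r_avg below threshold, the replicate with the lowest
    mean correlation to its siblings is removed and r_avg recomputed, until
    the sample recovers or fewer than two replicates remain (then the sample
    is discarded).  When ``r_th`` is None the threshold is computed from the
    cohort (mu - 3*sigma of the per-sample r_avg values); passing an explicit
    threshold supports the frozen-threshold path used to classify unknowns.

    Returns ``(filtered matrix, QCReport)``.
    """
    values = feature_values(matrix)
    blocks = _sample_blocks(matrix)
    for sid, idx in blocks.items():
        if len(idx) < 2:
            raise QCError(f"sample {sid!r} has fewer than 2 replicates")
    r_avg = {sid: sample_avg_correlation(values[idx])
             for sid, idx in blocks.items()}
    if r_th is None:
        mu, sigma, r_th = compute_threshold(r_avg.values())
    else:
        mu = float(np.mean(list(r_avg.values())))
        sigma = float(np.std(list(r_avg.values()), ddof=1)) \
            if len(r_avg) > 1 else 0.0
        r_th = float(r_th)

    removed_reps: list = []
    removed_samples: list = []
    surviving_r_avg: dict = {}
    keep_rows: list = []
    for sid, idx in blocks.items():
        idx = list(idx)
        current = r_avg[sid]
        while current < r_th and len(idx) > 2:
            sub = values[idx]
            corr = np.corrcoef(sub)
            np.fill_diagonal(corr, np.nan)
            mean_sibling = np.nanmean(corr, axis=1)
            worst = int(np.argmin(mean_sibling))
            removed_reps.append((sid, matrix["replicate_id"].iloc[idx[worst]]))
            del idx[worst]
            current = sample_avg_correlation(values[idx])
        if current < r_th:
            # <=2 replicates left and still below threshold: discard the sample
            removed_reps.extend((sid, matrix["replicate_id"].iloc[i]) for i in idx)
            removed_samples.append(sid)
        else:
            surviving_r_avg[sid] = current
            keep_rows.extend(idx)
    if not keep_rows:
        raise QCError("quality control removed every replicate")
    filtered = matrix.iloc[sorted(keep_rows)].reset_index(drop=True)
    report = QCReport(r_avg=r_avg, mu=mu, sigma=sigma, r_th=r_th,
                      removed_replicates=removed_reps,
                      removed_samples=removed_samples)
    return filtered, report


def interexperimental_reproducibility(matrix: pd.DataFrame) -> float:
    """Mean replicate-average correlation over samples measured in >= 2
    acquisition batches (replicates pooled across batches)."""
    if "batch" not in matrix.columns:
        raise QCError("feature matrix has no batch column")
    values = feature_values(matrix)
    blocks = _sample_blocks(matrix)
    means = []
    for sid, idx in blocks.items():
        batches = set(matrix["batch"].iloc[idx])
        batches.discard("")
        if len(batches) >= 2:
            means.append(sample_avg_correlation(values[idx]))
    if not means:
        raise QCError("no samples measured in more than one batch")
    return float(np.mean(means))


class ReplicateCorrelationQC:
    """scikit-learn-style transformer around the correlation QC.

    ``fit`` computes the cohort statistics (``mu_``, ``sigma_``, ``r_th_``)
    from a feature matrix — or freezes an externally supplied threshold —
    and ``transform`` filters a matrix with the fitted threshold, storing the
    removal report in ``report_``.
    """

    def __init__(self, r_th: float | None = None):
        self.r_th = r_th

    def get_params(self, deep: bool = True) -> dict:
        return {"r_th": self.r_th}

    def set_params(self, **params) -> "ReplicateCorrelationQC":
        for k, v in params.items():
            if k != "r_th":
                raise ValueError(f"unknown parameter {k!r}")
            self.r_th = v
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "ReplicateCorrelationQC":
        values = feature_values(X)
        blocks = _sample_blocks(X)
        r_avg = {sid: sample_avg_correlation(values[idx])
                 for sid, idx in blocks.items() if len(idx) >= 2}
        if len(r_avg) < 2:
            raise QCError("need at least 2 multi-replicate samples to fit QC")
        self.r_avg_ = r_avg
        self.mu_, self.sigma_, computed = compute_threshold(r_avg.values())
        self.r_th_ = float(self.r_th) if self.r_th is not None else computed
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "r_th_"):
            raise RuntimeError("ReplicateCorrelationQC is not fitted")
        filtered, report = filter_replicates(X, r_th=self.r_th_)
        report.mu = self.mu_
        report.sigma = self.sigma_
        self.report_ = report
        return filtered

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
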