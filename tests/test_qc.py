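"""Replicate-correlation quality control."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from maldipep import (QCError, ReplicateCorrelationQC, compute_threshold,
                      filter_replicates, interexperimental_reproducibility,
                      sample_avg_correlation, threshold_from_moments)
from maldipep.io import feature_values


def frame(rows_by_sample, batches=None):
    """Build a feature frame from {sample_id: [replicate vectors]}."""
    records = []
    for sid, rows in rows_by_sample.items():
        for j, vec in enumerate(rows):
            records.append({"sample_id": sid, "replicate_id": f"R{j + 1}",
                            "group": "HC",
                            "batch": (batches or {}).get((sid, j), "B1"),
                            **{f"{1000 + k}.00": float(v)
                               for k, v in enumerate(vec)}})
    return pd.DataFrame(records)


def correlated_pair(r, n=60, seed=0):
    """Two vectors with Pearson correlation exactly r (Gram-Schmidt)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x
    z /= z.std()
    return x, r * x + np.sqrt(1 - r * r) * z


class TestSampleAvgCorrelation:
    def test_identical_rows(self):
        rows = np.tile(np.array([1.0, 3.0, 2.0, 5.0]), (2, 1))
        assert sample_avg_correlation(rows) == pytest.approx(1.0)

    def test_anticorrelated_rows(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert sample_avg_correlation(np.vstack([x, -x])) == pytest.approx(-1.0)

    def test_three_rows_equal_bruteforce_pairwise_mean(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(size=(3, 30))
        expected = np.mean([pearsonr(rows[i], rows[j]).statistic
                            for i in range(3) for j in range(i + 1, 3)])
        assert sample_avg_correlation(rows) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(QCError):
            sample_avg_correlation(np.ones((1, 5)))
        with pytest.raises(QCError):
            sample_avg_correlation(np.vstack([np.ones(5),
                                              np.arange(5.0)]))


class TestThreshold:
    def test_cohort_statistics_reproduce_published_threshold(self):
        """mu 0.984, sigma 0.028 -> r_th = 0.9 (exact arithmetic)."""
        assert threshold_from_moments(0.984, 0.028) == pytest.approx(0.9,
                                                                     abs=1e-12)
        d = 0.028 / np.sqrt(2)
        mu, sigma, r_th = compute_threshold([0.984 - d, 0.984 + d])
        assert mu == pytest.approx(0.984)
        assert sigma == pytest.approx(0.028)
        assert r_th == pytest.approx(0.9)

    def test_equal_values_give_threshold_at_value(self):
        mu, sigma, r_th = compute_threshold([0.7, 0.7, 0.7])
        assert sigma == pytest.approx(0.0, abs=1e-12)
        assert r_th == pytest.approx(0.7)

    def test_two_value_hand_arithmetic(self):
        mu, sigma, r_th = compute_threshold([0.8, 1.0])
        assert mu == pytest.approx(0.9)
        assert sigma == pytest.approx(0.141421, abs=1e-5)
        assert r_th == pytest.approx(0.475736, abs=1e-5)

    def test_needs_two_samples(self):
        with pytest.raises(QCError):
            compute_threshold([0.9])


class TestFilterReplicates:
    def _good_sample(self, rng, n=3, length=40):
        base = rng.normal(0, 1, length) * 10
        return [base + rng.normal(0, 0.1, length) for _ in range(n)]

    def test_all_above_threshold_unchanged(self):
        rng = np.random.default_rng(0)
        fm = frame({f"S{i}": self._good_sample(rng) for i in range(4)})
        out, report = filter_replicates(fm, r_th=0.9)
        assert out.equals(fm)
        assert report.removed_replicates == []
        assert report.removed_samples == []

    def test_shuffled_replicate_removed_exactly(self):
        rng = np.random.default_rng(1)
        rows = self._good_sample(rng, n=4)
        rows[2] = rng.permutation(rows[2])      # corrupted replicate
        fm = frame({"S0": rows, "S1": self._good_sample(rng)})
        out, report = filter_replicates(fm, r_th=0.9)
        assert report.removed_replicates == [("S0", "R3")]
        assert report.removed_samples == []
        assert len(out) == len(fm) - 1

    def test_two_discordant_replicates_discard_sample(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        fm = frame({"S0": [a, rng.permutation(a)],
                    "S1": self._good_sample(rng)})
        out, report = filter_replicates(fm, r_th=0.9)
        assert report.removed_samples == ["S0"]
        assert sorted(report.removed_replicates) == [("S0", "R1"), ("S0", "R2")]
        assert set(out.sample_id) == {"S1"}

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rows = self._good_sample(rng, n=4)
        rows[0] = rng.permutation(rows[0])
        fm = frame({"S0": rows, "S1": self._good_sample(rng)})
        once, _ = filter_replicates(fm, r_th=0.9)
        twice, report = filter_replicates(once, r_th=0.9)
        assert twice.equals(once)
        assert report.removed_replicates == []

    def test_removing_worst_never_lowers_r_avg(self):
        """Dropping the replicate with the minimum mean sibling correlation
        cannot decrease the sample's average correlation."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            rows = np.asarray(self._good_sample(rng, n=4))
            rows[rng.integers(4)] = rng.normal(size=rows.shape[1])
            before = sample_avg_correlation(rows)
            corr = np.corrcoef(rows)
            np.fill_diagonal(corr, np.nan)
            worst = int(np.argmin(np.nanmean(corr, axis=1)))
            after = sample_avg_correlation(np.delete(rows, worst, axis=0))
            assert after >= before - 1e-12

    def test_single_replicate_sample_rejected(self):
        rng = np.random.default_rng(5)
        fm = frame({"S0": [rng.normal(size=10)],
                    "S1": self._good_sample(rng)})
        with pytest.raises(QCError):
            filter_replicates(fm, r_th=0.5)


class TestInterexperimental:
    def test_identical_replicates_across_batches(self):
        vec = np.arange(20.0)
        fm = frame({"S0": [vec, vec + 0.0]},
                   batches={("S0", 0): "B1", ("S0", 1): "B2"})
        assert interexperimental_reproducibility(fm) == pytest.approx(1.0)

    def test_mean_of_known_sample_correlations(self):
        x1, y1 = correlated_pair(0.9, seed=1)
        x2, y2 = correlated_pair(0.96, seed=2)
        fm = frame({"S0": [x1, y1], "S1": [x2, y2]},
                   batches={("S0", 0): "B1", ("S0", 1): "B2",
                            ("S1", 0): "B1", ("S1", 1): "B2"})
        assert interexperimental_reproducibility(fm) == pytest.approx(0.93,
                                                                      abs=1e-9)

    def test_no_multibatch_samples_rejected(self):
        rng = np.random.default_rng(0)
        fm = frame({"S0": [rng.normal(size=10), rng.normal(size=10)]})
        with pytest.raises(QCError):
            interexperimental_reproducibility(fm)


class TestEstimator:
    def test_fit_transform_and_frozen_threshold(self):
        rng = np.random.default_rng(6)
        samples = {}
        for i in range(6):
            center = rng.normal(0, 1, 40) * 10
            samples[f"S{i}"] = [center + rng.normal(0, 0.1, 40)
                                for _ in range(3)]
        fm = frame(samples)
        qc = ReplicateCorrelationQC().fit(fm)
        assert qc.r_th_ == pytest.approx(qc.mu_ - 3 * qc.sigma_)
        out = qc.transform(fm)
        assert len(out) == len(fm)
        frozen = ReplicateCorrelationQC(r_th=0.5).fit(fm)
        assert frozen.r_th_ == 0.5

    def test_transform_requires_fit(self):
        with pytest.raises(RuntimeError):
            ReplicateCorrelationQC().transform(frame(
                {"S0": [np.arange(5.0), np.arange(5.0) + 1]}))
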