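"""Peak detection, clustering, alignment and the feature matrix."""

import numpy as np
import pandas as pd
import pytest

from maldipep import (PeakConfig, Spectrum, SpectrumError, align_peaklist,
                      bin_and_select_features, build_feature_matrix,
                      build_reference_peaks, detect_peaks, estimate_noise)
from maldipep.io import CohortManifest, ManifestError
from maldipep.peaks import Peak, PeakList, ReferencePeakSet, _cluster_peaks
from maldipep.spectrum import PREPROCESSED


def spec(intensity, mz=None, state=PREPROCESSED):
    intensity = np.asarray(intensity, dtype=float)
    if mz is None:
        mz = 2000.0 + np.arange(intensity.size)
    return Spectrum(mz, intensity, sample_id="S", replicate_id="R", state=state)


def peaklist(mzs, intensities=None, sid="S", rid="R"):
    intensities = intensities or [1.0] * len(mzs)
    return PeakList(sample_id=sid, replicate_id=rid,
                    peaks=[Peak(m, i, 10.0) for m, i in zip(mzs, intensities)])


class TestEstimateNoise:
    def test_gaussian_noise_within_15pct(self):
        rng = np.random.default_rng(0)
        sd = 2.5
        noise = estimate_noise(spec(rng.normal(0, sd, 4000)))
        assert abs(np.median(noise) - sd) / sd < 0.15

    def test_constant_spectrum_gives_zero(self):
        assert np.all(estimate_noise(spec(np.full(500, 4.0))) == 0)

    def test_robust_to_one_huge_peak(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1.0, 4000)
        peak = 500 * np.exp(-0.5 * ((np.arange(4000) - 2000) / 5.0) ** 2)
        clean = np.median(estimate_noise(spec(base)))
        spiked = np.median(estimate_noise(spec(base + peak)))
        assert abs(spiked - clean) / clean < 0.20


class TestDetectPeaks:
    def test_flat_zero_spectrum_empty(self):
        assert len(detect_peaks(spec(np.zeros(500)))) == 0

    def test_single_gaussian_detected_at_apex(self):
        rng = np.random.default_rng(7)
        x = np.arange(800, dtype=float)
        y = 6.0 + rng.normal(0, 1.0, 800) + 10.0 * np.exp(
            -0.5 * ((x - 400) / 4.0) ** 2)
        pl = detect_peaks(spec(y))
        assert len(pl) == 1
        assert pl.peaks[0].mz == pytest.approx(2400.0, abs=1.0)

    def test_two_peaks_detected_sorted(self):
        mz = np.arange(2000.0, 10000.0)
        y = np.zeros(mz.size)
        for center in (3000.0, 9000.0):
            y += 1.0 * np.exp(-0.5 * ((mz - center) / 3.0) ** 2)
        rng = np.random.default_rng(0)
        y += np.abs(rng.normal(0, 0.01, mz.size))
        pl = detect_peaks(spec(y, mz=mz))
        found = pl.mz_array
        assert np.any(np.abs(found - 3000) < 2)
        assert np.any(np.abs(found - 9000) < 2)
        assert np.all(np.diff(found) > 0)

    def test_raw_spectrum_rejected(self):
        with pytest.raises(SpectrumError, match="preprocessed"):
            detect_peaks(spec(np.zeros(100), state="raw"))

    def test_all_returned_peaks_meet_snr(self, small_processed):
        processed, _, _ = small_processed
        cfg = PeakConfig()
        for s in processed[:4]:
            for p in detect_peaks(s, cfg).peaks:
                assert p.snr >= cfg.snr_threshold


class TestReferencePeaks:
    def test_jittered_cluster_collapses_to_one_reference(self):
        rng = np.random.default_rng(0)
        lists = [peaklist([5906.25 * (1 + rng.uniform(-0.0017, 0.0017))],
                          sid=f"S{i}") for i in range(10)]
        ref = build_reference_peaks(lists, PeakConfig())
        assert len(ref) == 1
        assert ref.mz[0] == pytest.approx(5906.25, rel=0.002)

    def test_80pct_presence_excluded_at_90pct_rule(self):
        lists = [peaklist([4000.0] if i < 8 else [], sid=f"S{i}")
                 for i in range(10)]
        assert len(build_reference_peaks(lists, PeakConfig())) == 0

    def test_separated_clusters_stay_distinct(self):
        lists = [peaklist([1000.0, 1010.0], sid=f"S{i}") for i in range(4)]
        cfg = PeakConfig(tolerance_rel=0.0017)
        clusters = _cluster_peaks(lists, cfg.tolerance_rel)
        assert len(clusters) == 2

    def test_needs_at_least_two_lists(self):
        with pytest.raises(ValueError):
            build_reference_peaks([peaklist([3000.0])], PeakConfig())


class TestAlignment:
    ref = ReferencePeakSet((2500.0, 4000.0, 6000.0, 9000.0))

    def test_uniform_scaling_corrected(self):
        scale = 1.0005
        pl = peaklist([m * scale for m in self.ref.mz])
        aligned = align_peaklist(pl, self.ref, PeakConfig())
        assert aligned.aligned
        for got, want in zip(aligned.mz_array, self.ref.mz):
            assert abs(got - want) / want < 0.0002

    def test_already_aligned_identity(self):
        pl = peaklist(list(self.ref.mz))
        aligned = align_peaklist(pl, self.ref, PeakConfig())
        assert np.allclose(aligned.mz_array, self.ref.mz, rtol=1e-6)

    def test_no_matches_passes_through_flagged(self):
        pl = peaklist([3000.0, 5000.0])
        aligned = align_peaklist(pl, self.ref, PeakConfig())
        assert not aligned.aligned
        assert aligned.warning is not None
        assert np.allclose(aligned.mz_array, pl.mz_array)


class TestBinning:
    def test_rare_peak_excluded(self):
        lists = [peaklist([3000.0, 5000.0] if i < 3 else [5000.0],
                          sid=f"S{i}") for i in range(10)]
        features = bin_and_select_features(lists, PeakConfig())
        assert list(features.mz) == pytest.approx([5000.0])

    def test_seventy_pct_presence_included(self):
        """A peak dropped with probability 0.3 across 200 spectra stays above
        the 50% frequency rule."""
        rng = np.random.default_rng(12)
        lists = [peaklist([4000.0] if rng.random() > 0.3 else [], sid=f"S{i}")
                 for i in range(200)]
        features = bin_and_select_features(lists, PeakConfig())
        assert list(features.mz) == pytest.approx([4000.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_and_select_features([], PeakConfig())

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        lists = [peaklist(sorted(c * (1 + rng.uniform(-5e-4, 5e-4))
                                 for c in (2500.0, 4400.0, 7000.0)),
                          sid=f"S{i}") for i in range(12)]
        a = bin_and_select_features(lists, PeakConfig())
        perm = [lists[i] for i in rng.permutation(len(lists))]
        b = bin_and_select_features(perm, PeakConfig())
        assert np.allclose(a.mz, b.mz, atol=1e-9)

    def test_matches_bruteforce_clustering_on_small_instances(self):
        """Greedy tolerance clustering equals union-find over the all-pairs
        within-tolerance graph for small, well-separated instances."""
        rng = np.random.default_rng(8)
        tol = 0.0017
        for trial in range(10):
            centers = rng.uniform(2000, 9500, size=rng.integers(2, 4))
            lists = []
            for i in range(rng.integers(2, 6)):
                mzs = sorted(c * (1 + rng.uniform(-4e-4, 4e-4))
                             for c in centers)
                lists.append(peaklist(mzs, sid=f"S{i}"))
            got = sorted(c["center"] for c in _cluster_peaks(lists, tol))

            # brute-force oracle: connected components of the tolerance graph
            all_mz = sorted(m for pl in lists for m in pl.mz_array)
            parent = list(range(len(all_mz)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(all_mz)):
                for j in range(i + 1, len(all_mz)):
                    if abs(all_mz[i] - all_mz[j]) <= tol * min(all_mz[i],
                                                               all_mz[j]):
                        parent[find(i)] = find(j)
            comps = {}
            for i, m in enumerate(all_mz):
                comps.setdefault(find(i), []).append(m)
            want = sorted(float(np.median(v)) for v in comps.values())
            assert len(got) == len(want)
            assert np.allclose(got, want, atol=1e-9)


class TestFeatureMatrix:
    def test_shape_and_completeness(self, small_features):
        matrix, extractor, _, _ = small_features
        assert matrix.shape == (36, len(extractor.features_) + 4)
        assert not matrix.isna().any().any()
        values = matrix[extractor.features_.columns].to_numpy()
        assert np.all(values >= 0)

    def test_every_row_has_a_manifest_entry(self, small_features,
                                            small_processed):
        matrix, _, _, _ = small_features
        _, manifest, _ = small_processed
        keys = set(zip(manifest.frame.sample_id, manifest.frame.replicate_id))
        assert set(zip(matrix.sample_id, matrix.replicate_id)) == keys

    def test_dropped_peak_filled_from_spectrum(self):
        from maldipep.peaks import FeatureSet

        mz = np.arange(2000.0, 3000.0)
        y = np.full(mz.size, 1e-5)
        y[500] = 5e-4  # real signal at 2500 that the peak list missed
        s = Spectrum(mz, y, sample_id="A", replicate_id="R1",
                     state=PREPROCESSED)
        pl = PeakList(sample_id="A", replicate_id="R1", peaks=[])
        manifest = CohortManifest(pd.DataFrame(
            [{"sample_id": "A", "replicate_id": "R1"}]))
        fm = build_feature_matrix([s], [pl], FeatureSet((2500.0,)), manifest,
                                  PeakConfig())
        assert fm["2500.00"].iloc[0] == pytest.approx(5e-4)

    def test_zero_fill_rule(self):
        from maldipep.peaks import FeatureSet

        mz = np.arange(2000.0, 3000.0)
        s = Spectrum(mz, np.full(mz.size, 1e-5), sample_id="A",
                     replicate_id="R1", state=PREPROCESSED)
        pl = PeakList(sample_id="A", replicate_id="R1", peaks=[])
        manifest = CohortManifest(pd.DataFrame(
            [{"sample_id": "A", "replicate_id": "R1"}]))
        fm = build_feature_matrix([s], [pl], FeatureSet((2500.0,)), manifest,
                                  PeakConfig(fill="zero"))
        assert fm["2500.00"].iloc[0] == 0.0

    def test_duplicate_spectra_give_identical_rows(self, small_features):
        matrix, extractor, processed, _ = small_features
        cols = extractor.features_.columns
        again = extractor.transform(processed[:2])
        for i in range(2):
            row = matrix[(matrix.sample_id == processed[i].sample_id)
                         & (matrix.replicate_id == processed[i].replicate_id)]
            assert np.allclose(row[cols].to_numpy()[0],
                               again[cols].to_numpy()[i])

    def test_replicate_missing_from_manifest_rejected(self):
        from maldipep.peaks import FeatureSet

        mz = np.arange(2000.0, 2100.0)
        s = Spectrum(mz, np.ones(mz.size), sample_id="A", replicate_id="R1",
                     state=PREPROCESSED)
        pl = PeakList(sample_id="A", replicate_id="R1", peaks=[])
        manifest = CohortManifest(pd.DataFrame(
            [{"sample_id": "B", "replicate_id": "R1"}]))
        with pytest.raises(ManifestError):
            build_feature_matrix([s], [pl], FeatureSet((2050.0,)), manifest,
                                 PeakConfig())


class TestEndToEndFeatureRecovery:
    def test_forty_true_peaks_recovered_without_dropout(self, small_features):
        """With every peak always present the pipeline recovers exactly the
        simulator's 40 peak positions, each within the mass tolerance."""
        from maldipep import DEFAULT_PEAK_POSITIONS

        _, extractor, _, _ = small_features
        found = np.array(extractor.features_.mz)
        truth = np.array(DEFAULT_PEAK_POSITIONS)
        assert found.size == truth.size == 40
        assert np.all(np.abs(found - truth) / truth <= 0.0017)
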