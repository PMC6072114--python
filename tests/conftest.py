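"""Shared fixtures: small rendered cohorts and in-memory feature frames."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from maldipep import (PeakFeatureExtractor, SpectrumPreprocessor,
                      SimulationConfig, generate_cohort)
from maldipep.io import HC, MGUS

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """12-sample rendered cohort, 3 replicates each, no dropout/corruption."""
    cfg = SimulationConfig(n_mgus=6, n_hc=6, replicates_min=3, replicates_max=3,
                           dropout_prob=0.0, corrupt_prob=0.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    spectra, manifest, truth = small_cohort
    return SpectrumPreprocessor().fit_transform(spectra), manifest, truth


@pytest.fixture(scope="session")
def small_features(small_processed):
    processed, manifest, truth = small_processed
    extractor = PeakFeatureExtractor()
    matrix = extractor.fit_transform(processed, manifest=manifest)
    return matrix, extractor, processed, truth


def make_feature_frame(n_per_class: int = 10, reps: int = 3,
                       n_features: int = 8, effect: float = 3.0,
                       noise: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """In-memory replicate-by-feature frame with a class shift on the first
    feature block — a fast stand-in for the rendered pipeline in CV tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_class):
        group = MGUS if i < n_per_class else HC
        center = rng.normal(0.0, 1.0, n_features)
        if group == MGUS:
            center[: max(1, n_features // 4)] += effect
        for j in range(reps):
            vec = center + rng.normal(0.0, noise, n_features)
            rows.append({"sample_id": f"S{i:03d}", "replicate_id": f"R{j + 1}",
                         "group": group, "batch": "B1",
                         **{f"{1000 + 10 * k}.00": vec[k]
                            for k in range(n_features)}})
    return pd.DataFrame(rows)
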