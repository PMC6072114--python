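"""Peak detection, alignment, binning and feature-matrix construction.

Peaks are local maxima of preprocessed spectra with a signal-to-noise ratio of
at least 3 (noise estimated by a sliding-window median absolute deviation).
Peaks are clustered across spectra with a relative mass tolerance (default
0.17%); clusters present in more than 90% of spectra become the reference
peaks used for mass-axis alignment, and clusters present in more than 50% of
aligned spectra become the spectral features.  The replicate-by-feature
intensity matrix is the object consumed by quality control and the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .io import CohortManifest, ManifestError
from .spectrum import PREPROCESSED, Spectrum, SpectrumError

_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass
class PeakConfig:
    snr_threshold: float = 3.0
    tolerance_rel: float = 0.0017      # 0.17% relative mass tolerance
    ref_min_freq: float = 0.90         # strict: frequency must exceed this
    feature_min_freq: float = 0.50
    noise_window: int = 201            # points; sliding-MAD noise estimator
    fill: str = "window_max"           # missing-cell rule: "window_max" | "zero"

    def validate(self) -> None:
        if not 0 < self.tolerance_rel < 0.01:
            raise ValueError("tolerance_rel must be in (0, 0.01)")
        for name in ("ref_min_freq", "feature_min_freq"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be non-negative")
        if self.noise_window < 3:
            raise ValueError("noise_window must be >= 3")
        if self.fill not in ("window_max", "zero"):
            raise ValueError(f"unknown fill rule {self.fill!r}")


@dataclass
class Peak:
    mz: float
    intensity: float
    snr: float


@dataclass
class PeakList:
    """Detected peaks of one spectrum, sorted by m/z."""

    sample_id: str
    replicate_id: str
    peaks: list = field(default_factory=list)
    aligned: bool = False
    warp: tuple = (1.0, 0.0)           # corrected_mz = a * mz + b
    warning: str | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def key(self) -> tuple:
        return (self.sample_id, self.replicate_id)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class ReferencePeakSet:
    """High-frequency (>90%) peak positions used as alignment anchors."""

    mz: tuple
    tolerance_rel: float = 0.0017

    def __post_init__(self) -> None:
        mz = tuple(float(m) for m in self.mz)
        if any(b <= a for a, b in zip(mz, mz[1:])):
            raise ValueError("reference peaks must be sorted and distinct")
        self.mz = mz

    def __len__(self) -> int:
        return len(self.mz)

    def to_dict(self) -> dict:
        return {"mz": list(self.mz), "tolerance_rel": self.tolerance_rel}

    @classmethod
    def from_dict(cls, d: dict) -> "ReferencePeakSet":
        return cls(mz=tuple(d["mz"]), tolerance_rel=float(d["tolerance_rel"]))


@dataclass
class FeatureSet:
    """Feature m/z labels: peaks with frequency > 50% after alignment."""

    mz: tuple
    tolerance_rel: float = 0.0017

    def __post_init__(self) -> None:
        mz = tuple(float(m) for m in self.mz)
        if any(b <= a for a, b in zip(mz, mz[1:])):
            raise ValueError("features must be sorted and distinct")
        self.mz = mz

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def columns(self) -> list:
        return [f"{m:.2f}" for m in self.mz]

    def to_dict(self) -> dict:
        return {"mz": list(self.mz), "tolerance_rel": self.tolerance_rel}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(mz=tuple(d["mz"]), tolerance_rel=float(d["tolerance_rel"]))


def estimate_noise(s: Spectrum, window: int = 201) -> np.ndarray:
    """Sliding-window MAD noise level per point (robust to peaks).

    Returns 1.4826 x local median absolute deviation about the local median,
    which estimates the noise standard deviation for Gaussian noise.  A
    constant spectrum yields zero noise.
    """
    y = np.asarray(s.intensity, dtype=float)
    window = int(min(window, y.size if y.size % 2 else y.size - 1))
    if window < 3:
        window = 3
    local_median = median_filter(y, size=window, mode="reflect")
    mad = median_filter(np.abs(y - local_median), size=window, mode="reflect")
    return _MAD_TO_SD * mad


def detect_peaks(s: Spectrum, cfg: PeakConfig | None = None) -> PeakList:
    """Local maxima with S/N >= the configured threshold.

    Requires a preprocessed spectrum.  The signal-to-noise ratio of a
    candidate is its height above the local median divided by the local MAD
    noise level — measuring height from the local noise floor rather than
    from zero, since the SNIP-subtracted residual keeps the (all-positive)
    noise band.  Candidates closer than the relative tolerance are pruned
    keeping the most intense.
    """
    cfg = cfg or PeakConfig()
    cfg.validate()
    if s.state != PREPROCESSED:
        raise SpectrumError("peak detection requires a preprocessed spectrum")
    y = s.intensity
    window = int(min(cfg.noise_window, y.size if y.size % 2 else y.size - 1))
    floor = median_filter(y, size=max(window, 3), mode="reflect")
    noise = estimate_noise(s, cfg.noise_window)
    idx, _ = find_peaks(y)
    peaks = []
    for i in idx:
        height = y[i] - floor[i]
        if y[i] <= 0 or height <= 0:
            continue
        snr = height / noise[i] if noise[i] > 0 else np.inf
        if snr >= cfg.snr_threshold:
            peaks.append(Peak(mz=float(s.mz[i]), intensity=float(y[i]),
                              snr=float(snr)))
    # enforce minimum separation: greedily keep the most intense
    kept = []
    for p in sorted(peaks, key=lambda p: -p.intensity):
        if all(abs(p.mz - q.mz) > cfg.tolerance_rel * q.mz for q in kept):
            kept.append(p)
    return PeakList(sample_id=s.sample_id, replicate_id=s.replicate_id, peaks=kept)


def _cluster_peaks(peaklists, tolerance_rel: float):
    """Tolerance clustering of peaks pooled across spectra.

    Peaks are sorted globally by m/z (so the result is independent of the
    order of the input spectra) and recursively bisected at the largest
    consecutive gap until every member lies within the relative tolerance of
    its cluster centre (the median m/z).

    Returns a list of dicts with keys ``center``, ``mzs``, ``spectra``.
    """
    items = []
    for i, pl in enumerate(peaklists):
        for p in pl.peaks:
            items.append((p.mz, i, p))
    items.sort(key=lambda t: t[0])
    clusters = []

    stack = [items] if items else []
    while stack:
        chunk = stack.pop()
        mzs = np.array([t[0] for t in chunk])
        # acceptance uses the midrange so a cloud jittered by up to the full
        # +-tolerance around one true mass stays a single bin
        midrange = 0.5 * (mzs[0] + mzs[-1])
        if np.all(np.abs(mzs - midrange) <= tolerance_rel * midrange):
            clusters.append({"center": float(np.median(mzs)),
                             "mzs": list(mzs),
                             "spectra": {t[1] for t in chunk},
                             "peaks": [(t[1], t[2]) for t in chunk]})
        else:
            cut = int(np.argmax(np.diff(mzs))) + 1
            stack.append(chunk[:cut])
            stack.append(chunk[cut:])
    clusters.sort(key=lambda c: c["center"])
    return clusters


def build_reference_peaks(peaklists, cfg: PeakConfig | None = None) -> ReferencePeakSet:
    """Cluster peaks across spectra; clusters present in more than
    ``ref_min_freq`` of the spectra become the alignment reference."""
    cfg = cfg or PeakConfig()
    cfg.validate()
    peaklists = list(peaklists)
    if len(peaklists) < 2:
        raise ValueError("reference-peak construction needs at least 2 peak lists")
    n = len(peaklists)
    clusters = _cluster_peaks(peaklists, cfg.tolerance_rel)
    centers = sorted(c["center"] for c in clusters
                     if len(c["spectra"]) / n > cfg.ref_min_freq)
    return ReferencePeakSet(mz=tuple(centers), tolerance_rel=cfg.tolerance_rel)


def align_peaklist(pl: PeakList, ref: ReferencePeakSet,
                   cfg: PeakConfig | None = None) -> PeakList:
    """Monotone (linear shift + scale) mass-axis correction fit on matched
    reference peaks.

    Each reference is matched to its nearest detected peak within the relative
    tolerance; with fewer than two matches the list passes through unaligned
    and flagged.
    """
    cfg = cfg or PeakConfig()
    cfg.validate()
    mzs = pl.mz_array
    matches = []
    for r in ref.mz:
        if mzs.size == 0:
            break
        j = int(np.argmin(np.abs(mzs - r)))
        if abs(mzs[j] - r) <= cfg.tolerance_rel * r:
            matches.append((mzs[j], r))
    if len(matches) < 2:
        return replace(pl, peaks=[replace(p) for p in pl.peaks], aligned=False,
                       warp=(1.0, 0.0),
                       warning="unaligned: fewer than 2 reference matches")
    obs = np.array([m[0] for m in matches])
    tgt = np.array([m[1] for m in matches])
    if np.ptp(obs) == 0:
        a, b = 1.0, float(np.mean(tgt - obs))
    else:
        a, b = np.polyfit(obs, tgt, 1)
    if a <= 0:
        return replace(pl, peaks=[replace(p) for p in pl.peaks], aligned=False,
                       warp=(1.0, 0.0), warning="unaligned: non-monotone fit")
    new_peaks = [Peak(mz=float(a * p.mz + b), intensity=p.intensity, snr=p.snr)
                 for p in pl.peaks]
    return replace(pl, peaks=new_peaks, aligned=True, warp=(float(a), float(b)),
                   warning=None)


def bin_and_select_features(peaklists, cfg: PeakConfig | None = None) -> FeatureSet:
    """Tolerance-cluster aligned peaks; clusters with frequency above
    ``feature_min_freq`` become the spectral features."""
    cfg = cfg or PeakConfig()
    cfg.validate()
    peaklists = list(peaklists)
    if not peaklists:
        raise ValueError("no peak lists to bin")
    n = len(peaklists)
    clusters = _cluster_peaks(peaklists, cfg.tolerance_rel)
    centers = sorted(c["center"] for c in clusters
                     if len(c["spectra"]) / n > cfg.feature_min_freq)
    return FeatureSet(mz=tuple(centers), tolerance_rel=cfg.tolerance_rel)


def build_feature_matrix(spectra, peaklists, features: FeatureSet,
                         manifest: CohortManifest,
                         cfg: PeakConfig | None = None) -> pd.DataFrame:
    """Replicate-by-feature intensity matrix.

    One row per technical replicate listed in the manifest; the cell for
    feature f is the intensity of the matched aligned peak (most intense
    within tolerance), or — when the replicate has no peak there — the
    maximum preprocessed intensity inside the tolerance window around f on
    the replicate's (warped) mass axis, or zero under the ``zero`` fill rule.
    """
    cfg = cfg or PeakConfig()
    cfg.validate()
    spec_by_key = {s.key: s for s in spectra}
    pl_by_key = {pl.key: pl for pl in peaklists}
    extra = set(pl_by_key) - {(r.sample_id, r.replicate_id)
                              for r in manifest.frame.itertuples()}
    if extra:
        raise ManifestError(f"replicates missing from manifest: {sorted(extra)}")
    rows = []
    for rec in manifest.frame.itertuples():
        key = (rec.sample_id, rec.replicate_id)
        if key not in pl_by_key or key not in spec_by_key:
            raise ManifestError(f"no spectrum/peak list for manifest entry {key}")
        pl = pl_by_key[key]
        s = spec_by_key[key]
        a, b = pl.warp
        warped_mz = a * s.mz + b
        row = {"sample_id": rec.sample_id, "replicate_id": rec.replicate_id,
               "group": getattr(rec, "group", None),
               "batch": getattr(rec, "batch", "")}
        peak_mz = pl.mz_array
        peak_int = np.array([p.intensity for p in pl.peaks])
        for f, col in zip(features.mz, features.columns):
            tol = cfg.tolerance_rel * f
            value = None
            if peak_mz.size:
                inside = np.abs(peak_mz - f) <= tol
                if inside.any():
                    value = float(peak_int[inside].max())
            if value is None:
                if cfg.fill == "zero":
                    value = 0.0
                else:
                    lo = np.searchsorted(warped_mz, f - tol)
                    hi = np.searchsorted(warped_mz, f + tol, side="right")
                    value = float(s.intensity[lo:hi].max()) if hi > lo else 0.0
            row[col] = value
        rows.append(row)
    return pd.DataFrame(rows)


class PeakFeatureExtractor:
    """scikit-learn-style transformer: spectra -> feature matrix.

    ``fit`` learns the reference peaks (alignment anchors) and the feature
    set from a training cohort of preprocessed spectra; ``transform`` detects
    and aligns peaks in (new) spectra and emits the intensity matrix.  Fitted
    attributes: ``reference_peaks_``, ``features_``.
    """

    def __init__(self, snr_threshold: float = 3.0, tolerance_rel: float = 0.0017,
                 ref_min_freq: float = 0.90, feature_min_freq: float = 0.50,
                 noise_window: int = 201, fill: str = "window_max"):
        self.snr_threshold = snr_threshold
        self.tolerance_rel = tolerance_rel
        self.ref_min_freq = ref_min_freq
        self.feature_min_freq = feature_min_freq
        self.noise_window = noise_window
        self.fill = fill

    def _config(self) -> PeakConfig:
        return PeakConfig(snr_threshold=self.snr_threshold,
                          tolerance_rel=self.tolerance_rel,
                          ref_min_freq=self.ref_min_freq,
                          feature_min_freq=self.feature_min_freq,
                          noise_window=self.noise_window, fill=self.fill)

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("snr_threshold", "tolerance_rel", "ref_min_freq",
                 "feature_min_freq", "noise_window", "fill")}

    def set_params(self, **params) -> "PeakFeatureExtractor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "PeakFeatureExtractor":
        cfg = self._config()
        raw_lists = [detect_peaks(s, cfg) for s in X]
        self.reference_peaks_ = build_reference_peaks(raw_lists, cfg)
        aligned = [align_peaklist(pl, self.reference_peaks_, cfg)
                   for pl in raw_lists]
        self.features_ = bin_and_select_features(aligned, cfg)
        return self

    def transform(self, X, manifest: CohortManifest | None = None) -> pd.DataFrame:
        if not hasattr(self, "features_"):
            raise RuntimeError("PeakFeatureExtractor is not fitted")
        cfg = self._config()
        if manifest is None:
            manifest = CohortManifest(pd.DataFrame(
                {"sample_id": [s.sample_id for s in X],
                 "replicate_id": [s.replicate_id for s in X]}))
        aligned = [align_peaklist(detect_peaks(s, cfg), self.reference_peaks_, cfg)
                   for s in X]
        return build_feature_matrix(X, aligned, self.features_, manifest, cfg)

    def fit_transform(self, X, y=None, manifest: CohortManifest | None = None
                      ) -> pd.DataFrame:
        return self.fit(X).transform(X, manifest=manifest)
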