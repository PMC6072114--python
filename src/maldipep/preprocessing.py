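"""Single-spectrum preprocessing.

The fixed stage order is: trim to the analysis window, square-root transform
(variance stabilization), Savitzky-Golay smoothing, SNIP baseline estimation
and subtraction, and total-ion-current (TIC) normalization.  A preprocessed
spectrum has non-negative intensities summing to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectrum import PREPROCESSED, RAW, Spectrum, SpectrumError


@dataclass
class PreprocessConfig:
    sg_half_window: int = 10
    sg_poly_order: int = 3
    snip_iterations: int = 100
    mz_min: float = 2000.0
    mz_max: float = 10000.0

    def validate(self) -> None:
        if self.sg_half_window < 1:
            raise ValueError("sg_half_window must be >= 1")
        if not 0 <= self.sg_poly_order < 2 * self.sg_half_window + 1:
            raise ValueError("sg_poly_order must be below the window length")
        if self.snip_iterations < 1:
            raise ValueError("snip_iterations must be >= 1")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be below mz_max")


def sqrt_transform(s: Spectrum) -> Spectrum:
    """Square-root transform for variance stabilization."""
    negative = np.flatnonzero(s.intensity < 0)
    if negative.size:
        i = int(negative[0])
        raise SpectrumError(
            f"negative intensity {s.intensity[i]:g} at index {i}; "
            "square root undefined"
        )
    return s.with_intensity(np.sqrt(s.intensity), "sqrt")


def smooth_sg(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Savitzky-Golay least-squares local-polynomial smoothing."""
    cfg.validate()
    window = 2 * cfg.sg_half_window + 1
    if len(s) <= 2 * cfg.sg_half_window:
        raise SpectrumError(
            f"spectrum of length {len(s)} shorter than the "
            f"{window}-point smoothing window"
        )
    smoothed = savgol_filter(s.intensity, window_length=window,
                             polyorder=cfg.sg_poly_order, mode="interp")
    return s.with_intensity(smoothed, "savitzky_golay")


def snip_baseline(s: Spectrum, cfg: PreprocessConfig) -> np.ndarray:
    """SNIP baseline estimate (decreasing clipping-window variant).

    Iteratively replaces each point by the minimum of itself and the mean of
    its two neighbours at distance w, for w = iterations .. 1.  The estimate
    never exceeds the input and is non-negative for non-negative input.
    """
    cfg.validate()
    y = np.asarray(s.intensity, dtype=float)
    n = y.size
    baseline = y.copy()
    start = min(cfg.snip_iterations, (n - 1) // 2)
    for w in range(start, 0, -1):
        mid = 0.5 * (baseline[: n - 2 * w] + baseline[2 * w:])
        baseline[w: n - w] = np.minimum(baseline[w: n - w], mid)
    return baseline


def subtract_baseline(s: Spectrum, baseline: np.ndarray) -> Spectrum:
    """Subtract a baseline estimate, clipping negatives to zero."""
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != s.intensity.shape:
        raise SpectrumError(
            f"baseline length {baseline.size} does not match spectrum "
            f"length {len(s)}"
        )
    return s.with_intensity(np.clip(s.intensity - baseline, 0.0, None),
                            "snip_subtract")


def tic_normalize(s: Spectrum) -> Spectrum:
    """Divide intensities by the total ion current so they sum to one."""
    total = float(np.sum(s.intensity))
    if total <= 0:
        raise SpectrumError("total ion current is zero; TIC normalization undefined")
    return s.with_intensity(s.intensity / total, "tic")


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Full preprocessing pipeline on a raw spectrum.

    Stages (fixed order): sqrt -> Savitzky-Golay -> SNIP subtraction -> trim
    to the analysis window -> TIC.  Smoothing and baseline estimation run on
    the full acquired range so that their one-sided edge effects fall outside
    the trimmed window whenever the raw data extend beyond it; TIC normalizes
    over the analysis window only.  The result is flagged ``preprocessed``;
    re-running on an already preprocessed spectrum is an error.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    cfg.validate()
    if s.state != RAW:
        raise SpectrumError(
            f"preprocess expects a raw spectrum, got state {s.state!r}"
        )
    out = sqrt_transform(s)
    out = smooth_sg(out, cfg)
    out = subtract_baseline(out, snip_baseline(out, cfg))
    out = out.trimmed(cfg.mz_min, cfg.mz_max)
    out = tic_normalize(out)
    out.state = PREPROCESSED
    return out


class SpectrumPreprocessor:
    """Stateless scikit-learn-style transformer applying :func:`preprocess`.

    Operates on lists of :class:`Spectrum`; ``fit`` is a no-op kept for
    pipeline compatibility.
    """

    def __init__(self, sg_half_window: int = 10, sg_poly_order: int = 3,
                 snip_iterations: int = 100, mz_min: float = 2000.0,
                 mz_max: float = 10000.0):
        self.sg_half_window = sg_half_window
        self.sg_poly_order = sg_poly_order
        self.snip_iterations = snip_iterations
        self.mz_min = mz_min
        self.mz_max = mz_max

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            sg_half_window=self.sg_half_window,
            sg_poly_order=self.sg_poly_order,
            snip_iterations=self.snip_iterations,
            mz_min=self.mz_min,
            mz_max=self.mz_max,
        )

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("sg_half_window", "sg_poly_order", "snip_iterations",
                 "mz_min", "mz_max")}

    def set_params(self, **params) -> "SpectrumPreprocessor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "SpectrumPreprocessor":
        self._config().validate()
        self.n_fitted_ = len(X)
        return self

    def transform(self, X) -> list:
        cfg = self._config()
        return [preprocess(s, cfg) for s in X]

    def fit_transform(self, X, y=None) -> list:
        return self.fit(X).transform(X)
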