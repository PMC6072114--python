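"""Mass-spectrum container.

A :class:`Spectrum` holds one technical-replicate MALDI-TOF acquisition as a
pair of equal-length arrays (m/z in Da, intensity in arbitrary units) plus the
identity metadata needed to tie it back to a cohort manifest.  Spectra exist in
two states: ``raw`` (as acquired / simulated) and ``preprocessed`` (variance
stabilized, smoothed, baseline subtracted and TIC normalized, so intensities
are non-negative and sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RAW = "raw"
PREPROCESSED = "preprocessed"


class SpectrumError(ValueError):
    """Raised for malformed spectra (lengths, ordering, negative values...)."""


@dataclass
class Spectrum:
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""
    state: str = RAW
    stage_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("m/z and intensity must be one-dimensional arrays")
        if self.mz.size != self.intensity.size:
            raise SpectrumError(
                f"length mismatch: {self.mz.size} m/z values vs "
                f"{self.intensity.size} intensities"
            )
        if self.mz.size == 0:
            raise SpectrumError("empty spectrum")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise SpectrumError("non-finite value in spectrum")
        diffs = np.diff(self.mz)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            if diffs[i] == 0:
                raise SpectrumError(f"duplicated m/z value {self.mz[i]:g} at index {i}")
            raise SpectrumError(
                f"m/z values not strictly increasing at index {i} "
                f"({self.mz[i]:g} -> {self.mz[i + 1]:g})"
            )
        if self.state not in (RAW, PREPROCESSED):
            raise SpectrumError(f"unknown spectrum state {self.state!r}")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def key(self) -> tuple:
        """(sample_id, replicate_id) identity pair."""
        return (self.sample_id, self.replicate_id)

    def with_intensity(self, intensity, stage: str, state: str | None = None) -> "Spectrum":
        """Copy of this spectrum with new intensities and a stage-log entry."""
        return Spectrum(
            mz=self.mz.copy(),
            intensity=np.asarray(intensity, dtype=float),
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            state=self.state if state is None else state,
            stage_log=[*self.stage_log, stage],
        )

    def trimmed(self, mz_min: float, mz_max: float) -> "Spectrum":
        """Restrict to the analysis mass window [mz_min, mz_max]."""
        mask = (self.mz >= mz_min) & (self.mz <= mz_max)
        if not np.any(mask):
            raise SpectrumError(
                f"no data points inside the mass window [{mz_min}, {mz_max}]"
            )
        return Spectrum(
            mz=self.mz[mask],
            intensity=self.intensity[mask],
            sample_id=self.sample_id,
            replicate_id=self.replicate_id,
            state=self.state,
            stage_log=[*self.stage_log, f"trim[{mz_min:g},{mz_max:g}]"],
        )
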