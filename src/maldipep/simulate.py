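"""Synthetic serum-peptidome cohort generator.

Emulates linear-mode MALDI-TOF spectra of the 2–10 kDa serum peptidome for a
two-class cohort (MGUS patients vs healthy controls, HC) with 3–6 technical
replicates per sample.  Each raw spectrum is

    exponential baseline + Gaussian peaks + additive Gaussian noise, clipped at 0

where peak amplitudes are log-normal with a per-position scale, a per-sample
biological random effect and a per-replicate technical random effect; a subset
of positions ("discriminative peaks") has its mean amplitude multiplied by
``effect_size`` in the MGUS class.  Real-data nuisances are included: a
per-spectrum multiplicative mass-axis error (within the downstream 0.17%
alignment tolerance), per-peak dropout, and occasional corrupted replicates
whose peak amplitudes are permuted across positions so that they decorrelate
from their siblings and exercise the quality-control path.

The generator records a full ground-truth sidecar (true jittered peak
positions and amplitudes per spectrum, corruption flags, the discriminative
positions) so downstream stages can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CohortManifest, HC, MGUS, write_json, write_manifest, write_spectrum
from .spectrum import Spectrum

#: Default peak positions (Da): 40 peptide/small-protein peaks spanning the
#: 2–10 kDa window at a density typical of linear-mode serum profiling.
DEFAULT_PEAK_POSITIONS = (
    2021.69, 2082.35, 2114.80, 2192.65, 2209.83, 2378.88, 2495.96, 2554.40,
    2604.38, 2641.45, 2660.76, 2723.83, 2755.04, 2769.70, 2863.08, 2884.92,
    2933.20, 2954.46, 3159.17, 3192.90, 3215.50, 3242.07, 3263.82, 3449.01,
    3884.10, 3954.33, 4055.61, 4092.44, 4211.37, 4269.32, 4283.17, 4644.92,
    4965.40, 5338.46, 5906.25, 6434.47, 6632.72, 7767.10, 9133.84, 9290.47,
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Counts and replicate range follow the emulated study design (3–6 technical
    replicates per serum sample, 2–10 kDa analysis window); intensity-model
    parameters are package choices documented in docs/methods.md.
    """

    n_mgus: int = 40
    n_hc: int = 40
    replicates_min: int = 3
    replicates_max: int = 6
    mz_min: float = 2000.0
    mz_max: float = 10000.0
    grid_step: float = 1.0
    grid_margin: float = 300.0            # raw spectra extend past the window; trimming is a preprocessing step
    peak_positions: tuple = DEFAULT_PEAK_POSITIONS
    n_discriminative: int = 5
    effect_size: float = 2.0             # multiplicative MGUS shift on discriminative peaks
    peak_width_ppm: float = 500.0        # Gaussian s.d. relative to m/z (500 ppm = 0.05%)
    scale_min: float = 50.0              # per-position base amplitude, log-uniform
    scale_max: float = 500.0
    biological_sd: float = 0.35          # between-sample log-normal s.d.
    technical_sd: float = 0.15           # between-replicate log-normal s.d.
    baseline_amplitude: float = 300.0
    baseline_decay: float = 1500.0       # Da; baseline = A * exp(-(m - mz_min)/decay) + offset
    baseline_offset: float = 30.0        # detector offset: keeps the baseline above the noise floor
    noise_sd: float = 3.0
    mass_jitter_rel: float = 5e-4        # |per-spectrum mass-axis scale error| bound
    dropout_prob: float = 0.05
    corrupt_prob: float = 0.05
    n_batches: int = 2
    n_interexp: int = 4                  # samples whose replicates span two batches
    seed: int = 0

    def validate(self) -> None:
        if self.n_mgus < 1 or self.n_hc < 1:
            raise ValueError("both classes need at least one sample")
        if not (1 <= self.replicates_min <= self.replicates_max):
            raise ValueError("invalid replicate range")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be below mz_max")
        pos = np.asarray(self.peak_positions, dtype=float)
        if pos.size == 0:
            raise ValueError("no peak positions")
        if np.any(pos < self.mz_min) or np.any(pos > self.mz_max):
            raise ValueError("peak positions must lie inside the mass window")
        if self.n_discriminative > pos.size:
            raise ValueError(
                f"n_discriminative ({self.n_discriminative}) exceeds the number "
                f"of peak positions ({pos.size})"
            )
        for name in ("dropout_prob", "corrupt_prob", "mass_jitter_rel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.noise_sd < 0 or self.peak_width_ppm <= 0:
            raise ValueError("invalid noise/width parameters")


@dataclass
class ReplicateTruth:
    """Ground truth for one simulated technical replicate."""

    sample_id: str
    replicate_id: str
    group: str
    corrupted: bool
    mass_scale: float                    # applied multiplicative mass-axis error
    positions: np.ndarray                # jittered true peak centers (Da)
    amplitudes: np.ndarray               # rendered amplitudes (after dropout/corruption)
    clean_amplitudes: np.ndarray         # amplitudes before dropout/corruption
    dropped: np.ndarray                  # boolean dropout mask


@dataclass
class CohortTruth:
    """Cohort-level ground truth record."""

    peak_positions: np.ndarray
    discriminative_idx: np.ndarray
    base_scales: np.ndarray
    replicates: dict = field(default_factory=dict)   # (sample_id, replicate_id) -> ReplicateTruth

    def to_json_dict(self) -> dict:
        return {
            "peak_positions": self.peak_positions.tolist(),
            "discriminative_idx": self.discriminative_idx.tolist(),
            "base_scales": self.base_scales.tolist(),
            "replicates": {
                f"{s}/{r}": {
                    "group": t.group,
                    "corrupted": bool(t.corrupted),
                    "mass_scale": float(t.mass_scale),
                    "positions": t.positions.tolist(),
                    "amplitudes": t.amplitudes.tolist(),
                    "clean_amplitudes": t.clean_amplitudes.tolist(),
                    "dropped": t.dropped.astype(bool).tolist(),
                }
                for (s, r), t in self.replicates.items()
            },
        }


def _render(grid: np.ndarray, positions: np.ndarray, amplitudes: np.ndarray,
            widths: np.ndarray, baseline: np.ndarray, noise: np.ndarray) -> np.ndarray:
    y = baseline + noise
    for pos, amp, width in zip(positions, amplitudes, widths):
        if amp <= 0:
            continue
        lo = np.searchsorted(grid, pos - 5 * width)
        hi = np.searchsorted(grid, pos + 5 * width)
        seg = grid[lo:hi]
        y[lo:hi] += amp * np.exp(-0.5 * ((seg - pos) / width) ** 2)
    return np.clip(y, 0.0, None)


def generate_cohort(config: SimulationConfig):
    """Generate a labeled synthetic cohort.

    Returns ``(spectra, manifest, truth)``: a list of raw :class:`Spectrum`
    (one per technical replicate), a :class:`CohortManifest`, and a
    :class:`CohortTruth` ground-truth record.  Identical configs (including
    ``seed``) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = np.asarray(config.peak_positions, dtype=float)
    n_peaks = positions.size

    disc_idx = np.sort(rng.choice(n_peaks, size=config.n_discriminative, replace=False))
    base_scales = np.exp(rng.uniform(np.log(config.scale_min),
                                     np.log(config.scale_max), size=n_peaks))
    # dropout is detection-limit driven: weak peaks vanish preferentially,
    # with the configured probability as the per-peak average
    if config.dropout_prob > 0:
        inv = 1.0 / base_scales
        dropout_p = np.minimum(1.0, config.dropout_prob * inv / inv.mean())
    else:
        dropout_p = np.zeros(n_peaks)

    grid = np.arange(config.mz_min - config.grid_margin,
                     config.mz_max + config.grid_margin + config.grid_step,
                     config.grid_step)
    baseline = config.baseline_amplitude * np.exp(-(grid - config.mz_min)
                                                  / config.baseline_decay) \
        + config.baseline_offset

    spectra, rows = [], []
    truth = CohortTruth(peak_positions=positions, discriminative_idx=disc_idx,
                        base_scales=base_scales)

    labels = [MGUS] * config.n_mgus + [HC] * config.n_hc
    for i, group in enumerate(labels):
        sample_id = f"S{i:03d}"
        interexp = i < config.n_interexp or (
            config.n_mgus <= i < config.n_mgus + config.n_interexp)
        sample_batch = f"B{i % config.n_batches + 1}"
        sample_eff = np.exp(rng.normal(0.0, config.biological_sd, size=n_peaks))
        class_factor = np.ones(n_peaks)
        if group == MGUS:
            class_factor[disc_idx] = config.effect_size
        n_rep = int(rng.integers(config.replicates_min, config.replicates_max + 1))
        for j in range(n_rep):
            replicate_id = f"R{j + 1}"
            amps = (base_scales * class_factor * sample_eff
                    * np.exp(rng.normal(0.0, config.technical_sd, size=n_peaks)))
            clean = amps.copy()
            dropped = rng.random(n_peaks) < dropout_p
            amps = np.where(dropped, 0.0, amps)
            corrupted = bool(rng.random() < config.corrupt_prob)
            if corrupted:
                amps = rng.permutation(amps)
            scale = 1.0 + rng.uniform(-config.mass_jitter_rel, config.mass_jitter_rel)
            jittered = positions * scale
            widths = config.peak_width_ppm * 1e-6 * jittered
            noise = rng.normal(0.0, config.noise_sd, size=grid.size) \
                if config.noise_sd > 0 else np.zeros(grid.size)
            y = _render(grid, jittered, amps, widths, baseline, noise)
            spectra.append(Spectrum(grid.copy(), y, sample_id=sample_id,
                                    replicate_id=replicate_id))
            batch = (f"B{j % 2 + 1}" if interexp and config.n_batches >= 2
                     else sample_batch)
            rows.append({"sample_id": sample_id, "replicate_id": replicate_id,
                         "group": group, "batch": batch})
            truth.replicates[(sample_id, replicate_id)] = ReplicateTruth(
                sample_id=sample_id, replicate_id=replicate_id, group=group,
                corrupted=corrupted, mass_scale=scale, positions=jittered,
                amplitudes=amps, clean_amplitudes=clean, dropped=dropped)

    manifest = CohortManifest(pd.DataFrame(rows))
    return spectra, manifest, truth


def write_cohort(spectra, manifest: CohortManifest, truth: CohortTruth, outdir) -> Path:
    """Write one spectrum text file per replicate, a manifest CSV (with paths)
    and a JSON ground-truth sidecar; returns the manifest path."""
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    paths = []
    for s in spectra:
        rel = f"spectra/{s.sample_id}_{s.replicate_id}.txt"
        write_spectrum(s, outdir / rel)
        paths.append(rel)
    frame = manifest.frame.copy()
    frame["path"] = paths
    manifest_path = outdir / "manifest.csv"
    write_manifest(CohortManifest(frame), manifest_path)
    write_json(truth.to_json_dict(), outdir / "ground_truth.json")
    return manifest_path


def config_from_dict(data: dict) -> SimulationConfig:
    """Strict construction: unknown keys are rejected."""
    allowed = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    cfg = SimulationConfig(**{k: (tuple(v) if k == "peak_positions" else v)
                              for k, v in data.items()})
    cfg.validate()
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["peak_positions"] = list(d["peak_positions"])
    return d
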