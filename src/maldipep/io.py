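"""Plain-text I/O: two-column spectrum files and cohort manifests.

The canonical interchange format is a delimited two-column text file per
spectrum (m/z, intensity; tab, comma or whitespace separated; ``#`` comments
and one optional header line allowed) plus a CSV manifest with columns
``sample_id, replicate_id, group, batch, path`` (``group`` absent for blinded
cohorts, ``batch``/``path`` optional).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectrum import Spectrum, SpectrumError

MGUS = "MGUS"
HC = "HC"
GROUPS = (MGUS, HC)

#: Manifest / feature-matrix metadata columns (everything else is a feature).
METADATA_COLUMNS = ("sample_id", "replicate_id", "group", "batch")

_SPLIT = re.compile(r"[,\t ]+")


class ManifestError(ValueError):
    """Raised for malformed cohort manifests."""


def read_spectrum(path, sample_id: str = "", replicate_id: str = "") -> Spectrum:
    """Read a two-column (m/z, intensity) text file into a validated Spectrum.

    Malformed lines are reported with their 1-based line number.  Duplicated
    or unsorted m/z values are errors, not silently repaired.
    """
    path = Path(path)
    mz, intensity = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = _SPLIT.split(text)
            if len(parts) != 2:
                raise SpectrumError(
                    f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                mz.append(float(parts[0]))
                intensity.append(float(parts[1]))
            except ValueError:
                if lineno == 1:  # tolerate a single header line
                    continue
                raise SpectrumError(
                    f"{path.name}:{lineno}: non-numeric cell in {parts!r}"
                ) from None
    if not mz:
        raise SpectrumError(f"{path.name}: no data rows")
    try:
        return Spectrum(np.array(mz), np.array(intensity),
                        sample_id=sample_id, replicate_id=replicate_id)
    except SpectrumError as exc:
        raise SpectrumError(f"{path.name}: {exc}") from None


def write_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, data, fmt=["%.6f", "%.10g"], delimiter="\t",
               header="mz\tintensity", comments="")


@dataclass
class CohortManifest:
    """Validated table of (sample_id, replicate_id, group, batch[, path]) rows."""

    frame: pd.DataFrame
    blinded: bool = False

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in ("sample_id", "replicate_id"):
            if col not in df.columns:
                raise ManifestError(f"manifest missing required column {col!r}")
            df[col] = df[col].astype(str)
        if df.empty:
            raise ManifestError("empty manifest")
        dupes = df.duplicated(subset=["sample_id", "replicate_id"])
        if dupes.any():
            row = df[dupes].iloc[0]
            raise ManifestError(
                f"duplicate (sample_id, replicate_id) pair "
                f"({row['sample_id']}, {row['replicate_id']})"
            )
        if "group" not in df.columns:
            self.blinded = True
            df["group"] = None
        else:
            bad = set(df["group"].dropna().unique()) - set(GROUPS)
            if bad:
                raise ManifestError(f"unknown group label(s): {sorted(bad)}")
            per_sample = df.groupby("sample_id")["group"].nunique(dropna=True)
            if (per_sample > 1).any():
                sid = per_sample[per_sample > 1].index[0]
                raise ManifestError(f"group label not constant within sample {sid!r}")
        if "batch" not in df.columns:
            df["batch"] = ""
        df["batch"] = df["batch"].fillna("").astype(str)
        self.frame = df.reset_index(drop=True)

    @property
    def samples(self) -> list:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def group_of(self, sample_id: str):
        rows = self.frame[self.frame["sample_id"] == str(sample_id)]
        if rows.empty:
            raise ManifestError(f"sample {sample_id!r} not in manifest")
        return rows["group"].iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


def read_manifest(path, check_paths: bool = True) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    A manifest without a ``group`` column is accepted and flagged blinded
    (unknown samples awaiting classification).  If a ``path`` column is
    present the referenced spectrum files must exist.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    manifest = CohortManifest(frame)
    if check_paths and "path" in manifest.frame.columns:
        base = path.parent
        missing = [p for p in manifest.frame["path"]
                   if not (base / p).exists() and not Path(p).exists()]
        if missing:
            raise ManifestError(f"manifest references missing spectrum files: {missing}")
    return manifest


def write_manifest(manifest: CohortManifest, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest.frame.to_csv(path, index=False)


def feature_columns(matrix: pd.DataFrame) -> list:
    """Feature (m/z) columns of a feature matrix — everything non-metadata."""
    return [c for c in matrix.columns if c not in METADATA_COLUMNS]


def feature_values(matrix: pd.DataFrame) -> np.ndarray:
    """Replicate-by-feature intensity array of a feature matrix."""
    return matrix[feature_columns(matrix)].to_numpy(dtype=float)


def write_json(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    raise TypeError(f"cannot serialize {type(value)!r}")
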