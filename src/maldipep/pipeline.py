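"""End-to-end orchestration: simulate -> preprocess -> features -> QC ->
train / cross-validate, with every artifact stamped with the config digest
and seed."""

from __future__ import annotations

import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .crossval import double_cv, tune_20fold
from .io import read_manifest, read_spectrum, write_json
from .peaks import PeakFeatureExtractor
from .preprocessing import SpectrumPreprocessor
from .qc import ReplicateCorrelationQC, interexperimental_reproducibility, QCError
from .simulate import generate_cohort, write_cohort
from .svm import PredictiveModel, SVMConfig, train_svm

logger = logging.getLogger(__name__)


def _stamp(cfg: PipelineConfig) -> dict:
    return {"config_digest": cfg.digest, "seed": cfg.seed,
            "maldipep_version": __version__}


def load_cohort(manifest_path):
    """Read a manifest CSV and its referenced spectrum files."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    if "path" not in manifest.frame.columns:
        raise ValueError("manifest has no 'path' column; cannot load spectra")
    base = manifest_path.parent
    spectra = []
    for rec in manifest.frame.itertuples():
        p = Path(rec.path)
        spectra.append(read_spectrum(p if p.exists() else base / p,
                                     sample_id=rec.sample_id,
                                     replicate_id=rec.replicate_id))
    return spectra, manifest


def run_pipeline(cfg: PipelineConfig, outdir, manifest_path=None) -> dict:
    """Execute the configured workflow and write artifacts under ``outdir``.

    With no ``manifest_path`` a synthetic cohort is generated first.  Returns
    a dict of artifact paths.  Stage failures abort with the failing stage
    named.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    stage = "simulate"
    try:
        if manifest_path is None:
            cfg.simulation.seed = cfg.seed
            spectra, manifest, truth = generate_cohort(cfg.simulation)
            artifacts["manifest"] = str(write_cohort(spectra, manifest, truth,
                                                     outdir / "cohort"))
        else:
            spectra, manifest = load_cohort(manifest_path)
            artifacts["manifest"] = str(manifest_path)

        stage = "preprocess"
        pre = SpectrumPreprocessor(**{k: getattr(cfg.preprocessing, k)
                                      for k in ("sg_half_window", "sg_poly_order",
                                                "snip_iterations", "mz_min",
                                                "mz_max")})
        processed = pre.fit_transform(spectra)

        stage = "features"
        extractor = PeakFeatureExtractor(
            snr_threshold=cfg.peaks.snr_threshold,
            tolerance_rel=cfg.peaks.tolerance_rel,
            ref_min_freq=cfg.peaks.ref_min_freq,
            feature_min_freq=cfg.peaks.feature_min_freq,
            noise_window=cfg.peaks.noise_window, fill=cfg.peaks.fill)
        matrix = extractor.fit_transform(processed, manifest=manifest)
        matrix_path = outdir / "feature_matrix.csv"
        matrix.to_csv(matrix_path, index=False)
        artifacts["feature_matrix"] = str(matrix_path)
        write_json({**_stamp(cfg), "reference_peaks":
                    extractor.reference_peaks_.to_dict(),
                    "features": extractor.features_.to_dict()},
                   outdir / "features.json")
        artifacts["features"] = str(outdir / "features.json")

        stage = "qc"
        qc = ReplicateCorrelationQC()
        filtered = qc.fit_transform(matrix)
        report = qc.report_.to_dict()
        try:
            report["interexp_mean"] = interexperimental_reproducibility(filtered)
        except QCError:
            pass
        write_json({**_stamp(cfg), **report}, outdir / "qc.json")
        artifacts["qc"] = str(outdir / "qc.json")
        logger.info("QC: r_th=%.4f, removed %d replicates, %d samples",
                    qc.r_th_, len(qc.report_.removed_replicates),
                    len(qc.report_.removed_samples))

        stage = "evaluate"
        if cfg.cv.mode == "doublecv":
            result = double_cv(filtered, cfg.svm, outer_k=cfg.cv.outer_k,
                               inner_k=cfg.cv.inner_k, seed=cfg.seed)
        else:
            result = tune_20fold(filtered, cfg.svm, k=cfg.cv.k, seed=cfg.seed)
        write_json({**_stamp(cfg), **result.to_dict()}, outdir / "cv_report.json")
        result.to_frame().to_csv(outdir / "cv_report.csv", index=False)
        artifacts["cv_report"] = str(outdir / "cv_report.json")

        stage = "train"
        best = result.best_params
        svm_cfg = SVMConfig(gamma=best["gamma"], coef0=best["coef0"],
                            cost=best["cost"], scale=cfg.svm.scale)
        clf = train_svm(filtered, svm_cfg)
        model = PredictiveModel(
            classifier=clf, features=extractor.features_,
            reference_peaks=extractor.reference_peaks_, r_th=qc.r_th_,
            preprocess_params={k: getattr(cfg.preprocessing, k)
                               for k in ("sg_half_window", "sg_poly_order",
                                         "snip_iterations", "mz_min", "mz_max")},
            peak_params={k: getattr(cfg.peaks, k)
                         for k in ("snr_threshold", "tolerance_rel",
                                   "ref_min_freq", "feature_min_freq",
                                   "noise_window", "fill")},
            metadata={**_stamp(cfg), "tuned_params": best})
        model_path = outdir / "model.bundle"
        model.save(model_path)
        artifacts["model"] = str(model_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return artifacts
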