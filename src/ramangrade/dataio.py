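"""Dataset/basis file formats, run configuration and the end-to-end pipeline.

On-disk dataset format (plain delimited text):

* spectra file — CSV whose first column is ``wavenumber`` (strictly
  increasing, cm^-1) and every further column is one spectrum, headed by its
  spectrum ID; values stored to ten significant digits.
* metadata file — CSV with columns ``spectrum_id, mouse_id, strain, map_id,
  fibrosis_grade, pneumonitis_grade`` (extra columns round-trip untouched).

Basis libraries use the same spectra format with basis labels as headers.
A convenience shim imports instrument-style two-column (wavenumber,
intensity) text exports, one file per spectrum.

``run_pipeline`` ties the stages together: simulate (optional) ->
preprocess -> unmix + filter -> grade classification, writing scores, the
keep mask, confusion matrix, classification-rate report, coefficient map
and a parameter log.  One global seed expands deterministically into
per-stage seeds, so identical configs give identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .classify import SCHEME_LMH, SCHEME_ZLMH, BinningScheme, run_grading_experiment
from .preprocess import PreprocessConfig, SpectralDataset, preprocess_pipeline
from .synthetic import (GroundTruth, PeakSpec, SyntheticConfig, make_basis_library,
                        simulate_dataset)
from .unmixing import BasisSet, filter_spectra, fit_gbr_nmf, normalize_scores

logger = logging.getLogger("ramangrade.pipeline")

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_basis",
    "write_basis",
    "write_ground_truth",
    "read_ground_truth",
    "read_spectrum_files",
    "RunConfig",
    "load_config",
    "stage_seed",
    "run_pipeline",
]

METADATA_COLUMNS = ("spectrum_id", "mouse_id", "strain", "map_id",
                    "fibrosis_grade", "pneumonitis_grade")

_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A dataset file violates the on-disk schema."""


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_dataset(d: SpectralDataset, spectra_path: str | Path, metadata_path: str | Path) -> None:
    ids = d.metadata["spectrum_id"].astype(str)
    if ids.duplicated().any():
        raise SchemaError("duplicate spectrum_id values in metadata")
    frame = pd.DataFrame(d.matrix.T, columns=list(ids))
    frame.insert(0, "wavenumber", d.axis)
    frame.to_csv(spectra_path, index=False, float_format=_FLOAT_FMT)
    d.metadata.to_csv(metadata_path, index=False, float_format=_FLOAT_FMT)


def read_dataset(spectra_path: str | Path, metadata_path: str | Path) -> SpectralDataset:
    """Read a spectra/metadata file pair; schema violations name the file."""
    spectra_path, metadata_path = Path(spectra_path), Path(metadata_path)
    frame = pd.read_csv(spectra_path)
    if frame.columns[0] != "wavenumber":
        raise SchemaError(f"{spectra_path}: first column must be 'wavenumber', "
                          f"got {frame.columns[0]!r}")
    axis = frame["wavenumber"].to_numpy(dtype=float)
    if not (np.diff(axis) > 0).all():
        bad = int(np.flatnonzero(np.diff(axis) <= 0)[0]) + 2  # 1-based + header
        raise SchemaError(f"{spectra_path}: wavenumber column not strictly "
                          f"increasing at line {bad}")
    ids = [str(c) for c in frame.columns[1:]]
    if not ids:
        raise SchemaError(f"{spectra_path}: no spectrum columns")
    meta = pd.read_csv(metadata_path)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise SchemaError(f"{metadata_path}: missing columns {missing_cols}")
    meta["spectrum_id"] = meta["spectrum_id"].astype(str)
    meta_ids = set(meta["spectrum_id"])
    orphans = [s for s in ids if s not in meta_ids]
    if orphans:
        raise SchemaError(f"{metadata_path}: no metadata row for spectrum "
                          f"column(s) {orphans[:5]}")
    meta = meta.set_index("spectrum_id").loc[ids].reset_index()
    matrix = frame[ids].to_numpy(dtype=float).T
    return SpectralDataset(axis=axis, matrix=matrix, metadata=meta)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize simulation ground truth as a JSON sidecar (6 significant
    digits; baselines are the bulk of the payload)."""

    def r(arr):
        return [[float(f"{v:.6g}") for v in row] for row in np.atleast_2d(arr)]

    payload = {
        "basis_labels": list(truth.basis_labels),
        "weights": r(truth.weights),
        "baselines": r(truth.baselines),
        "grades": [float(g) for g in truth.grades],
        "shifts": [float(f"{s:.6g}") for s in truth.shifts],
        "collagen_component": r(truth.collagen_component)[0],
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        weights=np.asarray(data["weights"], dtype=float),
        basis_labels=tuple(data["basis_labels"]),
        baselines=np.asarray(data["baselines"], dtype=float),
        grades=np.asarray(data["grades"], dtype=float),
        shifts=np.asarray(data["shifts"], dtype=float),
        collagen_component=np.asarray(data["collagen_component"], dtype=float),
    )


def write_basis(basis: BasisSet, path: str | Path) -> None:
    frame = pd.DataFrame(basis.spectra.T, columns=list(basis.labels))
    frame.insert(0, "wavenumber", basis.axis)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_basis(path: str | Path) -> BasisSet:
    frame = pd.read_csv(path)
    if frame.columns[0] != "wavenumber":
        raise SchemaError(f"{path}: first column must be 'wavenumber'")
    axis = frame["wavenumber"].to_numpy(dtype=float)
    labels = tuple(str(c) for c in frame.columns[1:])
    if not labels:
        raise SchemaError(f"{path}: no basis columns")
    return BasisSet(labels=labels, spectra=frame[list(labels)].to_numpy(dtype=float).T, axis=axis)


def read_spectrum_files(paths: list[str | Path], delimiter: str | None = None) -> SpectralDataset:
    """Import shim for per-spectrum two-column (wavenumber, intensity) files.

    All files must share one wavenumber axis; metadata is stubbed with the
    file stem as spectrum ID and zero grades.
    """
    if not paths:
        raise SchemaError("no spectrum files given")
    axis = None
    rows, ids = [], []
    for p in paths:
        p = Path(p)
        arr = np.loadtxt(p, delimiter=delimiter)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise SchemaError(f"{p}: expected two columns (wavenumber, intensity)")
        if axis is None:
            axis = arr[:, 0]
        elif arr.shape[0] != axis.size or not np.allclose(arr[:, 0], axis):
            raise SchemaError(f"{p}: wavenumber axis differs from the first file")
        rows.append(arr[:, 1])
        ids.append(p.stem)
    meta = pd.DataFrame({
        "spectrum_id": ids, "mouse_id": "unknown", "strain": "unknown",
        "map_id": "unknown", "fibrosis_grade": 0.0, "pneumonitis_grade": 0.0,
    })
    return SpectralDataset(axis=np.asarray(axis), matrix=np.asarray(rows), metadata=meta)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: Mapping[str, Any], context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class UnmixingConfig:
    basis_path: str | None = None   # None = derive the library from the synthetic config
    tissue_min: float = 1.0
    media_max: float = 1.0
    free_rank: int = 0


@dataclass
class ClassifyConfig:
    response: str = "fibrosis"
    binning: str = "none"           # none | lmh | zlmh
    strain: str | None = None
    train_frac: float | None = 0.7
    folds: int = 10
    n_lambdas: int = 100

    def scheme(self) -> BinningScheme | None:
        if self.binning == "none":
            return None
        if self.binning == "lmh":
            return SCHEME_LMH
        if self.binning == "zlmh":
            return SCHEME_ZLMH
        raise ValueError(f"unknown binning {self.binning!r} (use none|lmh|zlmh)")


@dataclass
class RunConfig:
    """Nested run configuration; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "ramangrade_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    unmixing: UnmixingConfig = field(default_factory=UnmixingConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    #: paths of an existing dataset; None = simulate from ``synthetic``
    spectra_path: str | None = None
    metadata_path: str | None = None

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict[str, Any] = {}
        if "synthetic" in data:
            syn = dict(data.pop("synthetic"))
            for key in ("tissue_peaks", "media_peaks", "collagen_peaks"):
                if key in syn:
                    syn[key] = tuple(PeakSpec(*pk) if not isinstance(pk, PeakSpec) else pk
                                     for pk in syn[key])
            for key in ("points_per_map", "media_mix_fraction_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            kw["synthetic"] = _from_mapping(SyntheticConfig, syn, "synthetic")
        if "preprocess" in data:
            kw["preprocess"] = _from_mapping(PreprocessConfig, data.pop("preprocess"), "preprocess")
        if "unmixing" in data:
            kw["unmixing"] = _from_mapping(UnmixingConfig, data.pop("unmixing"), "unmixing")
        if "classify" in data:
            kw["classify"] = _from_mapping(ClassifyConfig, data.pop("classify"), "classify")
        kw.update(data)
        return cls(**kw)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_mapping(data)


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed derived from the global seed.

    Child *stage* of ``np.random.SeedSequence(seed)``, reduced below 2^31 so
    it is valid anywhere a small integer seed is expected.
    """
    child = np.random.SeedSequence(seed).spawn(stage + 1)[stage]
    return int(child.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    outdir: Path
    retention: float
    rate: float
    artifacts: dict[str, Path]
    report: dict


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute simulate (optional) -> preprocess -> unmix/filter -> classify.

    Writes all artifacts under ``config.outdir`` and returns their manifest
    together with the headline numbers.  Identical config and seed give
    byte-identical report JSON.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ramangrade")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, Path] = {"log": log_path}
    try:
        if config.spectra_path is not None:
            if config.metadata_path is None:
                raise ValueError("spectra_path given without metadata_path")
            dataset = read_dataset(config.spectra_path, config.metadata_path)
            logger.info("loaded dataset: %d spectra x %d channels",
                        dataset.n_spectra, dataset.n_channels)
        else:
            syn = config.synthetic.replace(seed=stage_seed(config.seed, 0))
            logger.info("simulate: %s", syn)
            dataset, truth = simulate_dataset(syn)
            spath, mpath = outdir / "spectra.csv", outdir / "metadata.csv"
            write_dataset(dataset, spath, mpath)
            tpath = outdir / "ground_truth.json"
            write_ground_truth(truth, tpath)
            artifacts["spectra"] = spath
            artifacts["metadata"] = mpath
            artifacts["ground_truth"] = tpath

        logger.info("preprocess: %s", config.preprocess)
        processed = preprocess_pipeline(dataset, config.preprocess)

        if config.unmixing.basis_path is not None:
            basis = read_basis(config.unmixing.basis_path)
        else:
            basis = make_basis_library(config.synthetic)
        if basis.axis.size != processed.axis.size or not np.allclose(basis.axis, processed.axis):
            # bases are defined on the uncropped axis; restrict to the window
            from .preprocess import Spectrum, auc_normalize, interpolate_to_axis
            rows = [auc_normalize(interpolate_to_axis(Spectrum(basis.axis, row),
                                                      processed.axis)).intensities
                    for row in basis.spectra]
            basis = BasisSet(labels=basis.labels, spectra=np.asarray(rows), axis=processed.axis)
        scores = normalize_scores(fit_gbr_nmf(processed.matrix, basis,
                                              free_rank=config.unmixing.free_rank,
                                              seed=stage_seed(config.seed, 1)))
        filt = filter_spectra(scores, config.unmixing.tissue_min, config.unmixing.media_max)
        logger.info("retention: %r", filt.retention)

        score_table = processed.metadata[["spectrum_id"]].copy()
        for j, lab in enumerate(scores.labels):
            score_table[f"raw_{lab}"] = scores.raw[:, j]
            score_table[f"norm_{lab}"] = scores.normalized[:, j]
        score_table["kept"] = filt.keep_mask
        scores_path = outdir / "scores.csv"
        score_table.to_csv(scores_path, index=False, float_format=_FLOAT_FMT)
        artifacts["scores"] = scores_path

        kept = processed.subset(filt.keep_mask)
        ccfg = config.classify
        report_obj = run_grading_experiment(
            kept, response=ccfg.response, scheme=ccfg.scheme(), strain=ccfg.strain,
            train_frac=ccfg.train_frac, seed=stage_seed(config.seed, 2),
            folds=ccfg.folds, n_lambdas=ccfg.n_lambdas)

        cm_path = outdir / "confusion_matrix.csv"
        report_obj.matrix.to_frame().to_csv(cm_path)
        artifacts["confusion_matrix"] = cm_path

        coef_path = outdir / "coefficient_map.csv"
        cmap = _classify.coefficient_map(report_obj.model, kept.axis)
        cmap[cmap["sign"] != "white"].to_csv(coef_path, index=False, float_format=_FLOAT_FMT)
        artifacts["coefficient_map"] = coef_path

        per_class = {}
        counts = report_obj.matrix.counts
        for i, lab in enumerate(report_obj.matrix.labels):
            row = counts[i].sum()
            per_class[str(lab)] = {
                "n_true": int(row),
                "recall": float(counts[i, i] / row) if row else None,
            }
        report = {
            "seed": config.seed,
            "n_spectra": dataset.n_spectra,
            "n_kept": kept.n_spectra,
            "retention": filt.retention,
            "classification_rate": report_obj.rate,
            "evaluation": report_obj.evaluation,
            "response": report_obj.response,
            "binning": report_obj.scheme,
            "strain": report_obj.strain,
            "lambda_min": report_obj.cv.lambda_min,
            "lambda_1se": report_obj.cv.lambda_1se,
            "n_nonzero_coefficients": report_obj.model.n_nonzero,
            "per_class": per_class,
            "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        artifacts["report"] = report_path
        logger.info("pipeline complete: CR=%.4f retention=%.4f", report_obj.rate, filt.retention)
        return PipelineResult(outdir=outdir, retention=filt.retention,
                              rate=report_obj.rate, artifacts=artifacts, report=report)
    finally:
        root.removeHandler(handler)
        handler.close()
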