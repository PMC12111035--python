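"""Workflow orchestration: simulate -> calibrate -> select -> recalibrate ->
validate, with YAML/JSON config and reproducible artifacts.

Each stage writes its reports (JSON + CSV) plus a manifest recording the
config and seeds, so every artifact is regenerable bit-identically. The CLI
module is a thin shell over these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import selection as _selection
from . import synthetic as _synthetic
from .model import ModelReport, evaluate_model, fit_svr
from .soa import tune_svr
from .spectra import (
    SpectraSet,
    SplitPlan,
    StandardizerParams,
    fit_standardizer_arrays,
    make_split,
    read_spectra_csv,
    write_spectra_csv,
)
from .stats import TwoSampleTestReport, two_sample_report

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "load_config",
    "run_simulate",
    "run_calibrate",
    "run_select",
    "run_validate",
    "CalibrationArtifacts",
]

logger = logging.getLogger(__name__)

# distinct exit codes per failing stage (CLI contract)
STAGE_EXIT_CODES = {
    "config": 2,
    "data": 3,
    "calibrate": 4,
    "select": 5,
    "validate": 6,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class PipelineConfig:
    """Declarative description of one end-to-end run."""

    input_csv: str | None = None
    reference_column: str | None = None
    synthetic_preset: str | None = "sv_like"
    n_samples: int = 200
    property_label: str = "SV"
    split_fraction: float = 0.8
    split_seed: int = 0
    soa_population: int = 30
    soa_iterations: int = 50
    soa_seed: int = 0
    cv_folds: int = 5
    cv_seed: int = 0
    kernel: str = "rbf"
    selection_strategy: str = "iwoa_spa"
    selection_k: int = 20
    selection_pool: int | None = None
    selection_seed: int = 0
    validation_n: int = 50
    data_seed: int = 0
    output_dir: str = "flourspec_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise PipelineError("config", "split_fraction must lie in (0,1)")
        if self.selection_k < 1:
            raise PipelineError("config", "selection_k must be >= 1")
        if self.input_csv is None and self.synthetic_preset is None:
            raise PipelineError("config", "need input_csv or synthetic_preset")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise PipelineError("config", f"input file not found: {self.input_csv}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON — valid YAML) config file."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except OSError as exc:
        raise PipelineError("config", str(exc)) from exc
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _write(outdir: Path, name: str, text: str) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / name
    p.write_text(text)
    return p


def _manifest(outdir: Path, config: PipelineConfig, stage: str, extra: dict) -> None:
    payload = {"stage": stage, "config": config.to_dict()}
    payload.update(extra)
    _write(outdir, f"manifest_{stage}.json", json.dumps(payload, indent=2))


def _load_data(config: PipelineConfig) -> SpectraSet:
    if config.input_csv is not None:
        try:
            return read_spectra_csv(config.input_csv, config.reference_column)
        except Exception as exc:
            raise PipelineError("data", str(exc)) from exc
    syn = _synthetic.SyntheticConfig.preset(
        config.synthetic_preset, n_samples=config.n_samples, seed=config.data_seed
    )
    spectra, _ = _synthetic.generate(syn)
    return spectra


def run_simulate(config: PipelineConfig) -> Path:
    """Generate a synthetic spectra CSV plus its ground truth JSON."""
    outdir = Path(config.output_dir)
    syn = _synthetic.SyntheticConfig.preset(
        config.synthetic_preset or "sv_like",
        n_samples=config.n_samples,
        seed=config.data_seed,
    )
    spectra, truth = _synthetic.generate(syn)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "synthetic_spectra.csv"
    write_spectra_csv(spectra, csv_path)
    _write(outdir, "synthetic_truth.json", truth.to_json())
    _manifest(outdir, config, "simulate", {"csv": str(csv_path)})
    return csv_path


@dataclass
class CalibrationArtifacts:
    """Everything later stages need from a calibration run."""

    report: ModelReport
    spectra: SpectraSet
    split: SplitPlan
    standardizer: StandardizerParams
    subset: _selection.WavelengthSubset | None = None
    model: object = None


def _prepare(config: PipelineConfig):
    spectra = _load_data(config)
    if spectra.reference is None:
        raise PipelineError("data", "dataset has no reference values")
    plan = make_split(spectra.n_samples, config.split_fraction, config.split_seed)
    Xtr = spectra.absorbance[plan.train_indices]
    ytr = spectra.reference[plan.train_indices]
    std = fit_standardizer_arrays(Xtr, ytr)
    return spectra, plan, std


def run_calibrate(
    config: PipelineConfig,
    subset: _selection.WavelengthSubset | None = None,
) -> CalibrationArtifacts:
    """Split -> standardize -> SOA hyperparameter search -> final fit ->
    evaluate; writes the calibration-table row (CSV + JSON) and the SOA
    convergence trace."""
    try:
        spectra, plan, std = _prepare(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("data", str(exc)) from exc
    try:
        cols = subset.indices if subset is not None else np.arange(spectra.n_wavelengths)
        Xtr = std.transform(spectra.absorbance[plan.train_indices])[:, cols]
        Xte = std.transform(spectra.absorbance[plan.prediction_indices])[:, cols]
        ytr = std.transform_target(spectra.reference[plan.train_indices])
        yte = std.transform_target(spectra.reference[plan.prediction_indices])

        h, opt = tune_svr(
            Xtr,
            ytr,
            population=config.soa_population,
            iterations=config.soa_iterations,
            seed=config.soa_seed,
            folds=config.cv_folds,
            cv_seed=config.cv_seed,
            kernel=config.kernel,
        )
        report = evaluate_model(
            Xtr, ytr, Xte, yte, h,
            kernel=config.kernel, folds=config.cv_folds, seed=config.cv_seed,
            standardizer=std,
        )
        model = fit_svr(Xtr, ytr, h, kernel=config.kernel)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("calibrate", str(exc)) from exc

    outdir = Path(config.output_dir)
    tag = "selected" if subset is not None else "full"
    _write(outdir, f"calibration_{tag}.json", report.to_json())
    _write(outdir, f"calibration_{tag}.csv", report.to_csv_row(label="SOA-SVR"))
    _write(outdir, f"soa_trace_{tag}.csv", opt.trace_csv())
    _write(outdir, f"split_{tag}.json", plan.to_json())
    _write(outdir, f"standardizer_{tag}.json", std.to_json())
    _manifest(outdir, config, f"calibrate_{tag}", {"best_fitness": opt.best_fitness})
    return CalibrationArtifacts(report, spectra, plan, std, subset, model)


def run_select(config: PipelineConfig) -> _selection.WavelengthSubset:
    """Run the configured MIW strategy on the training side and write the
    selection-table row plus index JSON."""
    try:
        spectra, plan, std = _prepare(config)
        Xtr_raw = spectra.absorbance[plan.train_indices]
        X = std.transform(Xtr_raw)
        y = std.transform_target(spectra.reference[plan.train_indices])
        Xc = Xtr_raw - Xtr_raw.mean(axis=0)  # SPA stage works on centered raw
        swarm = _selection.BinarySwarmConfig(seed=config.selection_seed)
        strategy = config.selection_strategy
        if strategy in ("iwoa_spa", "rfe_iwoa"):
            subset = _selection.joint_select(
                strategy, X, y, config.selection_k,
                pool_size=config.selection_pool,
                config=swarm, wavelengths=spectra.wavelengths_nm, X_spa=Xc,
            )
        elif strategy == "pca":
            subset = _selection.pca_select(
                X, config.selection_k, wavelengths=spectra.wavelengths_nm
            )
        elif strategy == "spa":
            subset = _selection.spa_select(
                Xc, config.selection_k, start_index="auto", y=y,
                wavelengths=spectra.wavelengths_nm,
            )
        elif strategy == "rfe":
            subset = _selection.rfe_select(
                X, y, config.selection_k, wavelengths=spectra.wavelengths_nm
            )
        elif strategy == "iwoa":
            subset = _selection.iwoa_select(
                X, y, config.selection_k, config=swarm,
                wavelengths=spectra.wavelengths_nm,
            )
        else:
            raise PipelineError("config", f"unknown strategy {strategy!r}")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("select", str(exc)) from exc

    outdir = Path(config.output_dir)
    header = "method,wavelengths,reduction\n"
    _write(outdir, f"subset_{subset.method}.csv", header + subset.to_csv_row())
    _write(outdir, f"subset_{subset.method}.json", subset.to_json())
    _manifest(outdir, config, "select", {"k": subset.k, "reduction": subset.reduction})
    logger.info(
        "selected %d/%d wavelengths (%.2f%% reduction)",
        subset.k, subset.n_total, subset.reduction,
    )
    return subset


def run_validate(
    config: PipelineConfig,
    artifacts: CalibrationArtifacts,
    holdout: SpectraSet,
    alpha: float = 0.05,
) -> tuple[TwoSampleTestReport, float]:
    """Predict an independent holdout, emit the two-sample report block and
    the fraction of samples with |relative bias| < 10%."""
    try:
        if holdout.reference is None:
            raise PipelineError("data", "holdout has no reference values")
        cols = (
            artifacts.subset.indices
            if artifacts.subset is not None
            else np.arange(holdout.n_wavelengths)
        )
        X = artifacts.standardizer.transform(holdout.absorbance)[:, cols]
        pred_std = artifacts.model.predict(X)
        predicted = artifacts.standardizer.inverse_transform_target(pred_std)
        measured = holdout.reference
        report = two_sample_report(measured, predicted, alpha=alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_bias = np.abs((predicted - measured) / measured)
        bias_fraction = float(np.mean(rel_bias < 0.10))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("validate", str(exc)) from exc

    outdir = Path(config.output_dir)
    _write(outdir, "validation_report.json", report.to_json())
    _write(outdir, "validation_report.txt", report.render_table())
    _manifest(outdir, config, "validate", {"bias_fraction_lt_10pct": bias_fraction})
    return report, bias_fraction
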