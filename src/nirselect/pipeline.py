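"""End-to-end SSC calibration workflow.

Stage order mirrors the measurement campaign: acquire (simulate or load) ->
truncate/average multi-frame scans -> absorbance conversion -> Monte-Carlo
outlier removal -> 3:1 calibration/prediction split -> preprocessing (fitted on
the calibration set, applied to both) -> full-spectrum PLSR -> binning ->
BVS-PLS -> simulated annealing -> final reduced-variable PLSR -> report.

All data-dependent statistics (MSC reference, centering means, outlier flags in
"strict" mode, wavelength selection) are computed on calibration samples only,
so the prediction set remains untouched until evaluation. Every random stage
draws a named seed derived deterministically from one master seed; reports
contain no timestamps, so identical configs reproduce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import outliers as outliers_mod
from . import pls, preprocess, selection, simulate
from .containers import (ReferenceTable, SpectrumSet, read_reference_csv,
                         read_spectra_csv, to_absorbance)

__all__ = [
    "PipelineConfig",
    "OutlierConfig",
    "SelectionConfig",
    "RunReport",
    "run",
    "compare_orientations",
    "derive_seed",
    "load_config",
    "config_from_dict",
]

log = logging.getLogger("nirselect")

VERSION = "0.1.0"


def derive_seed(master: int, name: str) -> int:
    """Independent named child seed (< 2**31) from one master seed."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class OutlierConfig:
    enabled: bool = True
    n_runs: int = 500
    validation_fraction: float = 0.25
    k_sigma: float = 2.5
    max_lv: int = 15
    inner_cv: str = "kfold:5"
    mode: str = "pre_split"  # remove from all samples ("pre_split") or calibration only


@dataclass
class SelectionConfig:
    enabled: bool = True
    bin_width: int = 16
    k: int = 20
    cv: str = "loo"
    max_lv: int = 20
    min_groups: int | None = None  # None -> max(k, half the bins)
    fast_lv: bool = False
    sa_L: int = 500
    sa_cooling_rule: str = "adaptive_decrement"
    sa_alpha: float = 0.95
    sa_decrement_fraction: float = 0.005


@dataclass
class PipelineConfig:
    """One document describing a full run; exactly one data source must be set."""

    simulate: simulate.SimulationConfig | None = None
    spectra_csv: str | None = None
    reference_csv: str | None = None
    absorbance: bool = True
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    split_ratio: str = "3:1"
    outlier: OutlierConfig = field(default_factory=OutlierConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    plsr_max_lv: int = 20
    plsr_cv: str = "loo"
    master_seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        has_sim = self.simulate is not None
        has_files = self.spectra_csv is not None and self.reference_csv is not None
        if has_sim == has_files:
            raise ValueError(
                "exactly one of a simulate block or spectra_csv+reference_csv is required"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("preprocess", {}).get("msc_reference") is not None:
            d["preprocess"]["msc_reference"] = "explicit"
        return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    if d.get("simulate") is not None:
        d["simulate"] = simulate.SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in d["simulate"].items()})
    if "preprocess" in d and isinstance(d["preprocess"], dict):
        d["preprocess"] = preprocess.PreprocessConfig(**d["preprocess"])
    if "outlier" in d and isinstance(d["outlier"], dict):
        d["outlier"] = OutlierConfig(**d["outlier"])
    if "selection" in d and isinstance(d["selection"], dict):
        d["selection"] = SelectionConfig(**d["selection"])
    return PipelineConfig(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON pipeline config document."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_dict(data)


@dataclass
class RunReport:
    """Everything the run computed, recomputable from the serialized intermediates."""

    tables: list[dict]  # rows: model, n_variables, n_lv, Rc, RMSEC, Rp, RMSEP
    selected_wavelengths: dict | None
    outliers_removed: list[str]
    seeds: dict
    config: dict
    version: str = VERSION
    artifacts: dict = field(default_factory=dict, repr=False)  # in-memory only

    def to_json_dict(self) -> dict:
        return {
            "version": self.version,
            "tables": self.tables,
            "selected_wavelengths": self.selected_wavelengths,
            "outliers_removed": self.outliers_removed,
            "seeds": self.seeds,
            "config": self.config,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_json_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def format_table(self) -> str:
        return pls.format_metrics_table(self.tables)


def _metrics_row(name, n_vars, n_lv, cal_m, pred_m) -> dict:
    return {
        "model": name,
        "n_variables": int(n_vars),
        "n_lv": int(n_lv),
        "Rc": round(float(cal_m.r), 6),
        "RMSEC": round(float(cal_m.rmse), 6),
        "Rp": round(float(pred_m.r), 6),
        "RMSEP": round(float(pred_m.rmse), 6),
    }


def _fit_and_score(name, X_cal, y_cal, X_pred, y_pred, max_lv, cv, cv_seed=0):
    cap = min(max_lv, pls.max_allowed_lv(X_cal.shape[0], X_cal.shape[1], cv))
    cvres = pls.rmsecv(X_cal, y_cal, cap, cv=cv, seed=cv_seed)
    model = pls.fit(X_cal, y_cal, cvres.chosen_lv)
    cal_m = pls.evaluate(y_cal, pls.predict(model, X_cal))
    pred_m = pls.evaluate(y_pred, pls.predict(model, X_pred))
    row = _metrics_row(name, X_cal.shape[1], cvres.chosen_lv, cal_m, pred_m)
    return row, model, cvres


def _acquire(config: PipelineConfig, out_dir: Path | None):
    artifacts: dict = {}
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate)
        if sim.frames_per_sample > 1:
            stack, ref, gt = simulate.generate_multiframe(sim)
            sset = preprocess.collapse_frames(stack, config.preprocess.truncate_factor)
            artifacts["frames"] = stack
        else:
            sset, ref, gt = simulate.generate(sim)
        artifacts["ground_truth"] = gt
        if out_dir is not None:
            simulate.write_dataset(out_dir, sset, ref, gt)
    else:
        sset = read_spectra_csv(config.spectra_csv)
        ref = read_reference_csv(config.reference_csv)
    return sset, ref, artifacts


def run(config: PipelineConfig, out_dir: str | Path | None = None,
        stages: tuple = ("outliers", "model", "select")) -> RunReport:
    """Execute the enabled pipeline stages and assemble a RunReport.

    ``stages`` can be reduced (e.g. ``()`` for simulate-only). Intermediates and
    the report are written under ``out_dir`` when given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = {name: derive_seed(config.master_seed, name)
             for name in ("split", "outliers", "sa", "cv")}
    stage = "acquire"
    try:
        sset, ref, artifacts = _acquire(config, out)
        tables: list[dict] = []
        removed: list[str] = []
        selected_info = None

        if not stages:
            return RunReport([], None, [], seeds, config.to_dict(), VERSION, artifacts)

        stage = "absorbance"
        work = to_absorbance(sset) if config.absorbance else sset

        stage = "outliers"
        if "outliers" in stages and config.outlier.enabled and config.outlier.mode == "pre_split":
            rep = outliers_mod.mc_scan(
                work.intensities, ref.aligned_to(work),
                n_runs=config.outlier.n_runs,
                validation_fraction=config.outlier.validation_fraction,
                max_lv=config.outlier.max_lv, seed=seeds["outliers"],
                inner_cv=config.outlier.inner_cv, sample_ids=work.sample_ids,
                k_sigma=config.outlier.k_sigma)
            removed = rep.flagged_ids
            work, ref = outliers_mod.remove(work, ref, removed)
            artifacts["outlier_report"] = rep
            if out is not None:
                (out / "outlier_report.json").write_text(json.dumps(rep.to_json_dict(), indent=1))
                rep.to_frame().to_csv(out / "outlier_stats.csv", index=False)
            log.info("outlier scan removed %d samples: %s", len(removed), removed)

        stage = "split"
        cal, cal_ref, pred, pred_ref = pls.split_calibration_prediction(
            work, ref, config.split_ratio, seeds["split"])

        stage = "outliers"
        if "outliers" in stages and config.outlier.enabled and config.outlier.mode == "post_split":
            rep = outliers_mod.mc_scan(
                cal.intensities, cal_ref.ssc, n_runs=config.outlier.n_runs,
                validation_fraction=config.outlier.validation_fraction,
                max_lv=config.outlier.max_lv, seed=seeds["outliers"],
                inner_cv=config.outlier.inner_cv, sample_ids=cal.sample_ids,
                k_sigma=config.outlier.k_sigma)
            removed = rep.flagged_ids
            cal, cal_ref = outliers_mod.remove(cal, cal_ref, removed)
            artifacts["outlier_report"] = rep

        stage = "preprocess"
        pp = dataclasses.replace(config.preprocess)
        cal_pp = preprocess.apply(cal, pp)
        reference = preprocess.fit_reference(cal, pp)
        if reference is not None:
            pp = dataclasses.replace(pp, msc_reference=reference)
        pred_pp = preprocess.apply(pred, pp)
        artifacts.update(calibration=cal_pp, prediction=pred_pp,
                         calibration_ref=cal_ref, prediction_ref=pred_ref)

        y_cal, y_pred = cal_ref.ssc, pred_ref.ssc

        stage = "model"
        if "model" in stages:
            row, model, cvres = _fit_and_score(
                "full_spectrum", cal_pp.intensities, y_cal, pred_pp.intensities,
                y_pred, config.plsr_max_lv, config.plsr_cv, seeds["cv"])
            tables.append(row)
            artifacts["full_model"] = model
            if out is not None:
                (out / "full_model.json").write_text(json.dumps(model.to_dict()))

        stage = "select"
        if "select" in stages and config.selection.enabled:
            sc = config.selection
            sa_cfg = selection.AnnealingConfig(
                k=sc.k, cooling_rule=sc.sa_cooling_rule, alpha=sc.sa_alpha,
                decrement_fraction=sc.sa_decrement_fraction, L=sc.sa_L,
                seed=seeds["sa"])
            combined = selection.combined_select(
                cal_pp, y_cal, sc.bin_width, sc.k, sa_config=sa_cfg, cv=sc.cv,
                max_lv=sc.max_lv, min_groups=sc.min_groups, fast_lv=sc.fast_lv,
                cv_seed=seeds["cv"])
            artifacts["combined"] = combined
            cal_binned = selection.bin_matrix(cal_pp.intensities, sc.bin_width)
            pred_binned = selection.bin_matrix(pred_pp.intensities, sc.bin_width)
            bins = combined.selected_bins
            row, model, _ = _fit_and_score(
                f"selected_{bins.size}bins", cal_binned[:, bins], y_cal,
                pred_binned[:, bins], y_pred, config.plsr_max_lv, config.plsr_cv,
                seeds["cv"])
            tables.append(row)
            artifacts["selected_model"] = model
            selected_info = combined.to_json_dict()
            del selected_info["bvs"]["provenance"]
            if out is not None:
                (out / "selection.json").write_text(
                    json.dumps(combined.to_json_dict(), indent=1))
                trace = combined.bvs.rmsecv_trace
                (out / "bvs_trace.csv").write_text(
                    "iteration,rmsecv\n" +
                    "\n".join(f"{i},{v:.6f}" for i, v in enumerate(trace)))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    report = RunReport(tables, selected_info, removed, seeds, config.to_dict(),
                       VERSION, artifacts)
    if out is not None:
        report.to_json(out / "report.json")
        (out / "report.txt").write_text(report.format_table() + "\n")
        if config.plots:
            from . import plots
            plots.run_diagnostics(report, out)
    return report


def compare_orientations(config: PipelineConfig, path_factors: tuple[float, float],
                         noise_sds: tuple[float, float] | None = None,
                         out_dir: str | Path | None = None) -> dict:
    """Run matched pipelines for two acquisition orientations (Z1 vs Z2).

    The two runs share every seed and differ only in the orientation-dependent
    path-length factor (optionally also the noise level). Returns a paired
    table in the orientation | LVs | Rc | RMSEC | Rp | RMSEP layout.
    """
    if config.simulate is None:
        raise ValueError("compare_orientations requires a simulate block")
    reports = {}
    for name, pf, idx in (("Z1", path_factors[0], 0), ("Z2", path_factors[1], 1)):
        sim = dataclasses.replace(config.simulate, path_factor=pf)
        if noise_sds is not None:
            sim = dataclasses.replace(sim, noise_sd=noise_sds[idx])
        cfg = dataclasses.replace(config, simulate=sim)
        sub = Path(out_dir) / name if out_dir is not None else None
        reports[name] = run(cfg, sub, stages=("model",))
    grids = [tuple(r.config["simulate"][k] for k in ("n_wavelengths", "wl_min", "wl_max"))
             for r in reports.values()]
    if grids[0] != grids[1]:
        raise ValueError("orientation runs have mismatched wavelength grids")
    rows = []
    for name, rep in reports.items():
        row = dict(rep.tables[0])
        row["model"] = name
        rows.append(row)
    paired = {"table": rows, "reports": reports}
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "orientations.json").write_text(
            json.dumps({"table": rows}, indent=1, sort_keys=True))
    return paired
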