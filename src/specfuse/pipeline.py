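"""Config-driven orchestration and standard report suites.

``run_pipeline`` executes one full recipe (split -> preprocess -> select
-> train -> fuse -> evaluate) from a YAML-serializable config and writes a
self-describing run directory: the verbatim config, the evaluation report
(deterministically serialized), selection and scatter-correction
artifacts, and a JSON-lines log of stage timings and derived seeds.

``benchmark_suite`` emits the four standard comparison tables for a
dataset: full-spectrum models, selector-PLSR models, and the two fusion
topologies under all five combiners.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .calibration import FUSIONS, REGRESSORS, SSCCalibration
from .crossval import MCCVConfig, derive_seed
from .evaluation import SplitSpec, compare_report, evaluate, split_dataset
from .fusion import COMBINERS, build_cncmf, build_mcmf
from .io import SpectralDataset, read_spectra_table, trim_wavelengths
from .preprocess import PREPROCESSORS, apply_preprocessing
from .regressors import fit_plsr
from .selection import SELECTORS, SelectionConfig
from .simulate import scenario, simulate

__all__ = ["PipelineConfig", "run_pipeline", "benchmark_suite"]


@dataclass
class PipelineConfig:
    """One experiment recipe; every stochastic stage seeds from ``seed``."""

    input: str | None = None           # spectral table path, or None
    scenario: str | None = "both"      # synthetic scenario if no input
    n_samples: int = 105
    window: tuple | None = None        # (lo, hi) nm, closed interval
    preprocess: str = "ss"
    selector: str | None = None
    model: str = "plsr"
    fusion: str | None = None
    combiner: str = "sa"
    split_ratio: tuple = (3, 1)
    split_rounding: str = "nearest"
    max_lvs: int = 15
    selector_runs: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.input is None and self.scenario is None:
            raise ValueError("config needs an input path or a scenario name")
        if self.preprocess not in PREPROCESSORS:
            raise ValueError(f"unknown preprocess {self.preprocess!r}")
        if self.selector is not None and self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.model not in REGRESSORS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.fusion is not None and self.fusion not in FUSIONS:
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("window", "split_ratio"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["window"] = None if self.window is None else list(self.window)
        d["split_ratio"] = list(self.split_ratio)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _load_dataset(cfg: PipelineConfig) -> SpectralDataset:
    if cfg.input is not None:
        ds = read_spectra_table(cfg.input)
    else:
        params = scenario(cfg.scenario, seed=derive_seed(cfg.seed, "simulate"),
                          n_samples=cfg.n_samples)
        ds, _ = simulate(params)
    if cfg.window is not None:
        ds = trim_wavelengths(ds, *cfg.window)
    return ds


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Execute the configured recipe; returns the run directory.

    The directory contains ``config.yaml`` (verbatim), ``report.json``
    (sorted keys, deterministic bytes given the config), optional
    ``selection.json`` / ``ss_model.json``, and ``log.jsonl`` with stage
    timings and derived seeds. Stage failures are re-raised with the stage
    name after the partial log is flushed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    log_path = outdir / "log.jsonl"
    log_entries = []

    def log(stage, **info):
        log_entries.append({"stage": stage, **info})
        with open(log_path, "w") as fh:
            for e in log_entries:
                fh.write(json.dumps(e, sort_keys=True) + "\n")

    stage = "load"
    try:
        t0 = time.perf_counter()
        ds = _load_dataset(cfg)
        log(stage, seconds=round(time.perf_counter() - t0, 3),
            n_samples=ds.n_samples, n_wavelengths=ds.n_wavelengths)
        stage = "fit"
        t0 = time.perf_counter()
        sel_cfg = SelectionConfig(n_runs=cfg.selector_runs,
                                  seed=derive_seed(cfg.seed, "selection"))
        model = SSCCalibration(
            ds, preprocess=cfg.preprocess, selector=cfg.selector,
            regressor=cfg.model, fusion=cfg.fusion, combiner=cfg.combiner,
            split=SplitSpec(ratio=cfg.split_ratio, rounding=cfg.split_rounding,
                            seed=derive_seed(cfg.seed, "split")),
            max_lvs=cfg.max_lvs, selection_config=sel_cfg, seed=cfg.seed)
        results = model.fit()
        log(stage, seconds=round(time.perf_counter() - t0, 3),
            seed=cfg.seed, derived={"split": derive_seed(cfg.seed, "split"),
                                    "selection": derive_seed(cfg.seed, "selection")})
        stage = "write"
        with open(outdir / "report.json", "w") as fh:
            json.dump(results.to_dict(), fh, sort_keys=True, indent=1)
        if results.selection is not None:
            results.selection.to_json(outdir / "selection.json",
                                      wavelengths=ds.wavelengths)
        if results.preprocess_state is not None and cfg.preprocess == "ss":
            results.preprocess_state.to_json(outdir / "ss_model.json")
        log(stage, report="report.json")
    except Exception as exc:
        log("error", failed_stage=stage, error=str(exc))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir


def benchmark_suite(ds: SpectralDataset, seed: int = 0,
                    split: SplitSpec | None = None, max_lvs: int = 15,
                    selector_runs: dict | None = None,
                    mccv_repeats: int = 50, combiners=COMBINERS):
    """The four standard comparison tables for one dataset.

    Returns a dict of DataFrames with columns
    ``model, factor, Rc, RMSEC, Rp, RMSEP, RPD``:

    * ``full_spectrum`` — PLSR / LS-SVR / PSO-ELM on scatter-corrected
      (spectra-to-spectra) full spectra;
    * ``selection`` — PLSR on the CARS / BOSS / iVISSA selections;
    * ``mcmf`` and ``cncmf`` — the fusion topologies under each combiner.

    ``selector_runs`` maps selector names to Monte-Carlo run counts for
    desk-scale use; values are data-dependent, the table structure fixed.
    """
    if ds.y is None:
        raise ValueError("dataset must carry reference values")
    split = split or SplitSpec(seed=derive_seed(seed, "split"))
    ds_cal, ds_pred = split_dataset(ds, split)
    mccv = MCCVConfig(n_repeats=mccv_repeats, seed=derive_seed(seed, "ss"))
    cal, pred, _ = apply_preprocessing("ss", ds_cal, ds_pred, mccv=mccv,
                                       max_lvs=max_lvs)
    selector_runs = selector_runs or {}
    reports_full = []
    for reg in REGRESSORS:
        model = SSCCalibration(ds, preprocess="ss", regressor=reg, split=split,
                               max_lvs=max_lvs, seed=seed)
        reports_full.append(model.fit().report)
    sel_results = {}
    reports_sel = []
    for key, name in (("CARS", "cars"), ("BOSS", "boss"), ("iVISSA", "ivissa")):
        cfg = SelectionConfig(n_runs=selector_runs.get(name),
                              seed=derive_seed(seed, f"sel-{name}"))
        res = SELECTORS[name](cal.X, cal.y, cfg)
        sel_results[key] = res
        plsr = fit_plsr(cal.X[:, res.selected], cal.y, max_lvs=max_lvs,
                        mccv=MCCVConfig(seed=derive_seed(seed, f"lv-{name}")))
        rep = evaluate(cal.y, plsr.predict(cal.X[:, res.selected]),
                       pred.y, plsr.predict(pred.X[:, res.selected]),
                       model=f"S/S-{key}-PLSR", factor=f"LVs: {plsr.n_lvs}")
        rep.extra["n_wavelengths"] = int(res.selected.size)
        reports_sel.append(rep)
    tables = {
        "full_spectrum": compare_report(reports_full),
        "selection": compare_report(reports_sel),
    }
    for topology in ("mcmf", "cncmf"):
        reports = []
        for comb in combiners:
            if topology == "mcmf":
                fm, preds = build_mcmf(cal, pred, sel_results, combiner=comb,
                                       seed=derive_seed(seed, f"mcmf-{comb}"),
                                       max_lvs=max_lvs)
            else:
                fm, preds = build_cncmf(cal, pred, sel_results["CARS"],
                                        combiner=comb,
                                        seed=derive_seed(seed, f"cncmf-{comb}"),
                                        max_lvs=max_lvs)
            reports.append(evaluate(cal.y, fm.predict(cal.X), pred.y, preds,
                                    model=f"{topology.upper()}-{comb.upper()}",
                                    factor=fm.factor_string()))
        tables[topology] = compare_report(reports)
    return tables
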