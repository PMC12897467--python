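"""End-to-end orchestration: cohort -> panels -> agreement -> benchmark.

``run_pipeline`` executes the full study protocol on a generated (or loaded)
cohort: a chronological-style development/validation split, framework panel
computation, unmeasured-ion agreement analysis on the development half,
the model benchmark (MLR + ML with CV, calibration, importance, ablation)
on the development half, and a replay of every fitted model on the held-out
validation half. All stage outputs are written to one run directory and
listed, with checksums, in a manifest. Given a fixed configuration and seed,
stage outputs are byte-identical across runs (the manifest's timestamp is
the only run-varying field).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bench
from .agreement import ReferenceBands, agreement_report
from .cases import run_cases
from .chem import SideMode, panel_table
from .cohort import CohortSpec, SyntheticCohort, generate_cohort, make_temporal_split
from .io import read_cohort, write_cohort

__all__ = ["DEFAULT_CONFIG", "PipelineError", "RunManifest", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "out_dir": "runs/default",
    "cohort": {"source": "generate", "n": 2000, "seed": 42},
    "split": {"frac": 0.654, "drift": None},
    "agreement": {"tolerance": 2.0},
    "bench": {
        "frameworks": list(bench.FRAMEWORKS),
        "algorithms": list(bench.ALGORITHMS),
        "seed": 42,
        "cv_folds": 10,
        "ablation": True,
    },
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclasses.dataclass(frozen=True)
class RunManifest:
    run_id: str
    config: dict
    seeds: dict
    outputs: dict[str, str]  # relative path -> sha256
    started_at: str
    finished_at: str

    def to_dict(self):
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> dict:
    """Default configuration, optionally updated from a YAML file and kwargs."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        elif value is not None:
            config[key] = value
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


@_stage("cohort_synth")
def _stage_cohort(cfg: dict, out: Path) -> SyntheticCohort:
    if cfg.get("source", "generate") == "csv":
        records = read_cohort(cfg["path"])
        cohort = SyntheticCohort(records, np.full(len(records), np.nan), CohortSpec(n=0), 0)
    else:
        cohort = generate_cohort(CohortSpec(n=int(cfg["n"]), seed=int(cfg["seed"])))
    if len(cohort.records) == 0:
        raise ValueError("cohort_synth produced an empty cohort (n=0?)")
    write_cohort(cohort.records, out / "cohort.csv")
    pd.DataFrame({"xa": cohort.truth}).to_csv(out / "cohort_truth.csv", index=False)
    _write_json(cohort.spec.to_dict(), out / "cohort_spec.json")
    return cohort


@_stage("panels")
def _stage_panels(dev: SyntheticCohort, val: SyntheticCohort, out: Path):
    dev_panels = panel_table(dev.records, SideMode.FORMULA)
    val_panels = panel_table(val.records, SideMode.FORMULA)
    dev_panels.to_csv(out / "panels_development.csv", index=False)
    val_panels.to_csv(out / "panels_validation.csv", index=False)
    return dev_panels, val_panels


@_stage("ui_agreement")
def _stage_agreement(dev_panels: pd.DataFrame, cfg: dict, out: Path):
    bands = ReferenceBands(tolerance=float(cfg.get("tolerance", 2.0)))
    report = agreement_report(dev_panels, bands)
    _write_json(report.to_dict(), out / "agreement.json")
    lines = []
    for (a, b), tab in report.crosstabs.items():
        tab.to_csv(out / f"crosstab_{a}_vs_{b}.csv")
        lines.append(f"{a} vs {b}: kappa={report.kappa[(a, b)]:.3f}")
        lines.append(tab.to_string())
        lines.append("")
    (out / "agreement.txt").write_text("\n".join(lines))
    return report


@_stage("model_bench")
def _stage_bench(dev_ft, val_ft, cfg: dict, out: Path) -> dict:
    seed = int(cfg["seed"])
    k = int(cfg["cv_folds"])
    results: dict = {"seed": seed, "hyperparameters": bench.HYPERPARAMETERS,
                     "frameworks": {}, "ablation": []}
    for framework in cfg["frameworks"]:
        features = bench.FRAMEWORKS[framework]
        X, y = dev_ft[features], dev_ft["ph"]
        Xv, yv = val_ft[features], val_ft["ph"]
        block: dict = {}
        for algorithm in cfg["algorithms"]:
            if algorithm == "mlr":
                report = bench.fit_mlr(X, y, seed=seed)
            else:
                report = bench.fit_ml(algorithm, X, y, seed=seed)
            report.cv = bench.crossvalidate(algorithm, X, y, k=k, seed=seed)
            entry = report.to_dict()
            entry["external"] = bench.evaluate_external(report, Xv, yv)
            block[algorithm] = entry
        results["frameworks"][framework] = block
        if cfg.get("ablation", True):
            for algorithm in cfg["algorithms"]:
                if algorithm == "mlr":
                    continue
                res = bench.run_ablation(framework, algorithm, dev_ft, y, seed=seed, k=k)
                results["ablation"].append(res.to_dict())
    _write_json(results, out / "benchmark.json")
    (out / "benchmark.md").write_text(_render_benchmark_md(results))
    return results


def _render_benchmark_md(results: dict) -> str:
    lines = ["# Benchmark summary", "", "## Model performance (development test split)", "",
             "| framework | algorithm | R2 | RMSE | MAE | CV R2 (mean +/- sd) |",
             "|---|---|---|---|---|---|"]
    for fw, block in results["frameworks"].items():
        for algo, entry in block.items():
            cv = entry.get("cv")
            cv_txt = f"{cv['r2'][0]:.3f} +/- {cv['r2'][1]:.3f}" if cv else "-"
            lines.append(
                f"| {fw} | {algo} | {entry['r2']:.3f} | {entry['rmse']:.4f} "
                f"| {entry['mae']:.4f} | {cv_txt} |"
            )
    if results.get("ablation"):
        lines += ["", "## Feature ablation (paired 10-fold CV)", "",
                  "| framework | algorithm | removed | full R2 | ablated R2 | delta R2 |",
                  "|---|---|---|---|---|---|"]
        for res in results["ablation"]:
            lines.append(
                f"| {res['framework']} | {res['algorithm']} | {res['removed']} "
                f"| {res['full_r2']:.3f} | {res['ablated_r2']:.3f} | {res['delta_r2']:.3f} |"
            )
    return "\n".join(lines) + "\n"


def run_pipeline(config: dict | None = None, overwrite: bool = False) -> RunManifest:
    """Execute all stages per ``config`` and write a manifest.

    The run directory is ``config['out_dir']``; refusing to overwrite a
    non-empty directory unless ``overwrite`` is set.
    """
    config = config or json.loads(json.dumps(DEFAULT_CONFIG))
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config["out_dir"])
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise PipelineError(f"output directory {out} is not empty; pass overwrite")
    out.mkdir(parents=True, exist_ok=True)

    cohort = _stage_cohort(config["cohort"], out)
    dev, val = make_temporal_split(
        cohort, float(config["split"]["frac"]), drift=config["split"].get("drift")
    )
    dev_panels, val_panels = _stage_panels(dev, val, out)
    _stage_agreement(dev_panels, config["agreement"], out)
    dev_ft = bench.feature_table(dev.records, dev_panels)
    val_ft = bench.feature_table(val.records, val_panels)
    _stage_bench(dev_ft, val_ft, config["bench"], out)
    (out / "cases.txt").write_text(run_cases(strict=True) + "\n")

    outputs = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    run_id = hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:12]
    manifest = RunManifest(
        run_id=run_id,
        config=config,
        seeds={"cohort": config["cohort"].get("seed"), "bench": config["bench"]["seed"]},
        outputs=outputs,
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    _write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
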