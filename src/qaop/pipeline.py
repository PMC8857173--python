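"""Stage orchestration: simulate -> explore -> fit -> diagnose -> predict ->
evaluate -> sensitivity, each writing one artifact into the output directory.

Every artifact embeds (or is accompanied by) the configuration hash and seed,
so a run is reproducible bit-for-bit from its config — re-running a stage with
the same config and seed rewrites the same artifact (archive timestamps
aside).  The CLI module is a thin wrapper over :func:`run`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .dataset import (
    DNTDataset,
    PredictorAssignment,
    build_design_matrices,
    explore_dataset,
    read_dataset,
)
from .diagnostics import diagnose_fit, sensitivity_analysis
from .model import MCMCConfig, ModelSpec, NODES, PosteriorSamples, PriorSpec, build_model, count_parameters, fit_posterior
from .prediction import build_report, performance_metrics
from .synthetic import GeneratorConfig, simulate_study, write_fixture

__all__ = ["PipelineConfig", "PipelineError", "SUBCOMMANDS", "run"]

log = logging.getLogger("qaop")

SUBCOMMANDS = (
    "simulate",
    "explore",
    "fit",
    "diagnose",
    "predict",
    "evaluate",
    "sensitivity",
    "all",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration for every stage; seed is mandatory."""

    seed: int
    outdir: str = "qaop_out"
    dataset_path: str | None = None
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    assignment: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)  # PriorSpec overrides
    mcmc: dict = field(default_factory=dict)  # chains/warmup/draws/target_accept
    interval_level: float = 0.95
    interval_method: str = "equal_tailed"
    thresholds: tuple[float, float] | None = None
    decision_cutoff: float = 0.5
    sensitivity_scales: tuple[float, ...] = (0.5, 1.0, 2.0)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        # validate sub-configs before any compute
        self.assignment_obj = PredictorAssignment.from_dict(self.assignment)
        self.priors_obj = PriorSpec(**self.priors)
        self.mcmc_obj = MCMCConfig(seed=int(self.seed), **self.mcmc)
        gen = dict(self.generator)
        gen.setdefault("seed", int(self.seed))
        gen["assignment"] = self.assignment_obj
        self.generator_obj = GeneratorConfig(**gen)
        self.generator_obj.validate()
        if not 0.0 < self.interval_level < 1.0:
            raise ValueError("interval_level must be in (0,1)")
        if self.interval_method not in ("equal_tailed", "hdi"):
            raise ValueError("interval_method must be equal_tailed or hdi")

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update(overrides or {})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
        }
        d["thresholds"] = list(self.thresholds) if self.thresholds else None
        d["sensitivity_scales"] = list(self.sensitivity_scales)
        return d

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _stamp(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.config_hash, "seed": int(cfg.seed)}


def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_line(cfg: PipelineConfig, stage: str, message: str) -> None:
    line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} stage={stage} hash={cfg.config_hash} seed={cfg.seed} {message}"
    log.info(line)
    with (_out(cfg) / "run.log").open("a", encoding="utf-8") as fh:
        fh.write(line + "\n")


def _load_dataset(cfg: PipelineConfig, stage: str) -> DNTDataset:
    if cfg.dataset_path:
        return read_dataset(cfg.dataset_path)
    fixture = _out(cfg) / "dataset.csv"
    if fixture.exists():
        return read_dataset(fixture)
    raise PipelineError(stage, "no dataset: give dataset_path or run 'simulate' first")


def _load_posterior(cfg: PipelineConfig, stage: str) -> PosteriorSamples:
    pdir = _out(cfg) / "posterior"
    if not (pdir / "meta.json").exists():
        raise PipelineError(stage, "no posterior found: run 'fit' first")
    return PosteriorSamples.load(pdir)


def _stage_simulate(cfg: PipelineConfig) -> Path:
    ds, true = simulate_study(cfg.generator_obj)
    path = write_fixture(ds, _out(cfg) / "dataset.csv", true)
    _log_line(cfg, "simulate", f"wrote {path.name} (n={len(ds)})")
    return path


def _stage_explore(cfg: PipelineConfig) -> Path:
    ds = _load_dataset(cfg, "explore")
    eda = explore_dataset(ds)
    payload = {
        **_stamp(cfg),
        "n_compounds": len(ds),
        "variable_types": eda.variable_types,
        "missing_fraction": eda.missing_fraction,
        "class_balance": eda.class_balance,
        "pearson_correlations": {
            "columns": list(eda.pearson_correlations.columns),
            "matrix": eda.pearson_correlations.where(
                np.isfinite(eda.pearson_correlations), None
            ).values.tolist(),
        },
        "histograms": {
            c: {"edges": e.tolist(), "counts": n.tolist()}
            for c, (e, n) in eda.histograms.items()
        },
    }
    path = _out(cfg) / "eda.json"
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    _log_line(cfg, "explore", f"wrote {path.name}")
    return path


def _stage_fit(cfg: PipelineConfig) -> Path:
    ds = _load_dataset(cfg, "fit")
    dm = build_design_matrices(ds, cfg.assignment_obj)
    model = build_model(dm, ModelSpec(priors=cfg.priors_obj))
    ps = fit_posterior(model, cfg.mcmc_obj)
    pdir = ps.save(_out(cfg) / "posterior")
    census = count_parameters(model)
    (pdir / "census.json").write_text(
        json.dumps({**_stamp(cfg), **dataclasses.asdict(census)}, indent=1),
        encoding="utf-8",
    )
    _log_line(
        cfg,
        "fit",
        f"saved posterior (dim={census.total_scalar_parameters}, divergences={sum(ps.divergences)})",
    )
    return pdir


def _stage_diagnose(cfg: PipelineConfig) -> Path:
    ps = _load_posterior(cfg, "diagnose")
    diag = diagnose_fit(ps)
    path = _out(cfg) / "diagnostics.json"
    path.write_text(
        json.dumps({**_stamp(cfg), **diag.to_dict()}, indent=1), encoding="utf-8"
    )
    _log_line(cfg, "diagnose", f"max_rhat={diag.max_rhat:.4f} divergences={diag.divergences}")
    return path


def _stage_predict(cfg: PipelineConfig) -> Path:
    ps = _load_posterior(cfg, "predict")
    report = build_report(
        ps,
        level=cfg.interval_level,
        interval_method=cfg.interval_method,
        thresholds=cfg.thresholds,
    )
    path = report.to_csv(_out(cfg) / "predictions.csv")
    (_out(cfg) / "predictions_summary.json").write_text(
        report.to_json_summary(), encoding="utf-8"
    )
    _log_line(cfg, "predict", f"wrote {path.name}")
    return path


def _stage_evaluate(cfg: PipelineConfig) -> Path:
    ps = _load_posterior(cfg, "evaluate")
    means = ps.prob.mean(axis=(0, 1))
    payload = dict(_stamp(cfg))
    for k, node in enumerate(NODES):
        mask = ps.y_missing_mask[node]
        if (mask == 0).sum() == 0:
            payload[node] = {"note": "no observed labels; not evaluable"}
            continue
        cm = performance_metrics(
            means[:, k],
            ps.y_obs[node].astype(float),
            label_missing=mask,
            decision_cutoff=cfg.decision_cutoff,
        )
        payload[node] = cm.to_dict()
    path = _out(cfg) / "metrics.json"
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    _log_line(cfg, "evaluate", f"wrote {path.name}")
    return path


def _stage_sensitivity(cfg: PipelineConfig) -> Path:
    import pandas as pd

    ds = _load_dataset(cfg, "sensitivity")
    dm = build_design_matrices(ds, cfg.assignment_obj)
    settings = [cfg.priors_obj.scaled(s) for s in cfg.sensitivity_scales]
    labels = [f"hyper_sigma_x{s:g}" for s in cfg.sensitivity_scales]
    res = sensitivity_analysis(dm, settings, cfg.mcmc_obj, labels=labels)
    rows = []
    for lab, met in zip(res.labels, res.metrics):
        row = {"setting": lab}
        row.update(met or {"error": res.errors.get(lab, "failed")})
        rows.append(row)
    df = pd.DataFrame(rows)
    df["max_delta_vs_first"] = [
        res.delta_matrix[0, i] for i in range(len(res.labels))
    ]
    path = _out(cfg) / "sensitivity.csv"
    df.to_csv(path, index=False)
    _log_line(cfg, "sensitivity", f"max_delta={res.max_delta:.4f}")
    return path


_STAGES = {
    "simulate": _stage_simulate,
    "explore": _stage_explore,
    "fit": _stage_fit,
    "diagnose": _stage_diagnose,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "sensitivity": _stage_sensitivity,
}


def run(subcommand: str, cfg: PipelineConfig) -> dict[str, Path]:
    """Run one stage (or ``all``, fail-fast); returns artifact paths."""
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand '{subcommand}'")
    stages = list(_STAGES) if subcommand == "all" else [subcommand]
    artifacts: dict[str, Path] = {}
    for stage in stages:
        try:
            artifacts[stage] = _STAGES[stage](cfg)
        except PipelineError:
            (_out(cfg) / "FAILED").write_text(stage, encoding="utf-8")
            raise
        except Exception as exc:
            (_out(cfg) / "FAILED").write_text(stage, encoding="utf-8")
            raise PipelineError(stage, str(exc)) from exc
    failed = _out(cfg) / "FAILED"
    if failed.exists():
        failed.unlink()
    return artifacts
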