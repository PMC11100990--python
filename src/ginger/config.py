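"""Experiment configuration: schema validation, defaults, and the
end-to-end ``run_experiment`` entry point used by the command line.

Configurations are plain YAML/JSON mappings.  A master seed plus run index
deterministically derives all per-run seeds, and numeric CSV output is
formatted to 10 significant digits, so identical configurations reproduce
identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import AGENT_KINDS
from .evaluation import Curve, ablation_report, learning_curve
from .ibl import AgentParams
from .representations import BVAESpec
from .runner import (StimulusRepresenter, build_agent_for_task, derive_seed,
                     run_task)
from .tasks import BanditTaskSpec, PhishingTask, PhishingTaskSpec, TransferTaskSpec

__all__ = ["ExperimentConfig", "validate_config", "run_experiment",
           "default_reference_curve", "CSV_FLOAT_FORMAT"]

log = logging.getLogger("ginger")

CSV_FLOAT_FORMAT = "%.10g"

_TASK_SPECS = {
    "bandit": BanditTaskSpec,
    "transfer": TransferTaskSpec,
    "phishing": PhishingTaskSpec,
}

_PARAM_KEYS = ("d", "mu", "omega", "sigma", "tau", "noise_on", "noise_dist")


@dataclass
class ExperimentConfig:
    """Validated, normalized experiment description."""

    task: str
    agents: list[dict]
    n_runs: int = 1
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"
    task_spec: dict = field(default_factory=dict)
    agent_params: dict = field(default_factory=dict)
    bvae: dict = field(default_factory=dict)
    reference_curve: str | None = None
    prepopulation: float | None = 1.0
    embedding_dim: int | None = None
    latent_dim: int = 9

    def build_task_spec(self):
        return _TASK_SPECS[self.task](**self.task_spec)

    def build_agent_params(self) -> AgentParams:
        return AgentParams(**self.agent_params)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(source: str | Path | dict) -> tuple[ExperimentConfig | None, list[str]]:
    """Schema-check a YAML/JSON config (path or mapping), filling documented
    defaults.  Returns (config, errors); all violations are reported at once
    and config is None when any error was found."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        raw = yaml.safe_load(text)
    else:
        raw = dict(source)
    errors: list[str] = []
    if not isinstance(raw, dict) or raw is None:
        return None, ["config must be a mapping with keys: task, agents"]

    known = {f for f in ExperimentConfig.__dataclass_fields__}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")

    task = raw.get("task")
    if task is None:
        errors.append("missing required key: task")
    elif task not in _TASK_SPECS:
        errors.append(f"task must be one of {sorted(_TASK_SPECS)}, got {task!r}")

    agents = raw.get("agents")
    if agents is None:
        errors.append("missing required key: agents (list of agent kinds)")
    else:
        if isinstance(agents, str):
            agents = [agents]
        agents = [a if isinstance(a, dict) else {"kind": a} for a in agents]
        for a in agents:
            kind = str(a.get("kind", "")).upper()
            if kind not in AGENT_KINDS:
                errors.append(f"unknown agent kind {a.get('kind')!r} "
                              f"(choose from {AGENT_KINDS})")
            else:
                a["kind"] = kind

    n_runs = raw.get("n_runs", 1)
    if not isinstance(n_runs, int) or n_runs < 1:
        errors.append(f"n_runs must be a positive integer, got {n_runs!r}")

    params = dict(raw.get("agent_params", {}))
    for key in params:
        if key not in _PARAM_KEYS:
            errors.append(f"unknown agent_params key: {key!r}")
    try:
        AgentParams(**{k: v for k, v in params.items() if k in _PARAM_KEYS})
    except (ValueError, TypeError) as exc:
        errors.append(f"invalid agent_params: {exc}")

    task_spec = dict(raw.get("task_spec", {}))
    if task in _TASK_SPECS:
        try:
            _TASK_SPECS[task](**task_spec)
        except (ValueError, TypeError) as exc:
            errors.append(f"invalid task_spec for {task}: {exc}")

    if errors:
        return None, errors
    cfg = ExperimentConfig(
        task=task,
        agents=agents,
        n_runs=n_runs,
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "results")),
        log_level=str(raw.get("log_level", "INFO")),
        task_spec=task_spec,
        agent_params=params,
        bvae=dict(raw.get("bvae", {})),
        reference_curve=raw.get("reference_curve"),
        prepopulation=raw.get("prepopulation", 1.0),
        embedding_dim=raw.get("embedding_dim"),
        latent_dim=int(raw.get("latent_dim", 9)),
    )
    return cfg, []


def default_reference_curve(n: int, chance: float = 1.0 / 3.0,
                            asymptote: float = 0.85, rate: float = 5.0) -> Curve:
    """Synthetic saturating-exponential reference learning curve
    p(t) = chance + (asymptote - chance)(1 - exp(-(t-1)/rate)).

    Used as the default comparison curve when no externally supplied
    reference (e.g. human data in the curve CSV schema) is configured.
    """
    t = np.arange(1, n + 1, dtype=float)
    return Curve(chance + (asymptote - chance) * (1.0 - np.exp(-(t - 1) / rate)))


def _load_reference(path: str, n: int) -> Curve:
    df = pd.read_csv(path)
    col = "mean" if "mean" in df.columns else df.columns[-1]
    return Curve(df[col].to_numpy()[:n])


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Simulate every agent x run, log all trials, and emit curves, the
    ablation report, and a manifest.  Returns paths and in-memory results."""
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    task_spec = config.build_task_spec()
    params = config.build_agent_params()

    needs_reps = any(a["kind"] != "IBL" for a in config.agents)
    representer = None
    if needs_reps and config.task in ("bandit", "transfer"):
        bvae_spec = BVAESpec(**{"seed": derive_seed(config.seed, 0), **config.bvae})
        log.info("training stimulus beta-VAE (latent %d, beta %.2f)",
                 bvae_spec.latent_dim, bvae_spec.beta)
        representer = StimulusRepresenter(bvae_spec)

    embedding_dim = config.embedding_dim
    if config.task == "phishing":
        embedding_dim = embedding_dim or task_spec.embedding_dim
        task_spec.embedding_dim = embedding_dim

    all_records = []
    curves: dict[str, list] = {}
    for a_idx, agent_cfg in enumerate(config.agents):
        kind = agent_cfg["kind"]
        curves[kind] = []
        for run in range(config.n_runs):
            agent_seed = derive_seed(config.seed, 1, a_idx, run)
            task_seed = derive_seed(config.seed, 2, run)  # same tasks across agents
            agent = build_agent_for_task(
                kind, config.task, agent_seed, params=params,
                prepopulation=config.prepopulation,
                embedding_dim=embedding_dim or 1536,
                latent_dim=config.latent_dim)
            records = run_task(config.task, agent, run, task_seed,
                               task_spec=task_spec, representer=representer)
            all_records.extend(records)
            curves[kind].append(
                learning_curve(records, field="correct").values)
        log.info("agent %s: %d runs complete", kind, config.n_runs)

    trials = pd.DataFrame([r.to_row() for r in all_records])
    trials_path = out / "trials.csv"
    trials.to_csv(trials_path, index=False, float_format=CSV_FLOAT_FORMAT)

    n_curve = min(min(len(c) for c in cs) for cs in curves.values())
    curves_trimmed = {k: [c[:n_curve] for c in cs] for k, cs in curves.items()}
    curve_frames = []
    for kind, cs in curves_trimmed.items():
        arr = np.vstack(cs)
        mu = arr.mean(0)
        se = arr.std(0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(n_curve)
        df = pd.DataFrame({
            "agent": kind,
            "trial_index": np.arange(1, n_curve + 1),
            "mean": mu,
            "ci_lo": np.clip(mu - 1.96 * se, 0, 1),
            "ci_hi": np.clip(mu + 1.96 * se, 0, 1),
            "n": arr.shape[0],
        })
        curve_frames.append(df)
    curves_path = out / "curves.csv"
    pd.concat(curve_frames).to_csv(curves_path, index=False,
                                   float_format=CSV_FLOAT_FORMAT)

    if config.reference_curve:
        reference = _load_reference(config.reference_curve, n_curve)
    else:
        reference = default_reference_curve(n_curve)
    report = ablation_report(curves_trimmed, reference, task=config.task)
    report_path = out / "report.csv"
    report.to_csv(report_path, index=False, float_format=CSV_FLOAT_FORMAT)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "master_seed": config.seed,
        "seed_scheme": "numpy SeedSequence(entropy=master, spawn_key=path)",
        "n_trials_logged": len(all_records),
        "outputs": {
            "trials": trials_path.name,
            "curves": curves_path.name,
            "report": report_path.name,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    return {"trials": trials, "curves": curves_trimmed, "report": report,
            "paths": {"trials": trials_path, "curves": curves_path,
                      "report": report_path, "manifest": manifest_path}}
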