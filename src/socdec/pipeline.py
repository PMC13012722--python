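"""End-to-end reproducible pipeline: simulate -> risk -> happiness ->
compare -> recover -> guilt, with a manifest and per-stage outputs."""
from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agents, guilt, happiness, io, risk

log = logging.getLogger("socdec")

STAGES = ("simulate", "risk_prefs", "fit_happiness", "compare", "recover",
          "guilt")


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 40
    sessions: int = 3
    generative_model: str = "responsibility_redux"
    models: tuple[str, ...] = tuple(happiness.MODEL_SPECS)
    recovery_reps: int = 10
    out_dir: str = "socdec_run"
    population_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = [m for m in (*self.models, self.generative_model)
                   if m not in happiness.MODEL_SPECS]
        if unknown:
            raise ValueError(f"unknown model name(s) {unknown}; known: "
                             f"{sorted(happiness.MODEL_SPECS)}")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; stop at the first failure with a clear status file.

    Deterministic stages reproduce bit-identical outputs for an identical
    config.  Returns the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config), "config_hash": _config_hash(config),
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        log.info("stage %s", stage)
        try:
            _run_stage(stage, config, state, out)
        except Exception as exc:  # halt downstream stages, record status
            manifest["stages"][stage] = {"status": "failed",
                                         "error": f"{type(exc).__name__}: {exc}"}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise
        manifest["stages"][stage] = {
            "status": "completed",
            "seconds": round(time.perf_counter() - t0, 3)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> None:
    if stage == "simulate":
        sampler = agents.default_param_sampler(
            config.generative_model, overrides=config.population_overrides)
        ds = agents.simulate_cohort(config.n_participants, config.sessions,
                                    sampler, seed=config.seed)
        io.write_dataset(ds, out / "dataset")
        state["dataset"] = ds
    elif stage == "risk_prefs":
        profiles = risk.cohort_risk_profiles(state["dataset"])
        profiles.to_csv(out / "risk_profiles.csv", index=False)
        wide = profiles.pivot(index="participant", columns="condition",
                              values="risk_premium").dropna()
        comp = risk.compare_conditions(wide["solo"], wide["social"])
        (out / "risk_premium_comparison.json").write_text(
            json.dumps(comp.__dict__, indent=2))
        state["profiles"] = profiles
    elif stage == "fit_happiness":
        fits = {m: [happiness.fit_model(p.trials, p.ratings, m)
                    for p in state["dataset"].participants]
                for m in config.models}
        rows = [{"participant": p.pid, "model": m, "gamma": f.gamma,
                 "r2": f.r2, "adj_r2": f.adj_r2, "aic": f.aic, "bic": f.bic,
                 **{f"w_{k}": v for k, v in f.weights.items()}}
                for m, fl in fits.items()
                for p, f in zip(state["dataset"].participants, fl)]
        pd.DataFrame(rows).to_csv(out / "happiness_fits.csv", index=False)
        state["fits"] = fits
    elif stage == "compare":
        table, pairwise = happiness.compare_cohort(state["fits"])
        table.to_csv(out / "model_comparison.csv", index=False)
        pairwise.to_csv(out / "model_comparison_pairwise.csv", index=False)
    elif stage == "recover":
        report = happiness.parameter_recovery(
            state["dataset"], config.generative_model,
            nreps=config.recovery_reps,
            rng=np.random.default_rng(
                np.random.SeedSequence([config.seed, 0x5EC0])))
        report.table.to_csv(out / "parameter_recovery.csv", index=False)
    elif stage == "guilt":
        rows = guilt.build_post_lottery_table(state["dataset"])
        rows.to_csv(out / "post_lottery_table.csv", index=False)
        lmm = guilt.fit_guilt_lmm(rows)
        lmm.to_csv(out / "guilt_lmm.csv", index=False)
        eff = guilt.guilt_effect(state["dataset"])
        eff.per_participant.to_csv(out / "guilt_effect_participants.csv",
                                   index=False)
        summary = {s: e.__dict__ for s, e in eff.strata.items()}
        agency = guilt.agency_effect(state["dataset"])
        summary["agency_beta"] = float(
            agency.loc[agency["term"] == "agency", "beta"].iloc[0])
        (out / "guilt_summary.json").write_text(json.dumps(summary, indent=2))
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage}")
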