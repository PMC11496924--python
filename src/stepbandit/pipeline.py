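"""Configuration, file surfaces and the end-to-end pipeline.

``run_pipeline`` chains the stages: cohort generation, stratified block
randomisation, the daily trial loop, the analysis-set quality filters, the
mixed-model fit and the trajectory projections — writing every artifact as
CSV plus a manifest. One global seed deterministically spawns independent
substreams per stage, so a re-run with the same config is byte-identical
and changing, say, the cohort size does not perturb the bandit's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lmm
from .bandit import ContextEncoder, ThompsonSampler
from .cohort import SimConfig, generate_cohort, profiles_to_frame
from .messages import MessageBank, default_bank, load_bank
from .trial import apply_assignments, apply_quality_filters, randomize, run_trial

ARTIFACTS = (
    "profiles.csv",
    "step_log.csv",
    "decision_log.csv",
    "exclusions.csv",
    "lmm_estimates.csv",
    "projections.csv",
)


class StepLogParseError(ValueError):
    """A step-log CSV violates the schema; names the column/row."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Everything one pipeline run needs, fully serialisable."""

    sim: SimConfig = field(default_factory=SimConfig)
    bank_path: str | None = None
    prior_scale: float = 1.0
    noise_var: float = 1.0
    context_features: str = "full"  # "full" | "minimal"
    horizon: int = 168
    subgroup: bool = True
    seed: int = 0
    out_dir: str = "out"

    def validate(self) -> None:
        self.sim.validate()
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be positive")
        if self.context_features not in ("full", "minimal"):
            raise ValueError("context_features must be 'full' or 'minimal'")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            if "arm_sizes" in sim:
                sim["arm_sizes"] = tuple(sim["arm_sizes"])
            for key in ("effect_means",):
                if key in sim:
                    sim[key] = {k: tuple(v) for k, v in sim[key].items()}
            sim = SimConfig(**sim)
        return cls(sim=sim, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            payload = json.loads(text)
        else:
            payload = yaml.safe_load(text)
        return cls.from_dict(payload or {})


def _engine_for(config: RunConfig) -> ThompsonSampler:
    encoder = (
        ContextEncoder.minimal()
        if config.context_features == "minimal"
        else ContextEncoder()
    )
    return ThompsonSampler(
        encoder=encoder, prior_scale=config.prior_scale, noise_var=config.noise_var
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the whole study simulation and analysis; returns the out dir."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    trial_seed = int(seeds[2].generate_state(1)[0] % (2**31))

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise PipelineError(name, exc) from exc

    profiles = stage(
        "generate_cohort", generate_cohort, config.sim, np.random.default_rng(seeds[0])
    )
    assignments = stage("randomize", randomize, profiles, np.random.default_rng(seeds[1]))
    profiles = stage("apply_assignments", apply_assignments, profiles, assignments, config.sim)
    bank = stage(
        "load_bank", load_bank, config.bank_path
    ) if config.bank_path else default_bank()
    engine = _engine_for(config)
    log = stage("run_trial", run_trial, profiles, bank, engine, config.sim, trial_seed)
    analysis, exclusions = stage("apply_quality_filters", apply_quality_filters, log.steps)
    fit = stage("fit_lmm", lmm.fit_lmm, analysis)
    projections = fit.projection_table(horizon=config.horizon)

    profiles_to_frame(profiles).to_csv(out_dir / "profiles.csv", index=False)
    log.steps.to_csv(out_dir / "step_log.csv", index=False)
    log.decisions.to_csv(out_dir / "decision_log.csv", index=False)
    exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    fit.coef_table().to_csv(out_dir / "lmm_estimates.csv", index=False)
    projections.to_csv(out_dir / "projections.csv", index=False)

    if config.subgroup:
        sub = lmm.subgroup_fit(analysis, grouping="recruitment_source")
        rows = []
        for group, res in sorted(sub.items()):
            if isinstance(res, Exception):
                continue
            t = res.projection_table(horizon=config.horizon)
            t.insert(0, "group", group)
            rows.append(t)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                out_dir / "subgroup_projections.csv", index=False
            )

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {
            name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
            for name in ARTIFACTS
        },
        "package": "stepbandit 0.1.0",
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str), encoding="utf-8"
    )
    (out_dir / "config_echo.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
    return out_dir


def read_step_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format step log CSV.

    Requires ``participant_id``, ``day``, ``steps``; an ``observed`` column
    defaults to True. Duplicate (participant, day) pairs are rejected,
    citing the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("participant_id", "day", "steps"):
        if col not in df.columns:
            raise StepLogParseError(f"{path}: missing column {col!r}")
    if "observed" not in df.columns:
        df["observed"] = True
    dup = df.duplicated(subset=["participant_id", "day"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        rec = df.iloc[row]
        raise StepLogParseError(
            f"{path}: duplicate (participant, day) = "
            f"({rec['participant_id']}, {rec['day']}) at row {row + 2}"
        )
    try:
        df["day"] = df["day"].astype(int)
        df["steps"] = df["steps"].astype(int)
        df["observed"] = df["observed"].astype(bool)
    except (TypeError, ValueError) as exc:
        raise StepLogParseError(f"{path}: bad dtype ({exc})") from exc
    if (df["steps"] < 0).any():
        row = int(df.index[df["steps"] < 0][0])
        raise StepLogParseError(f"{path}: negative steps at row {row + 2}")
    return df


def write_step_log(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
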