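"""Three-arm trial orchestration: randomisation, daily execution, filters.

Arms
----
* **control** — only the weekly mood self-monitoring message;
* **random**  — one feedback and one motivational message daily, categories
  and delivery slot drawn uniformly at random;
* **adaptive** — daily messages whose categories and slot are chosen by the
  pooled Thompson-sampling engine.

Allocation uses permuted-block randomisation (block size 3, 1:1:1)
stratified by language preference. The day loop respects causality: the
morning decision on day *t* sees step data only through day *t-1*, its
behavioural effect lands on day *t+1*, and the engine's posterior update for
that decision happens once the next-day count is in (observed days only).

Quality filters reproduce the analysis-set rules: drop participants with no
step data, with fewer than 28 observed days, or with more than 25% of their
observed days above 20,000 steps (a data-extraction red flag).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bandit import (
    ActionTriple,
    Context,
    ThompsonSampler,
    compute_reward,
    random_policy,
)
from .cohort import ARMS, ParticipantProfile, SimConfig, apply_missingness, step_model
from .messages import FEEDBACK, MOOD, MOTIVATION, MessageBank, sample_template

BLOCK_SIZE = 3
MIN_OBSERVED_DAYS = 28
HIGH_COUNT_THRESHOLD = 20_000
HIGH_COUNT_FRACTION = 0.25
MOOD_PERIOD = 7


class TrialSetupError(ValueError):
    """Configuration and inputs do not fit together."""


@dataclass(frozen=True)
class ArmAssignment:
    participant_id: str
    arm: str
    stratum: str
    block_index: int


@dataclass
class TrialLog:
    """Decision rows, step observations and the exclusion audit trail."""

    decisions: pd.DataFrame
    steps: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "decision_log.csv": out_dir / "decision_log.csv",
            "step_log.csv": out_dir / "step_log.csv",
        }
        self.decisions.to_csv(paths["decision_log.csv"], index=False)
        self.steps.to_csv(paths["step_log.csv"], index=False)
        return paths


def randomize(
    profiles: Sequence[ParticipantProfile],
    seed: int | np.random.Generator = 0,
) -> list[ArmAssignment]:
    """Stratified permuted-block randomisation (block size 3, 1:1:1).

    Within each language stratum, participants are taken in input order and
    every complete block of three contains each arm exactly once, so the
    arm-size imbalance never exceeds one per stratum.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    assignments: list[ArmAssignment] = []
    for stratum in ("en", "es"):
        members = [p for p in profiles if p.language == stratum]
        for block_start in range(0, len(members), BLOCK_SIZE):
            block = members[block_start : block_start + BLOCK_SIZE]
            order = [ARMS[i] for i in rng.permutation(len(ARMS))]
            for person, arm in zip(block, order):
                assignments.append(
                    ArmAssignment(
                        participant_id=person.id,
                        arm=arm,
                        stratum=stratum,
                        block_index=block_start // BLOCK_SIZE,
                    )
                )
    return assignments


def apply_assignments(
    profiles: Sequence[ParticipantProfile],
    assignments: Sequence[ArmAssignment],
    config: SimConfig,
) -> list[ParticipantProfile]:
    """Re-arm profiles after randomisation.

    The random-intercept *deviation* from the old arm mean is preserved and
    re-centred on the new arm's mean; drift and missingness are refreshed to
    the new arm's values. Deterministic — no new randomness.
    """
    by_id = {a.participant_id: a for a in assignments}
    out = []
    for p in profiles:
        a = by_id.get(p.id)
        if a is None:
            raise TrialSetupError(f"no assignment for participant {p.id}")
        deviation = p.baseline_level - config.arm_baselines[p.arm]
        new_baseline = max(0.0, config.arm_baselines[a.arm] + deviation)
        out.append(
            ParticipantProfile(
                id=p.id,
                language=p.language,
                arm=a.arm,
                recruitment_source=p.recruitment_source,
                age=p.age,
                sex=p.sex,
                phq8=p.phq8,
                baseline_level=new_baseline,
                drift=float(config.arm_drifts[a.arm]),
                responsiveness=p.responsiveness,
                missing_prob=float(config.missing_days_mean[a.arm]) / config.n_days,
                residual_sd=p.residual_sd,
                ar1_rho=p.ar1_rho,
                missing_burst_mean=p.missing_burst_mean,
            )
        )
    return out


class _ParticipantRuntime:
    """Per-person mutable state tracked across the day loop."""

    def __init__(self, profile: ParticipantProfile):
        self.profile = profile
        self.eps_prev = 0.0
        self.prev_action: ActionTriple | None = None  # sent yesterday morning
        self.today_decision: tuple | None = None  # (context, action, row_idx)
        self.rewardable: tuple | None = None  # yesterday's decision
        self.last_observed_steps: float | None = None
        self.yesterday_missing = False
        self.window: deque[tuple[int, int]] = deque()  # (day, steps), observed

    def trailing_stats(self, day: int) -> tuple[float, float, float]:
        """(28-day mean, 28-day SD, 7-day mean) of observed counts."""
        while self.window and self.window[0][0] < day - 28:
            self.window.popleft()
        vals = [s for _, s in self.window]
        if not vals:
            return np.nan, 0.0, np.nan
        mean28 = float(np.mean(vals))
        sd28 = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        vals7 = [s for d, s in self.window if d >= day - 7]
        mean7 = float(np.mean(vals7)) if vals7 else mean28
        return mean28, sd28, mean7


def run_trial(
    profiles: Sequence[ParticipantProfile],
    bank: MessageBank,
    engine: ThompsonSampler | None,
    config: SimConfig,
    seed: int = 0,
) -> TrialLog:
    """Simulate the full trial day by day.

    ``engine`` serves the adaptive arm (pooled across its participants) and
    is cold-started by the caller; it may be ``None`` only if no adaptive
    participants exist. Determinism: a fixed ``seed`` yields byte-identical
    logs, via four independent substreams (step noise, missingness, random
    policy + text sampling, engine sampling).

    Causality per day *t*: morning decisions for every participant are made
    first, against the posterior as of that morning and step data through
    day t-1; the day's counts are then realised (carrying the effect of the
    message sent on day t-1); finally day t-1's decisions receive today's
    count as their reward and the engine is updated, so the new information
    influences decisions from day t+1 onward.
    """
    config.validate()
    if engine is None and any(p.arm == "adaptive" for p in profiles):
        raise TrialSetupError("adaptive participants present but no engine supplied")
    ss = np.random.SeedSequence(seed).spawn(4)
    rng_steps, rng_missing, rng_policy, rng_engine = (
        np.random.default_rng(s) for s in ss
    )
    n_days = config.n_days
    ref_mean = 3200.0

    runtimes = [_ParticipantRuntime(p) for p in profiles]
    observed_masks = {
        rt.profile.id: apply_missingness(np.zeros(n_days), rt.profile, rng_missing)
        for rt in runtimes
    }

    decision_rows: list[dict] = []
    step_rows: list[dict] = []

    def _decision_row(pid, day, kind, policy, action=None, fb_id="", mo_id=""):
        decision_rows.append(
            {
                "participant_id": pid,
                "day": day,
                "kind": kind,
                "policy": policy,
                "feedback_code": action.feedback if action else pd.NA,
                "motivation_code": action.motivation if action else pd.NA,
                "slot": action.slot if action else pd.NA,
                "feedback_template": fb_id,
                "motivation_template": mo_id,
                "reward_observed": False,
                "raw_next_day_steps": pd.NA,
            }
        )
        return len(decision_rows) - 1

    for day in range(n_days):
        # Phase 1: morning decisions for everyone.
        for rt in runtimes:
            p = rt.profile
            rt.today_decision = None
            if day % MOOD_PERIOD == MOOD_PERIOD - 1:
                _decision_row(p.id, day, "mood", p.arm)
            if day > 0 and rt.yesterday_missing:
                _decision_row(p.id, day, "reminder", p.arm)
            if p.arm not in ("random", "adaptive"):
                continue
            context = None
            if p.arm == "random":
                action = random_policy(rng_policy)
            else:
                mean28, _, mean7 = rt.trailing_stats(day)
                prev_steps = (
                    rt.last_observed_steps
                    if rt.last_observed_steps is not None
                    else ref_mean
                )
                context = Context(
                    age=p.age,
                    sex=p.sex,
                    phq8=p.phq8,
                    language=int(p.language == "es"),
                    prev_day_steps=float(prev_steps),
                    trailing7_mean=float(mean7 if np.isfinite(mean7) else prev_steps),
                    missing_flag=int(rt.yesterday_missing),
                    day=day,
                    prev_action=rt.prev_action,
                )
                action = engine.select(context, rng_engine)
            fb = sample_template(bank, FEEDBACK, action.feedback, p.language, rng_policy)
            mo = sample_template(
                bank, MOTIVATION, action.motivation, p.language, rng_policy
            )
            row_idx = _decision_row(p.id, day, "daily", p.arm, action, fb.id, mo.id)
            rt.today_decision = (context, action, row_idx)

        # Phase 2: realise the day's counts and settle yesterday's rewards.
        for rt in runtimes:
            p = rt.profile
            scale = p.residual_sd * np.sqrt(1.0 - p.ar1_rho**2)
            if day == 0:
                rt.eps_prev = p.residual_sd * rng_steps.standard_normal()
            else:
                rt.eps_prev = (
                    p.ar1_rho * rt.eps_prev + scale * rng_steps.standard_normal()
                )
            steps = step_model(p, day, rt.prev_action, noise=rt.eps_prev)
            observed = bool(observed_masks[p.id][day])
            step_rows.append(
                {
                    "participant_id": p.id,
                    "day": day,
                    "steps": steps,
                    "observed": observed,
                    "arm": p.arm,
                    "recruitment_source": p.recruitment_source,
                }
            )
            if rt.rewardable is not None:
                context, action, row_idx = rt.rewardable
                if observed:
                    decision_rows[row_idx]["reward_observed"] = True
                    decision_rows[row_idx]["raw_next_day_steps"] = steps
                    if p.arm == "adaptive":
                        mean28, sd28, _ = rt.trailing_stats(day)
                        base = mean28 if np.isfinite(mean28) else ref_mean
                        engine.update(context, action, compute_reward(steps, base, sd28))
                elif p.arm == "adaptive":
                    engine.update(context, action, None)
            if observed:
                rt.window.append((day, steps))
                rt.last_observed_steps = float(steps)
            rt.yesterday_missing = not observed
            rt.rewardable = rt.today_decision
            rt.prev_action = rt.today_decision[1] if rt.today_decision else None

    decisions = pd.DataFrame(decision_rows)
    decisions = decisions.astype(
        {
            "feedback_code": "Int64",
            "motivation_code": "Int64",
            "slot": "Int64",
            "raw_next_day_steps": "Int64",
        }
    )
    steps_df = pd.DataFrame(step_rows)
    return TrialLog(decisions=decisions, steps=steps_df)


def apply_quality_filters(
    step_log: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the analysis set and an exclusion report.

    Exclusion rules, applied independently per participant:

    * ``no_step_data`` — zero observed days;
    * ``under_28_days`` — 1-27 observed days (at least 28 are required);
    * ``implausible_high_counts`` — strictly more than 25% of *observed*
      days exceed 20,000 steps.
    """
    report_cols = [
        "participant_id",
        "reason",
        "n_observed",
        "n_over_20k",
        "frac_over_20k",
    ]
    if step_log.empty:
        warnings.warn("empty step log: analysis set is empty", stacklevel=2)
        return step_log.copy(), pd.DataFrame(columns=report_cols)
    rows = []
    for pid, grp in step_log.groupby("participant_id", sort=True):
        obs = grp[grp["observed"].astype(bool)]
        n_obs = len(obs)
        n_hi = int((obs["steps"] > HIGH_COUNT_THRESHOLD).sum())
        frac_hi = n_hi / n_obs if n_obs else 0.0
        reason = None
        if n_obs == 0:
            reason = "no_step_data"
        elif n_obs < MIN_OBSERVED_DAYS:
            reason = "under_28_days"
        elif frac_hi > HIGH_COUNT_FRACTION:
            reason = "implausible_high_counts"
        if reason:
            rows.append(
                {
                    "participant_id": pid,
                    "reason": reason,
                    "n_observed": n_obs,
                    "n_over_20k": n_hi,
                    "frac_over_20k": round(frac_hi, 6),
                }
            )
    exclusions = pd.DataFrame(rows, columns=report_cols)
    keep = ~step_log["participant_id"].isin(exclusions["participant_id"])
    return step_log[keep].reset_index(drop=True), exclusions
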