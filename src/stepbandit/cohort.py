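"""Synthetic participant cohort and daily step-count generator.

The generator emulates a 24-week (168-day), 3-arm mobile-messaging trial in
adults with diabetes and elevated depressive symptoms:

* person-level heterogeneity through a Gaussian random intercept ``b_i``
  with very large between-person variance (default 5.42e6 steps^2, i.e.
  SD ~2328 steps);
* arm-specific linear secular drift in mean daily steps ("drift" mode), or
  heterogeneous per-message-category responsiveness ``theta_i`` whose
  benefit must be discovered by the bandit ("responsive" mode);
* AR(1) day-level noise (iid by default) floored at zero and rounded to
  integer counts;
* arm-specific missing-day burdens from phone-to-server transmission gaps,
  missing completely at random by default.

Defaults reproduce the emulated trial's marginals: 168 participants split
57/56/55 across control/random/adaptive, 24% Spanish speakers, 37.5%
clinic-recruited, day-1 arm means ~3200-3700 steps with cross-sectional SDs
~2900, and mean missing-day counts 26/20/14 per arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ARMS = ("control", "random", "adaptive")
N_DAYS = 168

_EFFECT_DIMS = {"feedback": 5, "motivation": 4, "slot": 4}


class ConfigError(ValueError):
    """A simulation configuration field is invalid; names the field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Baselines, the random-intercept variance, arm drifts, arm sizes and
    missing-day means are the emulated trial's values; the residual SD is
    calibrated so that the day-1 cross-sectional SD, sqrt(sigma_b^2 +
    residual_sd^2) ~ 2890 steps, matches the observed per-arm day-1 SDs
    (~2250-3275 steps).
    """

    n_participants: int = 168
    n_days: int = N_DAYS
    arm_sizes: tuple[int, int, int] = (57, 56, 55)  # control, random, adaptive
    arm_baselines: dict = field(
        default_factory=lambda: {
            "adaptive": 3196.79,
            "control": 3480.11,
            "random": 3697.71,
        }
    )
    sigma_b2: float = 5_419_080.25
    residual_sd: float = 1718.0
    ar1_rho: float = 0.0
    arm_drifts: dict = field(
        default_factory=lambda: {"adaptive": 3.61, "control": 0.81, "random": 0.35}
    )
    #: "drift": arm trends imposed directly (for evaluation testing);
    #: "responsive": trends must emerge from message effects + learning.
    effect_mode: str = "drift"
    #: responsive mode: SD of the per-person, per-category step effects and
    #: the symmetric bound they are clipped to (steps/day).
    effect_sd: float = 150.0
    effect_bound: float = 500.0
    #: responsive mode: population-mean effect per category (code 0 fixed 0).
    effect_means: dict = field(
        default_factory=lambda: {
            "feedback": (0.0, 0.0, 0.0, 0.0, 0.0),
            "motivation": (0.0, 0.0, 0.0, 0.0),
            "slot": (0.0, 0.0, 0.0, 0.0),
        }
    )
    spanish_fraction: float = 40 / 168
    clinic_fraction: float = 63 / 168
    female_fraction: float = 0.62
    age_mean: float = 49.0
    age_sd: float = 12.1
    phq8_mean: float = 10.88
    phq8_sd: float = 6.42
    missing_days_mean: dict = field(
        default_factory=lambda: {"control": 26.0, "random": 20.0, "adaptive": 14.0}
    )
    #: mean length of missing-day bursts; 1.0 means independent days (MCAR).
    missing_burst_mean: float = 1.0
    step_goal: int = 4000
    seed: int | None = None

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants", "must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days", "must be >= 1")
        if len(self.arm_sizes) != 3 or any(s < 0 for s in self.arm_sizes):
            raise ConfigError("arm_sizes", "need 3 non-negative sizes")
        if sum(self.arm_sizes) != self.n_participants:
            raise ConfigError(
                "arm_sizes",
                f"sum {sum(self.arm_sizes)} != n_participants {self.n_participants}",
            )
        if self.sigma_b2 < 0:
            raise ConfigError("sigma_b2", "must be >= 0")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd", "must be >= 0")
        if not -1 < self.ar1_rho < 1:
            raise ConfigError("ar1_rho", "must be in (-1, 1)")
        if self.effect_mode not in ("drift", "responsive"):
            raise ConfigError("effect_mode", "must be 'drift' or 'responsive'")
        for name, frac in (
            ("spanish_fraction", self.spanish_fraction),
            ("clinic_fraction", self.clinic_fraction),
            ("female_fraction", self.female_fraction),
        ):
            if not 0 <= frac <= 1:
                raise ConfigError(name, "must be in [0, 1]")
        for arm in ARMS:
            if arm not in self.arm_baselines:
                raise ConfigError("arm_baselines", f"missing arm {arm!r}")
            if arm not in self.arm_drifts:
                raise ConfigError("arm_drifts", f"missing arm {arm!r}")
            m = self.missing_days_mean.get(arm)
            if m is None or not 0 <= m < self.n_days:
                raise ConfigError("missing_days_mean", f"{arm}: need 0 <= mean < n_days")
        if self.missing_burst_mean < 1:
            raise ConfigError("missing_burst_mean", "must be >= 1")


@dataclass
class ParticipantProfile:
    """One simulated person: covariates, latent level and responsiveness."""

    id: str
    language: str  # "en" | "es"
    arm: str
    recruitment_source: str  # "clinic" | "web"
    age: float
    sex: int  # 1 = female, 0 = male
    phq8: int
    baseline_level: float  # random intercept b_i, steps
    drift: float  # secular trend, steps/day
    responsiveness: dict  # per-dimension per-category step effects
    missing_prob: float
    residual_sd: float
    ar1_rho: float
    missing_burst_mean: float = 1.0

    def effect_of(self, action) -> float:
        """Additive next-day step effect of an action (0 for no action)."""
        if action is None:
            return 0.0
        total = 0.0
        for dim in _EFFECT_DIMS:
            total += float(self.responsiveness[dim][action.component(dim)])
        return total


def _draw_intercept(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw re-drawn while negative (people cannot un-walk)."""
    b = rng.normal(mean, sd)
    while b < 0:
        b = rng.normal(mean, sd)
    return float(b)


def generate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[ParticipantProfile]:
    """Draw a full cohort of participant profiles.

    Arm labels are assigned exactly at the configured sizes (a shuffled
    multiset), so the default yields the 57/56/55 split; the trial runner's
    stratified block randomisation can later re-assign arms.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sigma_b = float(np.sqrt(config.sigma_b2))
    arm_labels = np.repeat(ARMS, config.arm_sizes)
    rng.shuffle(arm_labels)
    profiles = []
    width = len(str(config.n_participants))
    for i in range(config.n_participants):
        arm = str(arm_labels[i])
        language = "es" if rng.random() < config.spanish_fraction else "en"
        source = "clinic" if rng.random() < config.clinic_fraction else "web"
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 90))
        sex = int(rng.random() < config.female_fraction)
        phq8 = int(np.clip(round(rng.normal(config.phq8_mean, config.phq8_sd)), 0, 24))
        baseline = _draw_intercept(rng, config.arm_baselines[arm], sigma_b)
        responsiveness = {}
        for dim, k in _EFFECT_DIMS.items():
            if config.effect_mode == "responsive":
                means = np.asarray(config.effect_means[dim], dtype=float)
                theta = rng.normal(means, config.effect_sd)
                theta = np.clip(theta, -config.effect_bound, config.effect_bound)
            else:
                theta = np.zeros(k)
            theta[0] = 0.0  # code 0 means "no message": no effect by convention
            responsiveness[dim] = theta
        profiles.append(
            ParticipantProfile(
                id=f"P{i + 1:0{width}d}",
                language=language,
                arm=arm,
                recruitment_source=source,
                age=age,
                sex=sex,
                phq8=phq8,
                baseline_level=baseline,
                drift=float(config.arm_drifts[arm]),
                responsiveness=responsiveness,
                missing_prob=float(config.missing_days_mean[arm]) / config.n_days,
                residual_sd=float(config.residual_sd),
                ar1_rho=float(config.ar1_rho),
                missing_burst_mean=float(config.missing_burst_mean),
            )
        )
    return profiles


def step_model(
    profile: ParticipantProfile,
    day: int,
    action=None,
    rng: np.random.Generator | None = None,
    noise: float | None = None,
) -> int:
    """One day's step count: max(0, round(b_i + drift*day + effects + noise)).

    ``action`` is the action whose effect lands on this day (i.e. the
    message sent the previous morning); ``None`` or all-zero codes
    contribute nothing. ``noise`` overrides the random draw — callers
    simulating AR(1) trajectories supply the correlated noise themselves.
    """
    if not 0 <= day:
        raise ValueError("day must be >= 0")
    if noise is None:
        if profile.residual_sd > 0:
            if rng is None:
                rng = np.random.default_rng()
            noise = float(rng.normal(0.0, profile.residual_sd))
        else:
            noise = 0.0
    mean = profile.baseline_level + profile.drift * day + profile.effect_of(action)
    return int(max(0, round(mean + noise)))


def ar1_noise(
    n_days: int, sd: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise path with marginal SD ``sd``."""
    z = rng.standard_normal(n_days)
    eps = np.empty(n_days)
    if n_days == 0:
        return eps
    eps[0] = sd * z[0]
    scale = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_days):
        eps[t] = rho * eps[t - 1] + scale * z[t]
    return eps


def simulate_trajectory(
    profile: ParticipantProfile,
    n_days: int,
    rng: np.random.Generator,
    actions: Sequence | None = None,
) -> np.ndarray:
    """A full step trajectory; ``actions[t]`` is the effect landing on day t."""
    eps = ar1_noise(n_days, profile.residual_sd, profile.ar1_rho, rng)
    out = np.empty(n_days, dtype=int)
    for t in range(n_days):
        action = actions[t] if actions is not None else None
        out[t] = step_model(profile, t, action, noise=eps[t])
    return out


def apply_missingness(
    steps: np.ndarray, profile: ParticipantProfile, rng: np.random.Generator
) -> np.ndarray:
    """Observed-day flags for a complete trajectory.

    Default is per-day Bernoulli(missing_prob), i.e. missing completely at
    random. With ``missing_burst_mean > 1`` transmission gaps arrive as
    geometric bursts of that mean length, with the start rate scaled to
    keep the expected number of missing days at the configured mean.
    Flags never alter the stored step values.
    """
    n = len(steps)
    p = profile.missing_prob
    L = profile.missing_burst_mean
    if p <= 0:
        return np.ones(n, dtype=bool)
    if L <= 1.0:
        return rng.random(n) >= p
    observed = np.ones(n, dtype=bool)
    start_rate = p / L
    t = 0
    while t < n:
        if rng.random() < start_rate:
            gap = int(rng.geometric(1.0 / L))
            observed[t : t + gap] = False
            t += gap
        else:
            t += 1
    return observed


def simulate_step_log(
    profiles: Sequence[ParticipantProfile],
    n_days: int,
    rng: np.random.Generator,
    with_missingness: bool = True,
) -> pd.DataFrame:
    """Vectorised drift-mode step log (no message effects).

    In drift mode the daily decisions carry zero step effect, so this is
    distributionally identical to running the full trial loop — and fast
    enough for replicate-based recovery studies. Returns a long-format
    frame: participant_id, day, steps, observed, arm, recruitment_source.
    """
    n = len(profiles)
    b = np.array([p.baseline_level for p in profiles])
    drift = np.array([p.drift for p in profiles])
    sd = np.array([p.residual_sd for p in profiles])
    rho = np.array([p.ar1_rho for p in profiles])
    z = rng.standard_normal((n, n_days))
    eps = np.empty((n, n_days))
    eps[:, 0] = sd * z[:, 0]
    scale = sd * np.sqrt(1.0 - rho**2)
    for t in range(1, n_days):
        eps[:, t] = rho * eps[:, t - 1] + scale * z[:, t]
    days = np.arange(n_days)
    latent = b[:, None] + drift[:, None] * days[None, :] + eps
    steps = np.maximum(0, np.round(latent)).astype(int)
    if with_missingness:
        observed = np.stack(
            [apply_missingness(steps[i], profiles[i], rng) for i in range(n)]
        )
    else:
        observed = np.ones((n, n_days), dtype=bool)
    return pd.DataFrame(
        {
            "participant_id": np.repeat([p.id for p in profiles], n_days),
            "day": np.tile(days, n),
            "steps": steps.ravel(),
            "observed": observed.ravel(),
            "arm": np.repeat([p.arm for p in profiles], n_days),
            "recruitment_source": np.repeat(
                [p.recruitment_source for p in profiles], n_days
            ),
        }
    )


def profiles_to_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    """Flatten profiles for CSV export (responsiveness as per-code columns)."""
    rows = []
    for p in profiles:
        row = {
            "participant_id": p.id,
            "language": p.language,
            "arm": p.arm,
            "recruitment_source": p.recruitment_source,
            "age": p.age,
            "sex": p.sex,
            "phq8": p.phq8,
            "baseline_level": p.baseline_level,
            "drift": p.drift,
            "missing_prob": p.missing_prob,
            "residual_sd": p.residual_sd,
            "ar1_rho": p.ar1_rho,
        }
        for dim, k in _EFFECT_DIMS.items():
            for c in range(k):
                row[f"effect_{dim}_{c}"] = float(p.responsiveness[dim][c])
        rows.append(row)
    return pd.DataFrame(rows)
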