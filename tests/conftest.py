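"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import stepbandit as sb
from stepbandit.bandit import ActionTriple, Context, ContextEncoder, compute_reward
from stepbandit.cohort import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bank():
    return sb.default_bank()


@pytest.fixture
def small_config():
    """A fast trial: 12 participants, 6 weeks, missingness scaled to length."""
    return SimConfig(
        n_participants=12,
        arm_sizes=(4, 4, 4),
        n_days=42,
        missing_days_mean={"control": 5.0, "random": 4.0, "adaptive": 3.0},
    )


def run_planted_environment(
    seed: int,
    best: ActionTriple,
    n_participants: int = 16,
    n_days: int = 168,
    effect: float = 600.0,
    noise_sd: float = 400.0,
    base: float = 3000.0,
) -> np.ndarray:
    """Simulate the bandit against a single planted best action.

    Steps are ``base + effect * [yesterday's action == best] + noise``; the
    policy sees standardised next-day rewards exactly as in the trial loop.
    Returns the best-action selection frequency in each quarter of the run.
    """
    rng = np.random.default_rng(seed)
    engine = sb.ThompsonSampler(encoder=ContextEncoder.minimal())
    hits = np.zeros(4)
    ctx = Context()
    history: list[list[float]] = [[] for _ in range(n_participants)]
    pending: list[ActionTriple | None] = [None] * n_participants
    for t in range(n_days):
        quarter = min(3, t * 4 // n_days)
        for i in range(n_participants):
            action = engine.select(ctx, rng)
            hits[quarter] += action == best
            prev = pending[i]
            bonus = effect if (prev is not None and prev == best) else 0.0
            y = max(0.0, base + bonus + rng.normal(0.0, noise_sd))
            if prev is not None:
                window = history[i][-28:]
                mean = float(np.mean(window)) if window else base
                sd = float(np.std(window, ddof=1)) if len(window) > 1 else 0.0
                engine.update(ctx, prev, compute_reward(y, mean, sd))
            history[i].append(y)
            pending[i] = action
    return hits / (n_participants * n_days / 4)


@pytest.fixture
def planted_env_runner():
    return run_planted_environment
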