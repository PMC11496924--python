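"""Thompson-sampling contextual bandit over message category and timing.

Each simulated morning the policy picks, for one participant, an
:class:`ActionTriple` — feedback category (5 options), motivational category
(4 options) and delivery time slot (4 three-hour windows between 8 AM and
8 PM) — aiming to maximise the participant's *next-day* step count.

The reward model is a factored Bayesian linear regression: three independent
decision dimensions (feedback, motivation, slot) each regress the
standardised next-day step count on the interaction of the shared context
vector with the dimension's action one-hot. Factoring keeps the model
sample-efficient at trial scale (~55 adaptive participants) compared to a
joint 5x4x4 = 80-arm bandit. The model is pooled across participants, with
person-level covariates (age, sex, depression score, language) in the
context, so early participants' data informs later decisions for everyone.

Thompson sampling draws one coefficient vector per dimension from the
Gaussian posterior and plays the argmax of sampled predicted reward. With
the symmetric zero-mean prior the cold-start selection is exactly uniform,
which reproduces the required random cold-start behaviour without a special
case.

Rewards are z-scores of next-day steps against the participant's trailing
28-day observed mean/SD, clipped to [-5, 5]; standardisation stops
high-baseline walkers from dominating the pooled regression. Days with no
observed next-day count contribute no update (the decision is still logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np

logger = logging.getLogger(__name__)

#: Decision dimensions and their number of actions.
ACTION_DIMS: dict[str, int] = {"feedback": 5, "motivation": 4, "slot": 4}

#: Delivery windows (start hour, end hour) for slots 0-3.
SLOT_WINDOWS = ((8, 11), (11, 14), (14, 17), (17, 20))

#: Clipping bound for standardised rewards.
REWARD_CLIP = 5.0


class EncodingError(ValueError):
    """Context vector dimensions do not match the posterior state."""


@dataclass(frozen=True)
class ActionTriple:
    """One day's decision: feedback category, motivation category, time slot."""

    feedback: int
    motivation: int
    slot: int

    def __post_init__(self):
        for name, k in ACTION_DIMS.items():
            v = getattr(self, name)
            if not (0 <= int(v) < k):
                raise ValueError(f"{name} code {v} outside [0, {k})")

    def component(self, dim: str) -> int:
        return int(getattr(self, dim))


@dataclass(frozen=True)
class Context:
    """Raw per-decision side information; encoded by :class:`ContextEncoder`.

    ``prev_day_steps`` and ``trailing7_mean`` carry the last *observed*
    values; ``missing_flag`` marks that yesterday's count was unobserved.
    """

    age: float = 49.0
    sex: int = 0
    phq8: float = 10.9
    language: int = 0
    prev_day_steps: float = 3200.0
    trailing7_mean: float = 3200.0
    missing_flag: int = 0
    day: int = 0
    prev_action: ActionTriple | None = None


@dataclass(frozen=True)
class Reward:
    """Standardised next-day step count (z against trailing 28-day stats)."""

    value: float
    raw_steps: int


def compute_reward(
    next_day_steps: float,
    trailing_mean: float,
    trailing_sd: float,
    fallback_sd: float = 2900.0,
) -> Reward:
    """z-score next-day steps against trailing statistics, clipped to +-5."""
    sd = trailing_sd if trailing_sd > 1e-9 else fallback_sd
    z = (float(next_day_steps) - float(trailing_mean)) / sd
    z = float(np.clip(z, -REWARD_CLIP, REWARD_CLIP))
    return Reward(value=z, raw_steps=int(round(next_day_steps)))


class ContextEncoder:
    """Maps a :class:`Context` to the fixed-length feature vector.

    The full encoding is: intercept, standardised age, sex code,
    standardised PHQ-8, language code, z-scored previous-day steps and
    trailing 7-day mean (against cohort reference level/scale), a
    missing-yesterday flag, day/168, and the previous day's action one-hots
    (5 + 4 + 4). ``minimal()`` gives an intercept-only encoder, useful for
    small planted-effect environments.
    """

    AGE_MEAN, AGE_SD = 49.0, 12.1
    PHQ_MEAN, PHQ_SD = 10.9, 6.4
    STEP_REF_MEAN, STEP_REF_SD = 3200.0, 2900.0
    N_DAYS = 168

    def __init__(self, include_person: bool = True, include_history: bool = True):
        self.include_person = include_person
        self.include_history = include_history
        n = 1
        if include_person:
            n += 4
        if include_history:
            n += 4 + sum(ACTION_DIMS.values())
        self._n_features = n

    @classmethod
    def minimal(cls) -> "ContextEncoder":
        return cls(include_person=False, include_history=False)

    @property
    def n_features(self) -> int:
        return self._n_features

    def encode(self, context: Context) -> np.ndarray:
        x = [1.0]
        if self.include_person:
            x += [
                (context.age - self.AGE_MEAN) / self.AGE_SD,
                float(context.sex),
                (context.phq8 - self.PHQ_MEAN) / self.PHQ_SD,
                float(context.language),
            ]
        if self.include_history:
            x += [
                (context.prev_day_steps - self.STEP_REF_MEAN) / self.STEP_REF_SD,
                (context.trailing7_mean - self.STEP_REF_MEAN) / self.STEP_REF_SD,
                float(context.missing_flag),
                context.day / self.N_DAYS,
            ]
            for dim, k in ACTION_DIMS.items():
                onehot = np.zeros(k)
                if context.prev_action is not None:
                    onehot[context.prev_action.component(dim)] = 1.0
                x += list(onehot)
        return np.asarray(x, dtype=float)


@dataclass
class PosteriorState:
    """Sufficient statistics of the per-dimension Bayesian linear models.

    For each decision dimension ``d`` with ``K_d`` actions and context
    length ``p``, ``mean[d]`` and ``precision[d]`` are the posterior mean
    and precision of the ``K_d * p`` coefficient vector over the
    [action one-hot x context] interaction design. ``noise_var`` is the
    fixed observation noise of the standardised reward.
    """

    mean: dict[str, np.ndarray]
    precision: dict[str, np.ndarray]
    noise_var: float
    n_features: int
    _chol: dict[str, np.ndarray] = field(default_factory=dict, repr=False, compare=False)

    def copy(self) -> "PosteriorState":
        return PosteriorState(
            mean={d: m.copy() for d, m in self.mean.items()},
            precision={d: p.copy() for d, p in self.precision.items()},
            noise_var=self.noise_var,
            n_features=self.n_features,
        )

    def chol(self, dim: str) -> np.ndarray:
        """Cached Cholesky factor of the precision matrix."""
        if dim not in self._chol:
            self._chol[dim] = np.linalg.cholesky(self.precision[dim])
        return self._chol[dim]


def cold_start_state(
    n_features: int, prior_scale: float = 1.0, noise_var: float = 1.0
) -> PosteriorState:
    """Symmetric zero-mean prior: precision = prior_scale^-1 * identity.

    With no data the predictive distribution is identical across actions in
    every dimension, so the first Thompson selections are uniform — the
    cold start is "a randomly selected message" by construction.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not prior_scale > 0:
        raise ValueError("prior_scale must be positive")
    if not noise_var > 0:
        raise ValueError("noise_var must be positive")
    mean = {}
    precision = {}
    for dim, k in ACTION_DIMS.items():
        q = k * n_features
        mean[dim] = np.zeros(q)
        precision[dim] = np.eye(q) / prior_scale
    return PosteriorState(
        mean=mean, precision=precision, noise_var=float(noise_var), n_features=n_features
    )


def _check_context(state: PosteriorState, context_vec: np.ndarray) -> np.ndarray:
    x = np.asarray(context_vec, dtype=float).ravel()
    if x.shape[0] != state.n_features:
        raise EncodingError(
            f"context length {x.shape[0]} != state n_features {state.n_features}"
        )
    return x


def _design(x: np.ndarray, action_code: int, n_actions: int) -> np.ndarray:
    """[action one-hot (x) context] interaction row."""
    row = np.zeros(n_actions * x.shape[0])
    p = x.shape[0]
    row[action_code * p : (action_code + 1) * p] = x
    return row


def _sample_coefficients(
    state: PosteriorState, dim: str, rng: np.random.Generator
) -> np.ndarray:
    """One draw from N(mean, precision^-1) via the cached Cholesky factor."""
    L = state.chol(dim)
    z = rng.standard_normal(state.mean[dim].shape[0])
    # precision = L L^T  =>  covariance^{1/2} draw solves L^T u = z
    u = np.linalg.solve(L.T, z)
    return state.mean[dim] + u


def _argmax_tiebreak(values: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(values == values.max())
    if best.shape[0] == 1:
        return int(best[0])
    return int(rng.choice(best))


def select_action(
    state: PosteriorState, context_vec: np.ndarray, rng: np.random.Generator
) -> ActionTriple:
    """Thompson-sample each dimension and play the per-dimension argmax."""
    x = _check_context(state, context_vec)
    p = x.shape[0]
    chosen = {}
    for dim, k in ACTION_DIMS.items():
        w = _sample_coefficients(state, dim, rng)
        predicted = w.reshape(k, p) @ x
        chosen[dim] = _argmax_tiebreak(predicted, rng)
    return ActionTriple(**chosen)


def update_posterior(
    state: PosteriorState,
    context_vec: np.ndarray,
    action: ActionTriple,
    reward: Reward | None,
) -> PosteriorState:
    """Conjugate Gaussian update of each dimension's (mean, precision).

    Unobserved rewards (``None``) skip the update — the original state is
    returned unchanged and the skip is logged. The precision can only grow
    (Loewner order), so repeated updates never lose information.
    """
    if reward is None:
        logger.debug("skipping posterior update: reward unobserved")
        return state
    x = _check_context(state, context_vec)
    new = state.copy()
    for dim, k in ACTION_DIMS.items():
        row = _design(x, action.component(dim), k)
        prec = new.precision[dim]
        prec += np.outer(row, row) / state.noise_var
        rhs = state.precision[dim] @ state.mean[dim] + row * (
            reward.value / state.noise_var
        )
        new.mean[dim] = np.linalg.solve(prec, rhs)
    return new


def action_probabilities(
    state: PosteriorState,
    context_vec: np.ndarray,
    n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Monte-Carlo estimate of the Thompson selection distribution.

    Returns, per dimension, a probability table over actions summing to 1.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    x = _check_context(state, context_vec)
    p = x.shape[0]
    tables = {dim: np.zeros(k) for dim, k in ACTION_DIMS.items()}
    for _ in range(n_draws):
        for dim, k in ACTION_DIMS.items():
            w = _sample_coefficients(state, dim, rng)
            predicted = w.reshape(k, p) @ x
            tables[dim][_argmax_tiebreak(predicted, rng)] += 1
    return {dim: t / n_draws for dim, t in tables.items()}


def random_policy(rng: np.random.Generator) -> ActionTriple:
    """The Random arm's policy: independent uniform draws per component."""
    return ActionTriple(
        feedback=int(rng.integers(ACTION_DIMS["feedback"])),
        motivation=int(rng.integers(ACTION_DIMS["motivation"])),
        slot=int(rng.integers(ACTION_DIMS["slot"])),
    )


class ThompsonSampler:
    """Stateful wrapper tying the encoder and posterior together.

    One instance serves a whole trial arm (the reward model is pooled across
    participants). The functional operations above remain the primitive API;
    this class just owns the evolving :class:`PosteriorState`.
    """

    def __init__(
        self,
        encoder: ContextEncoder | None = None,
        prior_scale: float = 1.0,
        noise_var: float = 1.0,
    ):
        self.encoder = encoder if encoder is not None else ContextEncoder()
        self.state = cold_start_state(
            self.encoder.n_features, prior_scale=prior_scale, noise_var=noise_var
        )

    def select(self, context: Context, rng: np.random.Generator) -> ActionTriple:
        return select_action(self.state, self.encoder.encode(context), rng)

    def update(
        self, context: Context, action: ActionTriple, reward: Reward | None
    ) -> None:
        self.state = update_posterior(
            self.state, self.encoder.encode(context), action, reward
        )
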