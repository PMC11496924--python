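"""Randomisation, the trial day loop and the analysis-set filters."""

import numpy as np
import pandas as pd
import pytest

import stepbandit as sb
from stepbandit.cohort import ARMS, SimConfig, generate_cohort
from stepbandit.trial import (
    apply_assignments,
    apply_quality_filters,
    randomize,
    run_trial,
)


def _profiles(n, seed=0, **cfg_kwargs):
    sizes = (n - 2 * (n // 3), n // 3, n // 3)
    cfg = SimConfig(n_participants=n, arm_sizes=sizes, **cfg_kwargs)
    return cfg, generate_cohort(cfg, np.random.default_rng(seed))


class TestRandomize:
    def test_nine_per_stratum_gives_three_per_arm(self):
        cfg, profiles = _profiles(9, seed=1)
        for p in profiles:
            p.language = "en"
        counts = pd.Series([a.arm for a in randomize(profiles, seed=4)]).value_counts()
        assert all(counts[arm] == 3 for arm in ARMS)

    def test_every_complete_block_is_a_permutation(self):
        cfg, profiles = _profiles(30, seed=2)
        assignments = randomize(profiles, seed=9)
        for stratum in ("en", "es"):
            arms = [a.arm for a in assignments if a.stratum == stratum]
            for i in range(0, 3 * (len(arms) // 3), 3):
                assert sorted(arms[i : i + 3]) == sorted(ARMS)

    def test_imbalance_bounded_by_incomplete_blocks(self):
        cfg, profiles = _profiles(168, seed=3)
        for seed in range(50):
            counts = pd.Series(
                [a.arm for a in randomize(profiles, seed=seed)]
            ).value_counts()
            assert counts.max() - counts.min() <= 2

    def test_deterministic_under_seed(self):
        cfg, profiles = _profiles(20, seed=4)
        assert randomize(profiles, seed=5) == randomize(profiles, seed=5)

    def test_apply_assignments_recenters_intercepts(self):
        cfg, profiles = _profiles(12, seed=5)
        assignments = randomize(profiles, seed=1)
        rearmed = apply_assignments(profiles, assignments, cfg)
        by_id = {a.participant_id: a.arm for a in assignments}
        for old, new in zip(profiles, rearmed):
            assert new.arm == by_id[old.id]
            dev_old = old.baseline_level - cfg.arm_baselines[old.arm]
            dev_new = new.baseline_level - cfg.arm_baselines[new.arm]
            assert dev_new == pytest.approx(dev_old) or new.baseline_level == 0.0
            assert new.drift == cfg.arm_drifts[new.arm]


@pytest.fixture(scope="module")
def tiny_trial():
    cfg = SimConfig(
        n_participants=3,
        arm_sizes=(1, 1, 1),
        n_days=168,
        missing_days_mean={"control": 10.0, "random": 8.0, "adaptive": 6.0},
    )
    profiles = generate_cohort(cfg, np.random.default_rng(0))
    log = run_trial(profiles, sb.default_bank(), sb.ThompsonSampler(), cfg, seed=6)
    return cfg, profiles, log


class TestRunTrial:
    def test_control_gets_only_weekly_mood_messages(self, tiny_trial):
        _, _, log = tiny_trial
        control = log.decisions[log.decisions.policy == "control"]
        assert (control.kind != "daily").all()
        assert len(control[control.kind == "mood"]) == 24  # 168 / 7

    def test_random_and_adaptive_decide_daily(self, tiny_trial):
        _, _, log = tiny_trial
        for policy in ("random", "adaptive"):
            daily = log.decisions[
                (log.decisions.policy == policy) & (log.decisions.kind == "daily")
            ]
            assert len(daily) == 168
            assert daily.feedback_code.notna().all()
            assert daily.motivation_code.notna().all()
            assert daily.slot.between(0, 3).all()

    def test_rewards_recorded_for_observed_next_days(self, tiny_trial):
        _, _, log = tiny_trial
        daily = log.decisions[log.decisions.kind == "daily"]
        rewarded = daily[daily.reward_observed]
        assert len(rewarded) > 0
        assert rewarded.raw_next_day_steps.notna().all()
        # the day-167 decision has no next day to be rewarded on
        assert not daily[daily.day == 167].reward_observed.any()
        steps = log.steps.set_index(["participant_id", "day"]).steps
        for _, row in rewarded.head(25).iterrows():
            assert (
                steps.loc[(row.participant_id, row.day + 1)]
                == row.raw_next_day_steps
            )

    def test_step_log_is_complete(self, tiny_trial):
        cfg, profiles, log = tiny_trial
        assert (log.steps.groupby("participant_id").size() == cfg.n_days).all()
        assert (log.steps.steps >= 0).all()

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(
            n_participants=6,
            arm_sizes=(2, 2, 2),
            n_days=30,
            missing_days_mean={"control": 3.0, "random": 2.0, "adaptive": 2.0},
        )
        profiles = generate_cohort(cfg, np.random.default_rng(1))
        outs = []
        for run in range(2):
            log = run_trial(profiles, sb.default_bank(), sb.ThompsonSampler(), cfg, seed=13)
            d = tmp_path / f"run{run}"
            log.write(d)
            outs.append(d)
        for name in ("decision_log.csv", "step_log.csv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_adaptive_requires_engine(self):
        cfg, profiles = _profiles(6, seed=2, n_days=10,
                                  missing_days_mean={"control": 1.0, "random": 1.0, "adaptive": 1.0})
        with pytest.raises(Exception):
            run_trial(profiles, sb.default_bank(), None, cfg, seed=0)

    def test_adaptive_learns_to_send_feedback_when_it_helps(self):
        """Planted positive feedback effects pull the adaptive arm's
        "no feedback" share below the random arm's ~20% design share."""
        cfg = SimConfig(
            n_participants=30,
            arm_sizes=(0, 15, 15),
            n_days=120,
            effect_mode="responsive",
            effect_means={
                "feedback": (0.0, 500.0, 500.0, 500.0, 500.0),
                "motivation": (0.0, 0.0, 0.0, 0.0),
                "slot": (0.0, 0.0, 0.0, 0.0),
            },
            effect_sd=50.0,
            residual_sd=500.0,
            sigma_b2=250_000.0,
            missing_days_mean={"control": 5.0, "random": 5.0, "adaptive": 5.0},
        )
        profiles = generate_cohort(cfg, np.random.default_rng(10))
        log = run_trial(profiles, sb.default_bank(), sb.ThompsonSampler(), cfg, seed=10)
        daily = log.decisions[log.decisions.kind == "daily"]
        late = daily[daily.day >= 60]
        share = {
            pol: (late[late.policy == pol].feedback_code == 0).mean()
            for pol in ("adaptive", "random")
        }
        assert share["adaptive"] < share["random"]


class TestQualityFilters:
    @staticmethod
    def _log(spec):
        """spec: {pid: (n_observed, n_over_20k, n_unobserved)}"""
        rows = []
        for pid, (n_obs, n_hi, n_miss) in spec.items():
            day = 0
            for j in range(n_obs):
                steps = 25_000 if j < n_hi else 5_000
                rows.append((pid, day, steps, True))
                day += 1
            for _ in range(n_miss):
                rows.append((pid, day, 0, False))
                day += 1
        return pd.DataFrame(
            rows, columns=["participant_id", "day", "steps", "observed"]
        )

    def test_minimum_day_boundaries(self):
        log = self._log({"P1": (27, 0, 10), "P2": (28, 0, 10), "P3": (0, 0, 30)})
        kept, excl = apply_quality_filters(log)
        assert set(kept.participant_id) == {"P2"}
        reasons = dict(zip(excl.participant_id, excl.reason))
        assert reasons == {"P1": "under_28_days", "P3": "no_step_data"}

    def test_high_count_fraction_strictly_greater_than_quarter(self):
        log = self._log({"P4": (40, 11, 0), "P5": (40, 10, 0)})
        kept, excl = apply_quality_filters(log)
        assert set(kept.participant_id) == {"P5"}  # 10/40 = 25% exactly: kept
        assert excl.iloc[0].reason == "implausible_high_counts"

    def test_clean_log_passes_through(self):
        log = self._log({"P1": (60, 0, 5), "P2": (60, 10, 5)})  # 10/60 < 25%
        kept, excl = apply_quality_filters(log)
        assert excl.empty
        pd.testing.assert_frame_equal(kept, log)

    def test_empty_log_warns(self):
        with pytest.warns(UserWarning):
            kept, excl = apply_quality_filters(
                pd.DataFrame(columns=["participant_id", "day", "steps", "observed"])
            )
        assert kept.empty and excl.empty

    def test_survivors_invariant_under_row_order(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spec = {
                f"P{i}": (
                    int(rng.integers(0, 60)),
                    int(rng.integers(0, 20)),
                    int(rng.integers(0, 10)),
                )
                for i in range(8)
            }
            spec = {
                k: (n, min(h, n), m) for k, (n, h, m) in spec.items()
            }
            log = self._log(spec)
            shuffled = log.sample(frac=1.0, random_state=1).reset_index(drop=True)
            kept1, _ = apply_quality_filters(log)
            kept2, _ = apply_quality_filters(shuffled)
            assert set(kept1.participant_id) == set(kept2.participant_id)
            # independent brute-force oracle per participant
            survivors = set()
            for pid, (n, h, m) in spec.items():
                if n >= 28 and not (n > 0 and h / n > 0.25):
                    survivors.add(pid)
            assert set(kept1.participant_id) == survivors
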